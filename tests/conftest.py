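import pytest

from bearvitals import datasets
from bearvitals.data import EncounterHistory, IntervalRecord


@pytest.fixture(scope="session")
def example_litters():
    return datasets.litters()


@pytest.fixture(scope="session")
def example_encounters():
    return datasets.encounters()


def make_history(bear_id, statuses, population="MM", birth_year=1995,
                 year=2005, cause=None):
    """Encounter history from a compact status string, e.g. 'aaad'."""
    codes = {"a": "alive", "d": "dead", "c": "censored"}
    recs = [IntervalRecord(year + i // 8, i % 8 + 1, codes[s],
                           cause if codes[s] == "dead" else None)
            for i, s in enumerate(statuses)]
    return EncounterHistory(bear_id, population, birth_year, recs)
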