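"""Domain types, CSV round-trips, exposure and crude mortality."""

import pytest

from bearvitals import datasets
from bearvitals.data import (EncounterHistory, IntervalRecord, LitterRecord,
                             SchemaError, ValidationError, bear_years,
                             mortality_rate, read_encounters, read_interbirth,
                             read_litters, read_monitoring_tables,
                             read_primiparity, read_states, write_encounters,
                             write_interbirth, write_litters, write_primiparity,
                             write_states)
from conftest import make_history


class TestInvariants:
    def test_death_must_terminate_history(self):
        with pytest.raises(ValidationError, match="death does not terminate"):
            make_history("b1", "adaa")

    def test_at_most_one_death(self):
        with pytest.raises(ValidationError):
            make_history("b1", "add")

    def test_censoring_terminates_history(self):
        with pytest.raises(ValidationError, match="censoring"):
            make_history("b1", "acaa")

    def test_intervals_strictly_increasing(self):
        recs = [IntervalRecord(2005, 3, "alive"), IntervalRecord(2005, 3, "alive")]
        with pytest.raises(ValidationError, match="strictly increasing"):
            EncounterHistory("b1", "MM", 1999, recs)

    def test_litter_survivors_bounded_by_emergence(self):
        with pytest.raises(ValidationError):
            LitterRecord("m1", "MM", 2010, 2, 3, True)


class TestRoundTrips:
    def test_encounters_round_trip(self, tmp_path, example_encounters):
        path = tmp_path / "enc.csv"
        write_encounters(example_encounters, path)
        back = read_encounters(path)
        assert sorted(h.bear_id for h in back) == \
            sorted(h.bear_id for h in example_encounters)
        by_id = {(h.bear_id, h.segment): h for h in back}
        for h in example_encounters:
            assert by_id[(h.bear_id, h.segment)].records == h.records

    def test_litters_round_trip(self, tmp_path, example_litters):
        path = tmp_path / "lit.csv"
        write_litters(example_litters, path)
        assert read_litters(path) == example_litters

    def test_states_round_trip(self, tmp_path):
        seqs = datasets.state_sequences("MM")
        path = tmp_path / "states.csv"
        write_states(seqs, path)
        back = read_states(path)
        assert {s.bear_id: s.states for s in back} == \
            {s.bear_id: s.states for s in seqs}

    def test_long_format_histories_round_trip(self, tmp_path):
        prim = datasets.nulliparity_histories("MM")
        inter = datasets.interbirth_histories("NSN")
        write_primiparity(prim, tmp_path / "p.csv")
        write_interbirth(inter, tmp_path / "i.csv")
        assert read_primiparity(tmp_path / "p.csv") == prim
        assert read_interbirth(tmp_path / "i.csv") == inter

    def test_missing_column_is_schema_error(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("bear_id,population\nx,MM\n")
        with pytest.raises(SchemaError, match="status|year"):
            read_encounters(bad)

    def test_read_monitoring_tables_rejects_unknown_name(self, tmp_path):
        with pytest.raises(SchemaError, match="unknown table"):
            read_monitoring_tables({"bogus": tmp_path / "x.csv"})

    def test_single_bear_csv_parses_to_one_history(self, tmp_path):
        path = tmp_path / "one.csv"
        path.write_text(
            "bear_id,population,birth_year,year,interval,status,cause\n"
            "b1,MM,1999,2005,1,alive,NA\n"
            "b1,MM,1999,2005,2,alive,NA\n"
            "b1,MM,1999,2005,3,censored,NA\n")
        hist = read_encounters(path)
        assert len(hist) == 1 and hist[0].n_monitored_intervals == 3


class TestExposure:
    def test_full_year_is_one_bear_year(self):
        assert bear_years([make_history("b1", "a" * 8)]) == 1.0

    def test_half_year(self):
        assert bear_years([make_history("b1", "aaaa")]) == 0.5

    def test_additive_over_populations(self, example_encounters):
        total = bear_years(example_encounters)
        parts = sum(bear_years(example_encounters, p) for p in ("MM", "NSN"))
        assert total == pytest.approx(parts)

    def test_unknown_population_raises(self, example_encounters):
        with pytest.raises(ValidationError, match="unknown population"):
            bear_years(example_encounters, "XX")

    def test_bundled_effort_matches_published_totals(self, example_encounters):
        assert bear_years(example_encounters, "MM") == pytest.approx(43.1, abs=0.05)
        assert bear_years(example_encounters, "NSN") == pytest.approx(26.0)


class TestMortalityRate:
    def test_published_rates(self, example_encounters):
        assert round(mortality_rate(example_encounters, "NSN"), 2) == 0.19
        assert round(mortality_rate(example_encounters, "NSN",
                                    {"natural"}), 2) == 0.12

    def test_zero_deaths_zero_rate(self, example_encounters):
        assert mortality_rate(example_encounters, "MM") == 0.0

    def test_rate_additive_over_cause_partition(self, example_encounters):
        full = mortality_rate(example_encounters, "NSN")
        split = sum(mortality_rate(example_encounters, "NSN", {c})
                    for c in ("human", "natural", "unknown"))
        assert full == pytest.approx(split)

    def test_zero_exposure_is_error(self):
        with pytest.raises(ValidationError, match="zero bear-years"):
            mortality_rate([])
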