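"""Bundled example data: two monitored brown bear populations.

These tables describe the two southwest British Columbia study
populations the package was built around: the larger, connected
McGillvary Mountains population (``MM``) and the small, isolated North
Stein-Nahatlatch population (``NSN``).  They are a synthetic
reconstruction assembled from the published summary numbers, suitable for
worked examples and for exercising every estimator at realistic scale.

Exact fields (taken directly from the published summaries):

* litter fate patterns - MM: losses of 2-of-3 and 1-of-2 with six intact
  litters totalling 20 monitored cubs; NSN: one litter of three lost
  entirely and three litters that each lost one of two cubs;
* litter counts - 21 cubs in 9 litters (MM) and 9 cubs in 4 litters (NSN);
* yearling tallies - 20 (MM) and 6 (NSN) yearlings, no mortalities;
* reproductive-state transition probabilities for both populations, and
  the transition totals (38 over 13 females MM, 30 over 6 females NSN);
* monitoring effort - 16 and 9 collared females, 43.1 and 26.0
  bear-years; five NSN deaths (two human-caused at ages 7 and 8, three
  natural at ages 18, 4 and 20), none in MM;
* point vital rates (cub / yearling / independent-female survival and
  the adult reproductive rate).

Filled-in fields (not published; chosen consistent with the above):

* the individual sizes of the six intact MM litters, (3, 3, 3, 2, 2, 2);
* the size-1 ninth MM litter whose mother dropped her collar (so litter
  sizes total 21 over 9 while only 20 cubs were monitored);
* the per-female partition of state transitions into year chains;
* the exact per-bear monitoring spans behind the bear-year totals.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .data import (EncounterHistory, IntervalRecord, InterbirthHistory,
                   LitterRecord, NulliparityHistory, StateObservation,
                   StateSequence, YearlingRecord, write_encounters,
                   write_interbirth, write_litters, write_primiparity,
                   write_states, write_yearlings)
from .projection import VitalRateSet
from .transitions import STATES, TransitionMatrix

POPULATIONS = ("MM", "NSN")

# (size at emergence, survivors, monitored to autumn)
_LITTER_FATES = {
    "MM": [(3, 1, True), (2, 1, True), (3, 3, True), (3, 3, True),
           (3, 3, True), (2, 2, True), (2, 2, True), (2, 2, True),
           (1, 0, False)],   # collar dropped before autumn
    "NSN": [(3, 0, True), (2, 1, True), (2, 1, True), (2, 1, True)],
}

_YEARLING_BROODS = {
    "MM": [(3, 3), (3, 3), (3, 3), (3, 3), (2, 2), (2, 2), (2, 2), (2, 2)],
    "NSN": [(2, 2), (2, 2), (2, 2)],
}

# published transition probabilities, rows/cols ordered (A, C, Y, T)
TRANSITION_PROBS = {
    "MM": np.array([[0.63, 0.38, 0.00, 0.00],
                    [0.00, 0.00, 1.00, 0.00],
                    [0.00, 0.00, 0.00, 1.00],
                    [0.75, 0.25, 0.00, 0.00]]),
    "NSN": np.array([[0.67, 0.33, 0.00, 0.00],
                     [0.17, 0.00, 0.83, 0.00],
                     [0.00, 0.00, 0.00, 1.00],
                     [1.00, 0.00, 0.00, 0.00]]),
}

# reconstructed integer tallies: row proportions reproduce the published
# entries; row totals reproduce the published transition totals (38, 30)
TRANSITION_COUNTS = {
    "MM": np.array([[10, 6, 0, 0],
                    [0, 0, 10, 0],
                    [0, 0, 0, 8],
                    [3, 1, 0, 0]]),
    "NSN": np.array([[8, 4, 0, 0],
                     [1, 0, 5, 0],
                     [0, 0, 0, 7],
                     [5, 0, 0, 0]]),
}

_N_FEMALES_TRANSITIONS = {"MM": 13, "NSN": 6}

# point vital rates: (S_cub, S_yearling, S_subadult, S_adult, m_adult)
_VITAL_RATES = {
    "MM": (0.85, 1.00, 1.00, 1.00, 0.23),
    "NSN": (0.33, 1.00, 0.81, 0.81, 0.19),
}

LITTER_SIZE_POINT = {"MM": 2.33, "NSN": 2.25}
PI_C_POINT = {"MM": 0.20, "NSN": 0.17}  # published stationary cub proportion


def _check_pop(population: str) -> None:
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}; "
                         f"expected one of {POPULATIONS}")


def litters(population: str | None = None) -> list[LitterRecord]:
    pops = POPULATIONS if population is None else (population,)
    out = []
    for p in pops:
        _check_pop(p)
        for i, (size, surv, mon) in enumerate(_LITTER_FATES[p]):
            out.append(LitterRecord(f"{p}-L{i + 1:02d}", p, 2006 + i, size,
                                    surv if mon else 0, mon))
    return out


def yearlings(population: str | None = None) -> list[YearlingRecord]:
    pops = POPULATIONS if population is None else (population,)
    out = []
    for p in pops:
        _check_pop(p)
        for i, (n, surv) in enumerate(_YEARLING_BROODS[p]):
            out.append(YearlingRecord(f"{p}-Y{i + 1:02d}", p, 2007 + i, n,
                                      surv, True))
    return out


def transition_matrix(population: str,
                      source: str = "printed") -> TransitionMatrix:
    """The reproductive-state transition matrix for one population.

    ``source='printed'`` uses the published (2-dp, row-renormalized)
    probabilities; ``source='counts'`` uses the reconstructed integer
    tallies (exactly row-stochastic).
    """
    _check_pop(population)
    if source == "printed":
        return TransitionMatrix.from_probabilities(TRANSITION_PROBS[population])
    if source == "counts":
        return TransitionMatrix.from_counts(TRANSITION_COUNTS[population])
    raise ValueError(f"unknown source {source!r}")


def state_sequences(population: str) -> list[StateSequence]:
    """Per-female annual state chains whose pooled transitions equal the
    reconstructed tallies (a deterministic walk decomposition)."""
    _check_pop(population)
    remaining = TRANSITION_COUNTS[population].copy()
    n_females = _N_FEMALES_TRANSITIONS[population]
    seqs: list[StateSequence] = []
    fid = 0
    while remaining.sum() > 0:
        fid += 1
        # start at the state with the largest remaining out-degree
        start = int(np.argmax(remaining.sum(axis=1)))
        chain = [start]
        females_left = max(1, n_females - len(seqs))
        target_len = int(np.ceil(remaining.sum() / females_left))
        cur = start
        while remaining[cur].sum() > 0 and len(chain) - 1 < target_len:
            nxt = int(np.argmax(remaining[cur]))
            remaining[cur, nxt] -= 1
            chain.append(nxt)
            cur = nxt
        year0 = 2005 + (fid % 3)
        birth_year = year0 - 8  # adult throughout
        obs = [StateObservation(year0 + i, STATES[s], year0 + i - birth_year)
               for i, s in enumerate(chain)]
        seqs.append(StateSequence(f"{population}-S{fid:02d}", population, obs))
    return seqs


def _spans(total_intervals: int, n_bears: int) -> list[int]:
    base = total_intervals // n_bears
    extra = total_intervals - base * n_bears
    return [base + (1 if i < extra else 0) for i in range(n_bears)]


def encounters() -> list[EncounterHistory]:
    """Monitoring histories matching the published effort and mortalities.

    16 MM females over 345 bear-intervals (43.1 bear-years, no deaths) and
    9 NSN females over 208 bear-intervals (26.0 bear-years) with five
    deaths: human-caused at ages 7 and 8, natural at ages 18, 4 and 20.
    """
    out: list[EncounterHistory] = []
    # NSN deaths: (age at death, cause); remaining bears are censored
    nsn_deaths = [(7, "human"), (8, "human"), (18, "natural"),
                  (4, "natural"), (20, "natural")]
    for pop, total, n_bears in (("MM", 345, 16), ("NSN", 208, 9)):
        for i, n_int in enumerate(_spans(total, n_bears)):
            start_year = 2005 + (i % 10)
            death = nsn_deaths[i] if pop == "NSN" and i < len(nsn_deaths) else None
            age_at_end = death[0] if death else 10
            birth_year = start_year + (n_int - 1) // 8 - age_at_end
            recs = []
            for k in range(n_int):
                year = start_year + k // 8
                interval = k % 8 + 1
                if k == n_int - 1:
                    if death:
                        recs.append(IntervalRecord(year, interval, "dead",
                                                   death[1]))
                    else:
                        recs.append(IntervalRecord(year, interval, "censored"))
                else:
                    recs.append(IntervalRecord(year, interval, "alive"))
            out.append(EncounterHistory(f"{pop}-E{i + 1:02d}", pop,
                                        birth_year, recs))
    return out


def vital_rates(population: str) -> VitalRateSet:
    """Published point vital rates assembled for the projection model."""
    _check_pop(population)
    sc, sy, ss, sa, m = _VITAL_RATES[population]
    return VitalRateSet(s_cub=sc, s_yearling=sy, s_subadult=ss, s_adult=sa,
                        m_adult=m)


def interbirth_histories(population: str) -> list[InterbirthHistory]:
    """Completed and partial interbirth intervals at published scale.

    NSN: four completed intervals {4, 4, 5, 5} under full monitoring (the
    published mean is 4.50).  MM: six completed and six partial intervals
    (individual values unpublished; filled in around the published 4.08).
    """
    _check_pop(population)
    out = []
    if population == "NSN":
        for i, t in enumerate([4, 4, 5, 5]):
            out.append(InterbirthHistory(f"NSN-I{i + 1:02d}", "NSN", 2006 + i,
                                         frozenset(range(1, t + 1)), t))
    else:
        completed = [3, 4, 4, 4, 4, 5]
        partial = [2, 3, 3, 2, 1, 3]   # monitored offsets with no next litter
        for i, t in enumerate(completed):
            out.append(InterbirthHistory(f"MM-I{i + 1:02d}", "MM", 2006 + i,
                                         frozenset(range(1, t + 1)), t))
        for i, w in enumerate(partial):
            out.append(InterbirthHistory(f"MM-I{i + 7:02d}", "MM", 2008 + i,
                                         frozenset(range(1, w + 1)), None))
    return out


def nulliparity_histories(population: str = "MM") -> list[NulliparityHistory]:
    """Age-of-primiparity histories for the larger population.

    Reconstruction of the published narrative: three females censored
    still-nulliparous at ages 6, 7 and 8; first surviving litters observed
    at ages 8, 9 and 11.
    """
    _check_pop(population)
    if population != "MM":
        return [NulliparityHistory("NSN-P01", "NSN", frozenset({7}), None),
                NulliparityHistory("NSN-P02", "NSN", frozenset({6, 7, 8}), None),
                NulliparityHistory("NSN-P03", "NSN",
                                   frozenset(range(8, 12)), 12)]
    return [
        NulliparityHistory("MM-P01", "MM", frozenset({5, 6}), None),
        NulliparityHistory("MM-P02", "MM", frozenset({5, 6, 7}), None),
        NulliparityHistory("MM-P03", "MM", frozenset({6, 7, 8}), None),
        NulliparityHistory("MM-P04", "MM", frozenset(range(5, 11)), 11),
        NulliparityHistory("MM-P05", "MM", frozenset({4, 5, 6, 7}), 8),
        NulliparityHistory("MM-P06", "MM", frozenset({6, 7, 8}), 9),
    ]


def write_tables(directory: str | Path) -> None:
    """Write all example tables as the standard CSV files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_encounters(encounters(), d / "encounters.csv")
    write_litters(litters(), d / "litters.csv")
    write_yearlings(yearlings(), d / "yearlings.csv")
    write_states([s for p in POPULATIONS for s in state_sequences(p)],
                 d / "states.csv")
    write_primiparity([h for p in POPULATIONS for h in nulliparity_histories(p)],
                      d / "primiparity.csv")
    write_interbirth([h for p in POPULATIONS for h in interbirth_histories(p)],
                     d / "interbirth.csv")
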