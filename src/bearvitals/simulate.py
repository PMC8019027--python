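"""Individual-based simulator of a telemetry-monitored bear population.

The simulator exists so that every estimator in this package can be tested
by parameter recovery: it generates female life histories from known true
vital rates, overlays a monitoring layer that mimics a collaring study
(staggered capture, collar loss, imperfect per-relocation detection, an
8-week censoring rule), and emits exactly the monitoring tables the
estimators consume, together with the generating truth.

Biology (one annual cycle, den emergence to den emergence):

* cubs appear at den emergence (interval 1; a birth-pulse model);
* an Alone female breeds in spring with probability given by her
  age-at-first-litter hazard (nulliparous) or a fixed post-weaning
  breeding probability (parous) - interbirth intervals therefore EMERGE
  from the weaning age and breeding probability rather than being drawn
  from an assumed distribution;
* each cub survives its first year independently with S_cub; surviving
  cubs make the mother "with yearlings" (Y) next spring, total litter
  loss returns her to Alone;
* yearlings survive with S_yearling; with weaning age 3 the family spends
  one more year in the two-year-old state (T) before the offspring are
  weaned;
* half of weaned offspring (binomially) are daughters and join the
  population as independent subadults;
* a female dies within a year with probability 1 - S(age class), at a
  uniformly drawn monthly interval so encounter histories carry
  within-year information; orphaned cubs die with their mother, older
  dependents finish dependency on their own.

Monitoring:

* expected new collars per population-year (Poisson draw; truncated with
  a warning if fewer uncollared females are alive);
* collar retention is exponential with configurable mean life; collar
  drop censors the bear at the drop interval;
* relocation flights are spread over the April..October intervals; each
  contacts the bear with fixed probability.  A missed flight opens a gap
  longer than eight weeks before the next possible contact, so the bear
  is censored at her last successful contact.  Deaths before the
  monitoring span ends are always recorded (mortality-signal collars)
  with a cause split between human and natural.

Every female carries her own RNG substream derived from the scenario seed
and her creation index, so her life history is invariant to changes in
the monitoring schedule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data import (INTERVALS_PER_YEAR, EncounterHistory, IntervalRecord,
                   InterbirthHistory, LitterRecord, NulliparityHistory,
                   StateObservation, StateSequence, YearlingRecord,
                   write_encounters, write_interbirth, write_litters,
                   write_primiparity, write_states, write_yearlings)

_ACTIVE_INTERVALS = 7  # April..October; interval 8 is the pooled denning gap


@dataclass
class PopulationTruth:
    """Generating vital rates for one simulated population."""

    label: str
    n_initial_females: int
    true_s_cub: float
    true_s_yearling: float
    true_s_subadult: float
    true_s_adult: float
    litter_size_pmf: Mapping[int, float]
    age_first_litter_hazard: Mapping[int, float]
    post_weaning_breed_prob: float
    weaning_age: int = 3
    cause_human_prob: float = 0.4

    def __post_init__(self) -> None:
        for p in (self.true_s_cub, self.true_s_yearling, self.true_s_subadult,
                  self.true_s_adult, self.post_weaning_breed_prob,
                  self.cause_human_prob, *self.age_first_litter_hazard.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.litter_size_pmf.values()) - 1.0) > 1e-9:
            raise ValueError("litter_size_pmf must sum to 1")
        if self.weaning_age not in (2, 3):
            raise ValueError("weaning_age must be 2 or 3")

    def survival_at(self, age: int) -> float:
        if age == 0:
            return self.true_s_cub
        if age == 1:
            return self.true_s_yearling
        if age < 6:
            return self.true_s_subadult
        return self.true_s_adult

    def first_litter_hazard(self, age: int) -> float:
        haz = self.age_first_litter_hazard
        if not haz or age < min(haz):
            return 0.0
        return haz[age] if age in haz else haz[max(haz)]

    @property
    def mean_litter_size(self) -> float:
        return sum(k * p for k, p in self.litter_size_pmf.items())


@dataclass
class SimulationScenario:
    populations: list[PopulationTruth]
    n_years: int = 14
    start_year: int = 2005
    capture_schedule: Mapping[str, Sequence[float] | float] = field(
        default_factory=dict)  # expected new collars / population / year
    collar_life_mean: float = 3.0            # years, exponential retention
    detection_prob_per_relocation: float = 0.95
    relocations_per_year: int = 3
    censor_rule_weeks: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("n_years must be at least 2")
        if not 0.0 <= self.detection_prob_per_relocation <= 1.0:
            raise ValueError("detection probability outside [0, 1]")

    def expected_captures(self, label: str, year_index: int) -> float:
        sched = self.capture_schedule.get(label, 0.0)
        if np.isscalar(sched):
            return float(sched)
        return float(sched[year_index]) if year_index < len(sched) else 0.0


class _Female:
    """A simulated female's full (true) life history."""

    __slots__ = ("uid", "pop", "birth_year", "death_gi", "death_cause",
                 "parous", "init_parous", "state", "n_dep", "rng", "births",
                 "cub_survivors", "yearling_survivors", "states_by_year")

    def __init__(self, uid: int, pop: str, birth_year: int,
                 rng: np.random.Generator):
        self.uid = uid
        self.pop = pop
        self.birth_year = birth_year
        self.death_gi: int | None = None     # global interval index of death
        self.death_cause: str | None = None
        self.parous = False
        self.init_parous = False             # parous before the study began
        self.state = "A"
        self.n_dep = 0                       # dependents currently alive
        self.rng = rng
        self.births: dict[int, int] = {}     # year -> litter size at emergence
        self.cub_survivors: dict[int, int] = {}       # birth year -> alive at 1
        self.yearling_survivors: dict[int, int] = {}  # birth year -> alive at 2
        self.states_by_year: dict[int, str] = {}

    @property
    def alive(self) -> bool:
        return self.death_gi is None


def _gi(start_year: int, year: int, interval: int) -> int:
    """Global interval index from (calendar year, interval 1..8)."""
    return (year - start_year) * INTERVALS_PER_YEAR + (interval - 1)


def _female_rng(seed: int, pop_index: int, uid: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(pop_index, uid)))


def _simulate_lives(scenario: SimulationScenario, truth: PopulationTruth,
                    pop_index: int) -> tuple[list[_Female], dict]:
    """Run the demographic process for one population (no monitoring)."""
    seed = scenario.rng_seed
    init_rng = _female_rng(seed, pop_index, 0)
    females: list[_Female] = []
    uid = 1
    y0 = scenario.start_year
    for _ in range(truth.n_initial_females):
        age = int(init_rng.integers(2, 13))
        f = _Female(uid, truth.label, y0 - age, _female_rng(seed, pop_index, uid))
        if age >= 7 and init_rng.random() < 0.5:
            f.parous = f.init_parous = True
        females.append(f)
        uid += 1

    sizes = sorted(truth.litter_size_pmf)
    size_p = np.array([truth.litter_size_pmf[s] for s in sizes])
    tally = {"cubs": [0, 0], "independent_years": [0, 0],
             "litter_sizes": [], "completed_intervals": []}

    for yi in range(scenario.n_years):
        year = y0 + yi
        recruits: list[int] = []   # birth years of newly weaned daughters
        for f in females:
            if not f.alive:
                continue
            age = year - f.birth_year
            if age < 2:
                continue  # pre-independence ages live through their mother
            # spring: breeding decision for females without dependents
            if f.state == "A":
                p = (truth.post_weaning_breed_prob if f.parous
                     else truth.first_litter_hazard(age))
                if p > 0 and f.rng.random() < p:
                    size = int(f.rng.choice(sizes, p=size_p))
                    prev = [y for y in f.births if y < year]
                    if prev:
                        tally["completed_intervals"].append(year - max(prev))
                    f.state = "C"
                    f.parous = True
                    f.n_dep = size
                    f.births[year] = size
                    tally["litter_sizes"].append(size)
            f.states_by_year[year] = f.state
            # the female's own mortality this year
            died = f.rng.random() >= truth.survival_at(age)
            tally["independent_years"][0] += 1
            tally["independent_years"][1] += int(died)
            if died:
                f.death_gi = _gi(y0, year,
                                 int(f.rng.integers(1, INTERVALS_PER_YEAR + 1)))
                f.death_cause = ("human"
                                 if f.rng.random() < truth.cause_human_prob
                                 else "natural")
            # dependent offspring fates this year
            if f.state == "C":
                survivors = 0
                for _ in range(f.n_dep):
                    lived = (f.rng.random() < truth.true_s_cub) and not died
                    tally["cubs"][0] += 1
                    tally["cubs"][1] += int(lived)
                    survivors += int(lived)
                f.cub_survivors[year] = survivors
                f.n_dep = survivors
                f.state = "Y" if survivors > 0 else "A"
            elif f.state == "Y":
                by = year - 1
                survivors = int(sum(f.rng.random() < truth.true_s_yearling
                                    for _ in range(f.n_dep)))
                f.yearling_survivors[by] = survivors
                f.n_dep = survivors
                if truth.weaning_age == 2 or survivors == 0:
                    recruits.extend([by] * int(f.rng.binomial(survivors, 0.5)))
                    f.n_dep = 0
                    f.state = "A"
                else:
                    f.state = "T"
            elif f.state == "T":
                by = year - 2
                survivors = int(sum(f.rng.random() < truth.true_s_subadult
                                    for _ in range(f.n_dep)))
                recruits.extend([by] * int(f.rng.binomial(survivors, 0.5)))
                f.n_dep = 0
                f.state = "A"
            if died:
                f.n_dep = 0  # orphans either died above or were weaned here
        for birth_year in recruits:
            females.append(_Female(uid, truth.label, birth_year,
                                   _female_rng(seed, pop_index, uid)))
            uid += 1
    return females, tally


def _monitor(scenario: SimulationScenario, truth: PopulationTruth,
             pop_index: int, females: list[_Female]
             ) -> dict[int, list[tuple[int, int, str]]]:
    """Collaring layer: per-female monitored spans (start, stop, end status)."""
    mon_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=scenario.rng_seed,
                               spawn_key=(pop_index, 10_000_000)))
    y0 = scenario.start_year
    end_gi = _gi(y0, y0 + scenario.n_years - 1, INTERVALS_PER_YEAR)
    k = max(1, scenario.relocations_per_year)
    flight_intervals = sorted({int(round(v))
                               for v in np.linspace(1, _ACTIVE_INTERVALS, k)})
    spans: dict[int, list[tuple[int, int, str]]] = {}

    def span_active(uid: int, gi: int) -> bool:
        return any(a <= gi <= b for a, b, _ in spans.get(uid, []))

    for yi in range(scenario.n_years):
        year = y0 + yi
        start_gi = _gi(y0, year, 1)
        expected = scenario.expected_captures(truth.label, yi)
        n_new = int(mon_rng.poisson(expected)) if expected > 0 else 0
        if n_new == 0:
            continue
        candidates = [f for f in females
                      if year - f.birth_year >= 2
                      and (f.death_gi is None or f.death_gi >= start_gi)
                      and not span_active(f.uid, start_gi)]
        if n_new > len(candidates):
            warnings.warn(
                f"{truth.label} year {year}: schedule asks for {n_new} new "
                f"collars but only {len(candidates)} uncollared females "
                "available; truncated")
            n_new = len(candidates)
        chosen = mon_rng.choice(len(candidates), size=n_new, replace=False)
        for ci in sorted(chosen):
            f = candidates[ci]
            drop_gi = start_gi + int(
                mon_rng.exponential(scenario.collar_life_mean)
                * INTERVALS_PER_YEAR)
            last_known = start_gi  # capture itself is a contact
            censor_gi: int | None = None
            for g in range(start_gi + 1, min(drop_gi, end_gi) + 1):
                if g % INTERVALS_PER_YEAR + 1 in flight_intervals:
                    if mon_rng.random() < scenario.detection_prob_per_relocation:
                        last_known = g
                    else:
                        censor_gi = last_known  # >8-week gap to next contact
                        break
            limit = censor_gi if censor_gi is not None else min(drop_gi, end_gi)
            death_gi = f.death_gi if f.death_gi is not None else end_gi + 1
            if death_gi <= limit:
                stop, status = death_gi, "dead"
            elif censor_gi is not None:
                stop, status = censor_gi, "censored"
            elif drop_gi <= end_gi:
                stop, status = drop_gi, "censored"
            else:
                stop, status = end_gi, "alive"  # monitored through study end
            spans.setdefault(f.uid, []).append((start_gi, stop, status))
    return spans


def _tables_from_monitoring(scenario: SimulationScenario,
                            females: list[_Female],
                            spans: dict[int, list[tuple[int, int, str]]]
                            ) -> dict[str, list]:
    """Derive the monitoring CSV tables from true lives + collar spans."""
    y0 = scenario.start_year
    last_year = y0 + scenario.n_years - 1
    by_uid = {f.uid: f for f in females}
    tables: dict[str, list] = {k: [] for k in ("encounters", "litters",
                                               "yearlings", "states",
                                               "primiparity", "interbirth")}

    def covers(uid: int, year: int, interval: int) -> bool:
        if not y0 <= year <= last_year:
            return False
        gi = _gi(y0, year, interval)
        return any(a <= gi <= b for a, b, _ in spans.get(uid, []))

    for uid in sorted(spans):
        f = by_uid[uid]
        bid = f"{f.pop}-{uid:03d}"
        for seg, (a, b, status) in enumerate(spans[uid]):
            recs = []
            for g in range(a, b + 1):
                year = y0 + g // INTERVALS_PER_YEAR
                interval = g % INTERVALS_PER_YEAR + 1
                if g == b and status != "alive":
                    recs.append(IntervalRecord(
                        year, interval, status,
                        f.death_cause if status == "dead" else None))
                else:
                    recs.append(IntervalRecord(year, interval, "alive"))
            tables["encounters"].append(
                EncounterHistory(bid, f.pop, f.birth_year, recs, segment=seg))

        obs = [StateObservation(y, s, y - f.birth_year)
               for y, s in sorted(f.states_by_year.items())
               if covers(uid, y, 1)]
        if obs:
            tables["states"].append(StateSequence(bid, f.pop, obs))

        for year, size in sorted(f.births.items()):
            if not covers(uid, year, 1):
                continue
            to_autumn = covers(uid, year, _ACTIVE_INTERVALS)
            cub_surv = f.cub_survivors.get(year, 0)
            tables["litters"].append(LitterRecord(
                bid, f.pop, year, size, cub_surv if to_autumn else 0,
                to_autumn))
            # yearling brood, observable while mother monitored next year
            if cub_surv > 0 and covers(uid, year + 1, 1):
                mon = (covers(uid, year + 1, _ACTIVE_INTERVALS)
                       and year in f.yearling_survivors)
                tables["yearlings"].append(YearlingRecord(
                    bid, f.pop, year + 1, cub_surv,
                    f.yearling_survivors.get(year, 0) if mon else 0, mon))

        prim = _primiparity_history(f, bid, covers)
        if prim is not None:
            tables["primiparity"].append(prim)
        tables["interbirth"].extend(
            _interbirth_histories(f, bid, scenario, covers))
    return tables


def _primiparity_history(f: _Female, bid: str, covers) -> NulliparityHistory | None:
    """Availability history for age of first litter; None if uninformative.

    Females parous before the study, or first seen already with a litter,
    are left-truncated and contribute nothing (their parity history is
    unknown); monitored nulliparous springs contribute exposure from age 4.
    """
    if f.init_parous:
        return None
    first = min(f.births) if f.births else None
    nullip = {y - f.birth_year for y in f.states_by_year
              if (first is None or y < first) and y - f.birth_year >= 4
              and covers(f.uid, y, 1)}
    event = None
    if first is not None and covers(f.uid, first, 1) and nullip:
        event = first - f.birth_year
    if not nullip:
        return None
    return NulliparityHistory(bid, f.pop, frozenset(nullip), event)


def _interbirth_histories(f: _Female, bid: str, scenario: SimulationScenario,
                          covers) -> list[InterbirthHistory]:
    out = []
    last_year = scenario.start_year + scenario.n_years - 1
    for by in sorted(f.births):
        if not covers(f.uid, by, 1):
            continue
        offsets: set[int] = set()
        event = None
        for t in range(1, last_year - by + 1):
            target = by + t
            if target in f.births:       # risk ends at the next true birth
                if covers(f.uid, target, 1):
                    offsets.add(t)
                    event = t
                break
            if covers(f.uid, target, 1):
                offsets.add(t)
        if offsets:
            out.append(InterbirthHistory(bid, f.pop, by, frozenset(offsets),
                                         event))
    return out


@dataclass
class SimulationResult:
    scenario: SimulationScenario
    encounters: list[EncounterHistory]
    litters: list[LitterRecord]
    yearlings: list[YearlingRecord]
    states: list[StateSequence]
    primiparity: list[NulliparityHistory]
    interbirth: list[InterbirthHistory]
    truth: dict

    def write_tables(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_encounters(self.encounters, d / "encounters.csv")
        write_litters(self.litters, d / "litters.csv")
        write_yearlings(self.yearlings, d / "yearlings.csv")
        write_states(self.states, d / "states.csv")
        write_primiparity(self.primiparity, d / "primiparity.csv")
        write_interbirth(self.interbirth, d / "interbirth.csv")
        with open(d / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def simulate_population(scenario: SimulationScenario) -> SimulationResult:
    """Run the full simulation: demography, monitoring, and table assembly."""
    all_tables: dict[str, list] = {k: [] for k in (
        "encounters", "litters", "yearlings", "states", "primiparity",
        "interbirth")}
    truth_out: dict = {"rng_seed": scenario.rng_seed, "populations": {}}
    for pi, truth in enumerate(scenario.populations):
        females, tally = _simulate_lives(scenario, truth, pi)
        spans = _monitor(scenario, truth, pi, females)
        for k, v in _tables_from_monitoring(scenario, females, spans).items():
            all_tables[k].extend(v)
        cub_n, cub_s = tally["cubs"]
        ind_n, ind_d = tally["independent_years"]
        truth_out["populations"][truth.label] = {
            "true_s_cub": truth.true_s_cub,
            "true_s_yearling": truth.true_s_yearling,
            "true_s_subadult": truth.true_s_subadult,
            "true_s_adult": truth.true_s_adult,
            "true_mean_litter_size": truth.mean_litter_size,
            "post_weaning_breed_prob": truth.post_weaning_breed_prob,
            "weaning_age": truth.weaning_age,
            "realized_cub_survival": (cub_s / cub_n) if cub_n else None,
            "realized_independent_survival": (1 - ind_d / ind_n) if ind_n else None,
            "realized_mean_litter_size": (float(np.mean(tally["litter_sizes"]))
                                          if tally["litter_sizes"] else None),
            "realized_mean_interbirth": (
                float(np.mean(tally["completed_intervals"]))
                if tally["completed_intervals"] else None),
        }
    return SimulationResult(scenario, truth=truth_out, **all_tables)


# ---------------------------------------------------------------------------
# Reference scenarios for the two study populations
# ---------------------------------------------------------------------------

def study_truth(label: str) -> PopulationTruth:
    """Generating truth matching the published point estimates per population.

    MM is the larger, connected population (high survival throughout);
    NSN the small, isolated one (low cub and independent-female survival).
    Litter-size distributions give the published means (2.33 and 2.25
    cubs); with weaning at 3 the post-weaning breeding probability p gives
    an emergent mean interbirth interval of 2 + 1/p years (4.08 and 4.5);
    the first-litter hazards encode the late (8+ years) primiparity these
    populations show.
    """
    if label == "MM":
        return PopulationTruth(
            label="MM", n_initial_females=14,
            true_s_cub=0.85, true_s_yearling=1.0,
            true_s_subadult=1.0, true_s_adult=1.0,
            litter_size_pmf={1: 0.13, 2: 0.41, 3: 0.46},      # mean 2.33
            age_first_litter_hazard={5: 0.05, 6: 0.10, 7: 0.20, 8: 0.35,
                                     9: 0.40, 10: 0.50, 11: 0.60},
            post_weaning_breed_prob=0.48,                      # mean IBI 4.08
            weaning_age=3, cause_human_prob=0.4)
    if label == "NSN":
        return PopulationTruth(
            label="NSN", n_initial_females=10,
            true_s_cub=0.33, true_s_yearling=1.0,
            true_s_subadult=0.81, true_s_adult=0.81,
            litter_size_pmf={1: 0.15, 2: 0.45, 3: 0.40},      # mean 2.25
            age_first_litter_hazard={6: 0.05, 7: 0.10, 8: 0.20, 9: 0.30,
                                     10: 0.40, 11: 0.50, 12: 0.60},
            post_weaning_breed_prob=0.40,                      # mean IBI 4.5
            weaning_age=3, cause_human_prob=0.4)
    raise ValueError(f"unknown population label {label!r}")


def study_scenario(populations: str | Sequence[str] = ("MM", "NSN"),
                   rng_seed: int = 0) -> SimulationScenario:
    """A 14-year two-population monitoring study at published scale.

    Collaring effort is calibrated so the expected realized effort matches
    the published study: about 16 collared females and 43 bear-years in
    the larger population, about 9 females and 26 bear-years in the
    smaller one, where captures stop after year 10 (captures there were
    halted once the high female mortality was recognized).  Three
    relocation flights per active season, 95% per-flight detection,
    4.5-year mean collar retention (recollaring of the same female
    maintains continuity as a new history segment).
    """
    if isinstance(populations, str):
        populations = (populations,)
    pops = [study_truth(p) for p in populations]
    schedule = {"MM": [1.3] * 14, "NSN": [2.0] * 10 + [0.0] * 4}
    return SimulationScenario(
        populations=pops, n_years=14, start_year=2005,
        capture_schedule={p.label: schedule[p.label] for p in pops},
        collar_life_mean=4.5, detection_prob_per_relocation=0.95,
        relocations_per_year=3, censor_rule_weeks=8, rng_seed=rng_seed)
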