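"""Domain types and CSV I/O for telemetry-based bear demography.

The monitoring year is divided into eight intervals: the seven months
April..October (intervals 1-7) plus a single pooled November..March
denning interval (8).  One full monitored year therefore contributes
eight bear-intervals, and exposure in bear-years is intervals / 8.

Statuses in an encounter history:

* ``alive``    - the bear was monitored and known alive through the interval;
* ``dead``     - the bear died during the interval (terminates the history);
* ``censored`` - last interval of known status before the bear left the
  study (collar drop, or unseen for more than eight consecutive weeks);
  the bear counts as at-risk exposure in this interval but contributes
  no further information.

A re-collared bear is a new :class:`EncounterHistory` with the same
``bear_id`` and an incremented ``segment``; the survival estimators only
need risk intervals, so re-entry is never modelled within one history.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

INTERVALS_PER_YEAR = 8
STATUSES = ("alive", "dead", "censored")
CAUSES = ("human", "natural", "unknown")
STATES = ("A", "C", "Y", "T")


class SchemaError(ValueError):
    """A CSV file is missing a mandatory column or has malformed values."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class AgeClassRule:
    """Age-class boundaries: subadults 2-5, adults 6+, last reproduction at 24."""

    subadult_min: int = 2
    adult_min: int = 6
    last_reproductive_age: int = 24

    def age_class(self, age: int) -> str:
        if age < 0:
            raise ValidationError(f"negative age {age}")
        if age == 0:
            return "cub"
        if age == 1:
            return "yearling"
        if age < self.adult_min:
            return "subadult"
        return "adult"


@dataclass(frozen=True)
class IntervalRecord:
    year: int
    interval: int  # 1..8
    status: str
    cause: str | None = None  # only meaningful for status == "dead"


@dataclass
class EncounterHistory:
    """Per-interval known-fate record for one collared female (one collar span)."""

    bear_id: str
    population: str
    birth_year: int
    records: list[IntervalRecord] = field(default_factory=list)
    segment: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev = None
        n_dead = 0
        for i, rec in enumerate(self.records):
            if rec.status not in STATUSES:
                raise ValidationError(
                    f"bear {self.bear_id}: unknown status {rec.status!r}")
            if not 1 <= rec.interval <= INTERVALS_PER_YEAR:
                raise ValidationError(
                    f"bear {self.bear_id}: interval {rec.interval} out of range")
            key = (rec.year, rec.interval)
            if prev is not None and key <= prev:
                raise ValidationError(
                    f"bear {self.bear_id}: intervals not strictly increasing at {key}")
            prev = key
            if rec.status == "dead":
                n_dead += 1
                if i != len(self.records) - 1:
                    raise ValidationError(
                        f"bear {self.bear_id}: death does not terminate the history")
            if rec.status == "censored" and i != len(self.records) - 1:
                raise ValidationError(
                    f"bear {self.bear_id}: censoring does not terminate the history")
        if n_dead > 1:
            raise ValidationError(f"bear {self.bear_id}: multiple death records")

    @property
    def n_monitored_intervals(self) -> int:
        return len(self.records)

    def age_in(self, year: int) -> int:
        """Age in completed years at den emergence of ``year``."""
        return year - self.birth_year


@dataclass
class LitterRecord:
    """A mother-year: cubs counted at den emergence and their first-year fates."""

    mother_id: str
    population: str
    year: int
    n_cubs_emergence: int
    n_cubs_survived: int
    monitored_to_autumn: bool

    def __post_init__(self) -> None:
        if not 0 <= self.n_cubs_survived <= self.n_cubs_emergence:
            raise ValidationError(
                f"mother {self.mother_id} year {self.year}: "
                f"{self.n_cubs_survived} survivors of {self.n_cubs_emergence} cubs")


@dataclass
class YearlingRecord:
    """A mother-year of yearling fates (same shape as :class:`LitterRecord`)."""

    mother_id: str
    population: str
    year: int
    n_yearlings: int
    n_survived: int
    monitored: bool

    def __post_init__(self) -> None:
        if not 0 <= self.n_survived <= self.n_yearlings:
            raise ValidationError(
                f"mother {self.mother_id} year {self.year}: "
                f"{self.n_survived} survivors of {self.n_yearlings} yearlings")


@dataclass(frozen=True)
class StateObservation:
    year: int
    state: str  # A | C | Y | T
    age: int


@dataclass
class StateSequence:
    """A female's annual reproductive states at den emergence."""

    bear_id: str
    population: str
    states: list[StateObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        years = [s.year for s in self.states]
        if years != sorted(set(years)):
            raise ValidationError(f"bear {self.bear_id}: state years not increasing")
        for s in self.states:
            if s.state not in STATES:
                raise ValidationError(
                    f"bear {self.bear_id}: unknown state {s.state!r}")


@dataclass
class NulliparityHistory:
    """Monitored nulliparous ages and (possibly censored) age at first litter."""

    bear_id: str
    population: str
    ages_monitored_nulliparous: frozenset[int]
    age_first_litter: int | None = None  # None = censored without reproducing

    def __post_init__(self) -> None:
        if self.age_first_litter is not None:
            if any(a >= self.age_first_litter
                   for a in self.ages_monitored_nulliparous):
                raise ValidationError(
                    f"bear {self.bear_id}: first litter at {self.age_first_litter} "
                    "does not exceed all nulliparous monitored ages")


@dataclass
class InterbirthHistory:
    """Offsets monitored after a birth year and the next-birth offset if seen."""

    bear_id: str
    population: str
    birth_year: int
    years_monitored_after: frozenset[int]
    next_birth_offset: int | None = None

    def __post_init__(self) -> None:
        if (self.next_birth_offset is not None
                and self.next_birth_offset not in self.years_monitored_after):
            raise ValidationError(
                f"bear {self.bear_id} birth {self.birth_year}: next-birth offset "
                f"{self.next_birth_offset} not among monitored offsets")


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_ENCOUNTER_COLS = ["bear_id", "population", "birth_year", "year",
                   "interval", "status", "cause"]
_LITTER_COLS = ["mother_id", "population", "year", "cubs_emergence",
                "cubs_survived", "monitored_to_autumn"]
_YEARLING_COLS = ["mother_id", "population", "year", "yearlings",
                  "yearlings_survived", "monitored"]
_STATE_COLS = ["bear_id", "population", "year", "state", "age"]
_PRIMI_COLS = ["bear_id", "population", "age", "first_litter"]
_INTERBIRTH_COLS = ["bear_id", "population", "birth_year", "offset", "litter"]


def _require(df: pd.DataFrame, cols: Sequence[str], path: object) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def read_encounters(path: str | Path) -> list[EncounterHistory]:
    df = pd.read_csv(path)
    _require(df, _ENCOUNTER_COLS[:6], path)
    if "cause" not in df.columns:
        df["cause"] = None
    if "segment" not in df.columns:
        df["segment"] = 0
    out: list[EncounterHistory] = []
    for (bid, seg), grp in df.groupby(["bear_id", "segment"], sort=True):
        grp = grp.sort_values(["year", "interval"])
        pops = grp["population"].unique()
        if len(pops) != 1:
            raise ValidationError(f"bear {bid}: inconsistent population labels {pops}")
        recs = [IntervalRecord(int(r.year), int(r.interval), str(r.status),
                               None if pd.isna(r.cause) or r.cause == "NA"
                               else str(r.cause))
                for r in grp.itertuples()]
        out.append(EncounterHistory(str(bid), str(pops[0]),
                                    int(grp["birth_year"].iloc[0]), recs,
                                    segment=int(seg)))
    return out


def write_encounters(histories: Iterable[EncounterHistory], path: str | Path) -> None:
    rows = []
    for h in histories:
        for r in h.records:
            rows.append((h.bear_id, h.population, h.birth_year, r.year,
                         r.interval, r.status, r.cause if r.cause else "NA",
                         h.segment))
    pd.DataFrame(rows, columns=_ENCOUNTER_COLS + ["segment"]).to_csv(path, index=False)


def read_litters(path: str | Path) -> list[LitterRecord]:
    df = pd.read_csv(path)
    _require(df, _LITTER_COLS, path)
    return [LitterRecord(str(r.mother_id), str(r.population), int(r.year),
                         int(r.cubs_emergence), int(r.cubs_survived),
                         bool(r.monitored_to_autumn))
            for r in df.itertuples()]


def write_litters(litters: Iterable[LitterRecord], path: str | Path) -> None:
    rows = [(l.mother_id, l.population, l.year, l.n_cubs_emergence,
             l.n_cubs_survived, int(l.monitored_to_autumn)) for l in litters]
    pd.DataFrame(rows, columns=_LITTER_COLS).to_csv(path, index=False)


def read_yearlings(path: str | Path) -> list[YearlingRecord]:
    df = pd.read_csv(path)
    _require(df, _YEARLING_COLS, path)
    return [YearlingRecord(str(r.mother_id), str(r.population), int(r.year),
                           int(r.yearlings), int(r.yearlings_survived),
                           bool(r.monitored))
            for r in df.itertuples()]


def write_yearlings(records: Iterable[YearlingRecord], path: str | Path) -> None:
    rows = [(r.mother_id, r.population, r.year, r.n_yearlings, r.n_survived,
             int(r.monitored)) for r in records]
    pd.DataFrame(rows, columns=_YEARLING_COLS).to_csv(path, index=False)


def read_states(path: str | Path) -> list[StateSequence]:
    df = pd.read_csv(path)
    _require(df, _STATE_COLS, path)
    out = []
    for bid, grp in df.groupby("bear_id", sort=True):
        grp = grp.sort_values("year")
        obs = [StateObservation(int(r.year), str(r.state), int(r.age))
               for r in grp.itertuples()]
        out.append(StateSequence(str(bid), str(grp["population"].iloc[0]), obs))
    return out


def write_states(sequences: Iterable[StateSequence], path: str | Path) -> None:
    rows = [(s.bear_id, s.population, o.year, o.state, o.age)
            for s in sequences for o in s.states]
    pd.DataFrame(rows, columns=_STATE_COLS).to_csv(path, index=False)


def read_primiparity(path: str | Path) -> list[NulliparityHistory]:
    """Long format: one row per monitored age; ``first_litter`` = 1 on the event row."""
    df = pd.read_csv(path)
    _require(df, _PRIMI_COLS, path)
    out = []
    for bid, grp in df.groupby("bear_id", sort=True):
        events = grp.loc[grp["first_litter"] == 1, "age"]
        event = int(events.min()) if len(events) else None
        nullip = frozenset(int(a) for a in grp.loc[grp["first_litter"] == 0, "age"]
                           if event is None or a < event)
        out.append(NulliparityHistory(str(bid), str(grp["population"].iloc[0]),
                                      nullip, event))
    return out


def write_primiparity(histories: Iterable[NulliparityHistory],
                      path: str | Path) -> None:
    rows = []
    for h in histories:
        for a in sorted(h.ages_monitored_nulliparous):
            rows.append((h.bear_id, h.population, a, 0))
        if h.age_first_litter is not None:
            rows.append((h.bear_id, h.population, h.age_first_litter, 1))
    pd.DataFrame(rows, columns=_PRIMI_COLS).to_csv(path, index=False)


def read_interbirth(path: str | Path) -> list[InterbirthHistory]:
    df = pd.read_csv(path)
    _require(df, _INTERBIRTH_COLS, path)
    out = []
    for (bid, by), grp in df.groupby(["bear_id", "birth_year"], sort=True):
        offsets = frozenset(int(t) for t in grp["offset"])
        events = grp.loc[grp["litter"] == 1, "offset"]
        event = int(events.min()) if len(events) else None
        out.append(InterbirthHistory(str(bid), str(grp["population"].iloc[0]),
                                     int(by), offsets, event))
    return out


def write_interbirth(histories: Iterable[InterbirthHistory],
                     path: str | Path) -> None:
    rows = []
    for h in histories:
        for t in sorted(h.years_monitored_after):
            rows.append((h.bear_id, h.population, h.birth_year, t,
                         int(t == h.next_birth_offset)))
    pd.DataFrame(rows, columns=_INTERBIRTH_COLS).to_csv(path, index=False)


def read_monitoring_tables(paths: Mapping[str, str | Path]) -> dict[str, list]:
    """Read any subset of the monitoring tables.

    ``paths`` maps table names (``encounters``, ``litters``, ``yearlings``,
    ``states``, ``primiparity``, ``interbirth``) to file locations.
    """
    readers = {"encounters": read_encounters, "litters": read_litters,
               "yearlings": read_yearlings, "states": read_states,
               "primiparity": read_primiparity, "interbirth": read_interbirth}
    unknown = set(paths) - set(readers)
    if unknown:
        raise SchemaError(f"unknown table name(s) {sorted(unknown)}")
    return {name: readers[name](p) for name, p in paths.items()}


# ---------------------------------------------------------------------------
# Exposure and crude mortality
# ---------------------------------------------------------------------------

def _filter_pop(histories: Sequence[EncounterHistory],
                population: str | None) -> list[EncounterHistory]:
    if population is None:
        return list(histories)
    sel = [h for h in histories if h.population == population]
    if not sel:
        known = sorted({h.population for h in histories})
        raise ValidationError(
            f"unknown population {population!r}; present: {known}")
    return sel


def bear_years(histories: Sequence[EncounterHistory],
               population: str | None = None) -> float:
    """Cumulative monitored exposure in bear-years (8 intervals = 1 year)."""
    sel = _filter_pop(histories, population)
    return sum(h.n_monitored_intervals for h in sel) / INTERVALS_PER_YEAR


def mortality_rate(histories: Sequence[EncounterHistory],
                   population: str | None = None,
                   cause_filter: Iterable[str] | None = None) -> float:
    """Deaths per bear-year of monitoring, optionally restricted by cause.

    ``cause_filter=None`` counts every death; otherwise only deaths whose
    recorded cause is in the filter set are counted (the exposure in the
    denominator is unchanged).
    """
    sel = _filter_pop(histories, population)
    exposure = bear_years(sel)
    if exposure == 0:
        raise ValidationError("mortality rate undefined: zero bear-years")
    causes = None if cause_filter is None else set(cause_filter)
    deaths = 0
    for h in sel:
        for r in h.records:
            if r.status == "dead" and (causes is None or r.cause in causes):
                deaths += 1
    return deaths / exposure
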