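"""Staggered-entry Kaplan-Meier and known-fate survival models.

Collared females enter the risk set at capture and leave at death or
censoring (staggered entry).  Because fates are known in every monitored
interval, each bear-interval is a Bernoulli survival trial and the
known-fate likelihood is a product of interval-survival terms: an interval
survived contributes ``s``, a death contributes ``1 - s``, and a censored
interval contributes nothing.  Candidate models are cell-mean models on
the interval-survival scale:

* ``S(~1)``   - one common interval survival;
* ``S(~Pop)`` - one cell per population;
* ``S(~Age)`` - one cell per age class (subadult 2-5 / adult 6+).

Annual survival is the interval estimate raised to the 8th power: the
monitoring year is seven monthly intervals April..October plus one pooled
denning interval, and the constant-hazard models treat the pooled winter
interval as a single interval exactly as the data are coded (monthly
mortality is not distinguishable while bears den).

Model comparison uses AICc with effective sample size equal to the number
of bear-intervals in the likelihood, and Akaike-weight model averaging of
all models within a ``delta`` threshold of the best model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2, norm

from .data import INTERVALS_PER_YEAR, AgeClassRule, EncounterHistory, ValidationError

_CHI2_95 = float(chi2.ppf(0.95, df=1))

MODEL_ALIASES = {
    "null": "S(~1)", "1": "S(~1)", "s(~1)": "S(~1)",
    "pop": "S(~Pop)", "population": "S(~Pop)", "s(~pop)": "S(~Pop)",
    "age": "S(~Age)", "s(~age)": "S(~Age)",
}


def canonical_model_name(name: str) -> str:
    key = name.strip().lower()
    if key in MODEL_ALIASES:
        return MODEL_ALIASES[key]
    if name in ("S(~1)", "S(~Pop)", "S(~Age)"):
        return name
    raise ValueError(f"unknown known-fate model {name!r}")


def _record_group(history: EncounterHistory, year: int, grouping: str,
                  age_rule: AgeClassRule) -> str:
    if grouping == "none":
        return "all"
    if grouping == "population":
        return history.population
    if grouping == "age":
        return age_rule.age_class(history.age_in(year))
    raise ValueError(f"unknown grouping {grouping!r}")


def build_risk_table(histories: Sequence[EncounterHistory],
                     grouping: str = "none",
                     age_rule: AgeClassRule = AgeClassRule()) -> pd.DataFrame:
    """Tally at-risk / death / censor counts per (group, interval-of-year).

    Years are pooled on the 8-interval annual cycle: a bear contributes to
    ``n_at_risk`` in every interval it carries a record (it was known alive
    at interval start), deaths and censors fall in their recorded interval.
    """
    counts: dict[tuple[str, int], list[int]] = {}
    for h in histories:
        for r in h.records:
            g = _record_group(h, r.year, grouping, age_rule)
            cell = counts.setdefault((g, r.interval), [0, 0, 0])
            cell[0] += 1
            if r.status == "dead":
                cell[1] += 1
            elif r.status == "censored":
                cell[2] += 1
    rows = [(g, i, *c) for (g, i), c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["group", "interval", "n_at_risk",
                                       "n_deaths", "n_censored"])


@dataclass
class SurvivalEstimate:
    group: str
    annual_s: float
    ci_low: float
    ci_high: float
    method: str
    n_intervals: int = 0
    n_deaths: int = 0
    interval_table: pd.DataFrame | None = field(default=None, repr=False)


def _zero_death_lower(n_intervals: int) -> float:
    """Profile-likelihood lower bound on interval survival with 0 deaths."""
    if n_intervals == 0:
        return 0.0
    return math.exp(-_CHI2_95 / (2 * n_intervals))


def kaplan_meier(risk: pd.DataFrame) -> dict[str, SurvivalEstimate]:
    """Product-limit annual survival per group from a pooled-cycle risk table.

    Interval survival is ``1 - d_t / n_t`` (deaths counted before censors);
    annual survival multiplies the interval estimates over the 8-interval
    cycle.  The CI uses Greenwood's variance on the log-survival scale;
    with zero deaths the estimate sits on the boundary and an asymmetric
    profile-likelihood interval (lower, 1.00) is reported instead.
    """
    if risk.empty:
        raise ValidationError("empty risk table")
    out: dict[str, SurvivalEstimate] = {}
    for g, grp in risk.groupby("group"):
        s_annual = 1.0
        greenwood = 0.0
        n_tot = int(grp["n_at_risk"].sum())
        d_tot = int(grp["n_deaths"].sum())
        detail = grp.copy()
        detail["s_hat"] = np.nan
        for idx, row in grp.iterrows():
            n, d = int(row["n_at_risk"]), int(row["n_deaths"])
            if n == 0:
                warnings.warn(f"group {g}: interval {row['interval']} has no "
                              "bears at risk; skipped")
                continue
            s_t = 1.0 - d / n
            detail.loc[idx, "s_hat"] = s_t
            s_annual *= s_t
            if d > 0 and d < n:
                greenwood += d / (n * (n - d))
        if d_tot == 0:
            lo = _zero_death_lower(n_tot) ** INTERVALS_PER_YEAR
            hi = 1.0
        elif s_annual == 0.0:
            lo, hi = 0.0, 0.0
        else:
            z = norm.ppf(0.975)
            se_log = math.sqrt(greenwood)
            lo = s_annual * math.exp(-z * se_log)
            hi = min(1.0, s_annual * math.exp(z * se_log))
        out[str(g)] = SurvivalEstimate(str(g), s_annual, lo, hi, "KM",
                                       n_tot, d_tot, interval_table=detail)
    return out


@dataclass
class CellFit:
    n: int                 # bear-intervals in the likelihood
    deaths: int
    s_interval: float      # MLE of per-interval survival
    annual_s: float
    ci_low: float          # annual scale
    ci_high: float


@dataclass
class KnownFateModel:
    name: str
    cells: dict[str, CellFit]
    group_map: dict[tuple[str, str], str]  # (population, age class) -> cell
    loglik: float
    k: int
    n_eff: int
    aicc: float
    fingerprint: tuple = ()

    def annual_survival(self, population: str, age_class: str) -> CellFit:
        return self.cells[self.group_map[(population, age_class)]]


def _binom_loglik(a: int, d: int, s: float) -> float:
    ll = 0.0
    if a:
        ll += a * math.log(s)
    if d:
        ll += d * math.log(1.0 - s)
    return ll


def _profile_ci_interval(a: int, d: int) -> tuple[float, float]:
    """95% profile-likelihood CI for binomial interval survival a/(a+d)."""
    n = a + d
    if n == 0:
        return (0.0, 1.0)
    s_hat = a / n
    ll_hat = _binom_loglik(a, d, s_hat) if 0 < s_hat < 1 else (
        0.0 if s_hat in (0.0, 1.0) else _binom_loglik(a, d, s_hat))

    def dev(s: float) -> float:
        return 2.0 * (ll_hat - _binom_loglik(a, d, s)) - _CHI2_95

    if d == 0:
        return (_zero_death_lower(n), 1.0)
    if a == 0:
        return (0.0, 1.0 - _zero_death_lower(n))
    lo = brentq(dev, 1e-12, s_hat - 1e-12)
    hi = brentq(dev, s_hat + 1e-12, 1.0 - 1e-12)
    return (float(lo), float(hi))


def fit_known_fate(histories: Sequence[EncounterHistory], model_name: str,
                   age_rule: AgeClassRule = AgeClassRule()) -> KnownFateModel:
    """Fit one cell-mean known-fate model by exact (closed-form) MLE.

    The cell MLE of interval survival is the binomial proportion
    survived/trials; censored records are excluded from the likelihood
    beyond their last alive interval.  AICc uses bear-intervals as the
    effective sample size.
    """
    name = canonical_model_name(model_name)
    grouping = {"S(~1)": "none", "S(~Pop)": "population", "S(~Age)": "age"}[name]
    trials: dict[str, list[int]] = {}   # cell -> [alive, dead]
    group_map: dict[tuple[str, str], str] = {}
    for h in histories:
        for r in h.records:
            if r.status == "censored":
                continue
            cell = _record_group(h, r.year, grouping, age_rule)
            ac = age_rule.age_class(h.age_in(r.year))
            group_map[(h.population, ac)] = {
                "none": "all", "population": h.population, "age": ac}[grouping]
            t = trials.setdefault(cell, [0, 0])
            if r.status == "dead":
                t[1] += 1
            else:
                t[0] += 1
    if not trials:
        raise ValidationError("no bear-intervals available to fit")
    cells: dict[str, CellFit] = {}
    loglik = 0.0
    n_eff = 0
    for cell, (a, d) in sorted(trials.items()):
        n = a + d
        s = a / n
        lo_i, hi_i = _profile_ci_interval(a, d)
        cells[cell] = CellFit(n, d, s, s ** INTERVALS_PER_YEAR,
                              lo_i ** INTERVALS_PER_YEAR,
                              hi_i ** INTERVALS_PER_YEAR)
        loglik += _binom_loglik(a, d, s) if 0.0 < s < 1.0 else 0.0
        n_eff += n
    k = len(cells)
    denom = n_eff - k - 1
    aicc = -2.0 * loglik + 2 * k + (2 * k * (k + 1) / denom if denom > 0
                                    else math.inf)
    total_deaths = sum(t[1] for t in trials.values())
    return KnownFateModel(name, cells, group_map, loglik, k, n_eff, aicc,
                          fingerprint=(n_eff, total_deaths))


def aicc_table(models: Sequence[KnownFateModel]) -> pd.DataFrame:
    """Rank models by AICc with delta and Akaike weights."""
    if len(models) < 2:
        raise ValidationError("need at least two models to rank")
    if len({m.fingerprint for m in models}) != 1:
        raise ValidationError("models were fit on differing data")
    df = pd.DataFrame({"model": [m.name for m in models],
                       "k": [m.k for m in models],
                       "loglik": [m.loglik for m in models],
                       "AICc": [m.aicc for m in models]})
    df = df.sort_values("AICc", kind="stable").reset_index(drop=True)
    df["delta"] = df["AICc"] - df["AICc"].iloc[0]
    rel = np.exp(-0.5 * df["delta"].to_numpy())
    df["weight"] = rel / rel.sum()
    return df


def model_average(models: Sequence[KnownFateModel],
                  threshold: float = 2.0) -> dict[tuple[str, str], SurvivalEstimate]:
    """Akaike-weight average of annual survival over models within ``threshold``.

    Returns one estimate per (population, age class) group present in the
    data.  With a single qualifying model this reduces to that model's own
    estimates.  CI bounds are averaged with the same weights (an
    approximation adequate for the near-degenerate weight sets seen here).
    """
    table = aicc_table(models)
    by_name = {m.name: m for m in models}
    qual = table[table["delta"] < threshold]
    weights = qual["weight"].to_numpy()
    weights = weights / weights.sum()
    chosen = [by_name[n] for n in qual["model"]]
    groups: set[tuple[str, str]] = set()
    for m in chosen:
        groups.update(m.group_map)
    out: dict[tuple[str, str], SurvivalEstimate] = {}
    for g in sorted(groups):
        s = lo = hi = 0.0
        n_int = n_d = 0
        for w, m in zip(weights, chosen):
            cf = m.annual_survival(*g)
            s += w * cf.annual_s
            lo += w * cf.ci_low
            hi += w * cf.ci_high
            n_int, n_d = cf.n, cf.deaths
        out[g] = SurvivalEstimate("/".join(g), s, lo, hi, "model-averaged",
                                  n_int, n_d)
    return out
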