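"""Bootstrap cub and yearling survival from litter observations.

Cub survival is the proportion of cubs counted at den emergence that are
still with their mother at the next denning season, over litters whose
mothers were monitored through autumn.  Uncertainty is a nonparametric
bootstrap (default B = 1000, percentile 95% CI) resampling either
individual cubs (default - justified when the litter-independence ANOVA
finds no within-litter clustering of fates) or whole litters (sensitivity
option preserving within-litter dependence).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.stats import f_oneway

from .bootstrap import BootstrapDistribution
from .data import LitterRecord, ValidationError, YearlingRecord


def _monitored(litters: Sequence[LitterRecord],
               population: str | None) -> list[LitterRecord]:
    sel = [l for l in litters
           if (population is None or l.population == population)
           and l.monitored_to_autumn]
    return sel


def _brood_bootstrap(statistic: str, broods: list[tuple[int, int]],
                     B: int, resample_unit: str,
                     rng: np.random.Generator) -> BootstrapDistribution:
    """Bootstrap survival of (n, survived) broods by individual or by brood."""
    total = sum(n for n, _ in broods)
    if total == 0:
        raise ValidationError(f"{statistic}: zero monitored offspring")
    survived = sum(s for _, s in broods)
    point = survived / total
    if resample_unit == "cub":
        fates = np.repeat(
            np.concatenate([np.r_[np.ones(s), np.zeros(n - s)]
                            for n, s in broods]), 1)
        idx = rng.integers(0, fates.size, size=(B, fates.size))
        reps = fates[idx].mean(axis=1)
    elif resample_unit == "litter":
        arr = np.asarray(broods, dtype=float)
        idx = rng.integers(0, len(broods), size=(B, len(broods)))
        tot = arr[idx, 0].sum(axis=1)
        reps = np.where(tot > 0, arr[idx, 1].sum(axis=1) / np.maximum(tot, 1), np.nan)
    else:
        raise ValueError(f"unknown resample unit {resample_unit!r}")
    no_deaths = survived == total
    return BootstrapDistribution.from_replicates(
        statistic, point, reps, variance_defined=not no_deaths)


def cub_survival(litters: Sequence[LitterRecord],
                 population: str | None = None, B: int = 1000,
                 resample_unit: str = "cub",
                 seed: int | np.random.Generator | None = None
                 ) -> BootstrapDistribution:
    """First-year cub survival with bootstrap CI over monitored litters."""
    sel = _monitored(litters, population)
    if not sel:
        raise ValidationError("no monitored litters")
    rng = np.random.default_rng(seed)
    broods = [(l.n_cubs_emergence, l.n_cubs_survived) for l in sel]
    return _brood_bootstrap("cub_survival", broods, B, resample_unit, rng)


def yearling_survival(records: Sequence[YearlingRecord],
                      population: str | None = None, B: int = 1000,
                      resample_unit: str = "cub",
                      seed: int | np.random.Generator | None = None
                      ) -> BootstrapDistribution:
    """Yearling survival, same estimator as cubs on yearling fate records.

    With zero observed mortalities the point is 1.0 and
    ``variance_defined`` is False (a degenerate bootstrap distribution).
    """
    sel = [r for r in records
           if (population is None or r.population == population) and r.monitored]
    if not sel:
        raise ValidationError("no monitored yearling records")
    rng = np.random.default_rng(seed)
    broods = [(r.n_yearlings, r.n_survived) for r in sel]
    return _brood_bootstrap("yearling_survival", broods, B, resample_unit, rng)


def litter_independence_test(litters: Sequence[LitterRecord],
                             population: str | None = None
                             ) -> tuple[float, float]:
    """One-way ANOVA of per-cub binary fate grouped by litter.

    A large p-value supports treating cub fates as independent of litter
    membership and hence resampling at the cub level.  Requires at least
    two monitored litters with two or more cubs.
    """
    sel = _monitored(litters, population)
    groups = [np.r_[np.ones(l.n_cubs_survived),
                    np.zeros(l.n_cubs_emergence - l.n_cubs_survived)]
              for l in sel if l.n_cubs_emergence >= 1]
    multi = [g for g in groups if g.size >= 2]
    if len(multi) < 2:
        raise ValidationError(
            "litter independence test needs >=2 litters with >=2 cubs")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # no fate variation at all: litters trivially alike
    stat = f_oneway(*[g for g in groups if g.size >= 1])
    return float(stat.statistic), float(stat.pvalue)
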