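"""Leslie-matrix assembly, growth rate, and stable structure.

The projection model has 25 age classes (ages 0..24, with reproduction
ending at 24).  Annual survival sits on the subdiagonal:

    P_0 = S_cub, P_1 = S_yearling, P_2..P_5 = S_subadult,
    P_6..P_23 = S_adult,

and the fecundity row carries the per-adult-female reproductive rate m
(female cubs / female / year) for ages 6..24.  By default fecundities are
placed without a survival discount, giving the characteristic (Euler-
Lotka) equation

    sum_x lambda^-(x+1) l(x) m(x) = 1,      l(0) = 1, l(x) = prod P_i.

A pre-breeding alternative (F = S_cub * m) is available behind the
``convention`` flag for sensitivity analysis.

The stable stage structure (cub / yearling / subadult / adult) is computed
two ways and cross-checked: by aggregating the age eigenvector over stage
bins, and by collapsing the age model into a 4-stage matrix with the
conditional age-group transition rate

    P_{j,i} = lambda^-(x_j - x_i - 1) l(x_j - 1)
              / sum_{x = x_i}^{x_j - 1} lambda^-(x - x_i) l(x),

which preserves the growth rate and stable structure exactly when the
population is at its stable age distribution.

Uncertainty propagates by Monte Carlo: each iteration draws one replicate
per vital rate from its bootstrap distribution (independent draws), builds
the matrix and records lambda, R0 and generation time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .bootstrap import BootstrapDistribution
from .data import AgeClassRule

N_AGE_CLASSES = 25
_STAGE_BINS = ((0, 1), (1, 2), (2, 6), (6, 25))  # cub, yearling, subadult, adult
STAGE_NAMES = ("cub", "yearling", "subadult", "adult")


@dataclass(frozen=True)
class VitalRateSet:
    """Annual age-class survival plus the adult reproductive rate."""

    s_cub: float
    s_yearling: float
    s_subadult: float
    s_adult: float
    m_adult: float  # female cubs / adult female / year, ages 6..24
    age_rule: AgeClassRule = AgeClassRule()

    def __post_init__(self) -> None:
        for name in ("s_cub", "s_yearling", "s_subadult", "s_adult"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.m_adult < 0:
            raise ValueError("m_adult must be nonnegative")

    @property
    def subdiagonal(self) -> np.ndarray:
        return np.array([self.s_cub, self.s_yearling]
                        + [self.s_subadult] * 4 + [self.s_adult] * 18)


def build_leslie(v: VitalRateSet, convention: str = "postbreeding") -> np.ndarray:
    """Assemble the 25x25 Leslie matrix from a vital-rate set."""
    L = np.zeros((N_AGE_CLASSES, N_AGE_CLASSES))
    sub = v.subdiagonal
    L[np.arange(1, N_AGE_CLASSES), np.arange(N_AGE_CLASSES - 1)] = sub
    lo, hi = v.age_rule.adult_min, v.age_rule.last_reproductive_age
    if convention == "postbreeding":
        L[0, lo:hi + 1] = v.m_adult
    elif convention == "prebreeding":
        L[0, lo:hi + 1] = v.s_cub * v.m_adult
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return L


def extract_vital_rates(L: np.ndarray,
                        age_rule: AgeClassRule = AgeClassRule()) -> VitalRateSet:
    """Inverse of :func:`build_leslie` (post-breeding convention)."""
    sub = L[np.arange(1, N_AGE_CLASSES), np.arange(N_AGE_CLASSES - 1)]
    return VitalRateSet(sub[0], sub[1], sub[2], sub[6],
                        float(L[0, age_rule.adult_min]), age_rule)


def survivorship(L: np.ndarray) -> np.ndarray:
    """l(x): probability of surviving from birth to age x, x = 0..24."""
    sub = L[np.arange(1, N_AGE_CLASSES), np.arange(N_AGE_CLASSES - 1)]
    return np.concatenate([[1.0], np.cumprod(sub)])


@dataclass
class SurvivorshipSchedule:
    l: np.ndarray
    growth_rate: float


def growth_rate(L: np.ndarray) -> float:
    """Dominant eigenvalue of the projection matrix (finite growth rate)."""
    if np.all(L[0] == 0):
        warnings.warn("zero fecundity row: matrix is reducible; the dominant "
                      "eigenvalue is degenerate")
    vals = np.linalg.eigvals(L)
    return float(np.max(vals.real[np.abs(vals.imag) < 1e-9]))


def euler_lotka_rate(L: np.ndarray) -> float:
    """Growth rate as the bisection root of the Euler-Lotka equation.

    Independent of the eigensolver: solves
    sum_x lambda^-(x+1) l(x) F(x) = 1 for the convention implied by the
    matrix's own fecundity row.
    """
    l = survivorship(L)
    F = L[0]
    if F.sum() == 0:
        raise ValueError("Euler-Lotka root undefined with zero fecundity")

    def f(lam: float) -> float:
        x = np.arange(N_AGE_CLASSES)
        return float(np.sum(lam ** (-(x + 1.0)) * l * F) - 1.0)

    return float(brentq(f, 1e-3, 20.0, xtol=1e-12))


def net_reproductive_rate(L: np.ndarray) -> float:
    """R0: expected lifetime female offspring per female, sum_x l(x) F(x)."""
    return float(np.sum(survivorship(L) * L[0]))


def generation_time(L: np.ndarray, lam: float | None = None,
                    r0: float | None = None) -> float:
    """Generation time ln(R0)/ln(lambda), with the lambda -> 1 limit.

    At lambda = 1 the ratio degenerates to the mean age of offspring
    production, sum (x+1) l F / sum l F (offspring are censused one step
    after the parental age class).
    """
    lam = growth_rate(L) if lam is None else lam
    r0 = net_reproductive_rate(L) if r0 is None else r0
    if r0 <= 0:
        return float("nan")
    if abs(lam - 1.0) < 1e-9:
        l = survivorship(L)
        F = L[0]
        x = np.arange(N_AGE_CLASSES)
        return float(np.sum((x + 1) * l * F) / np.sum(l * F))
    return float(np.log(r0) / np.log(lam))


def stage_transition_rate(x_i: int, x_j: int,
                          schedule: SurvivorshipSchedule) -> float:
    """Conditional probability of advancing from stage [x_i, x_j) to the next.

    Collapses consecutive age classes into one stage under the stable age
    distribution implied by ``schedule.growth_rate``.
    """
    if not 0 <= x_i < x_j <= N_AGE_CLASSES:
        raise ValueError(f"invalid stage bounds [{x_i}, {x_j})")
    lam = schedule.growth_rate
    if lam <= 0:
        raise ValueError("growth rate must be positive")
    l = schedule.l
    if np.any(l[x_i:x_j] <= 0):
        raise ValueError(f"zero survivorship inside stage [{x_i}, {x_j})")
    num = lam ** (-(x_j - x_i - 1)) * l[x_j - 1]
    ages = np.arange(x_i, x_j)
    den = np.sum(lam ** (-(ages - x_i).astype(float)) * l[ages])
    return float(num / den)


def stable_age_distribution(L: np.ndarray) -> np.ndarray:
    """Normalized dominant right eigenvector: proportions by age 0..24."""
    vals, vecs = np.linalg.eig(L)
    i = int(np.argmax(np.where(np.abs(vals.imag) < 1e-9, vals.real, -np.inf)))
    w = np.abs(np.real(vecs[:, i]))
    return w / w.sum()


def build_stage_matrix(v: VitalRateSet, lam: float,
                       convention: str = "postbreeding") -> np.ndarray:
    """4-stage projection matrix collapsed with the conditional rates."""
    L = build_leslie(v, convention)
    sched = SurvivorshipSchedule(survivorship(L), lam)
    surv = (v.s_cub, v.s_yearling, v.s_subadult, v.s_adult)
    A = np.zeros((4, 4))
    for i, (x_i, x_j) in enumerate(_STAGE_BINS):
        g = stage_transition_rate(x_i, x_j, sched)
        A[i, i] = surv[i] * (1.0 - g)
        if i < 3:
            A[i + 1, i] = surv[i] * g
    A[0, 3] += L[0, v.age_rule.adult_min]
    return A


def stable_stage_distribution(v: VitalRateSet, lam: float | None = None,
                              convention: str = "postbreeding",
                              atol: float = 1e-6
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Stable stage proportions (cub, yearling, subadult, adult), two ways.

    Returns ``(from_stage_model, from_age_aggregation)`` and raises if the
    two disagree beyond ``atol`` - they are equal in exact arithmetic, so a
    mismatch signals an assembly bug.
    """
    L = build_leslie(v, convention)
    lam = growth_rate(L) if lam is None else lam
    w = stable_age_distribution(L)
    agg = np.array([w[a:b].sum() for a, b in _STAGE_BINS])
    A = build_stage_matrix(v, lam, convention)
    vals, vecs = np.linalg.eig(A)
    i = int(np.argmax(np.where(np.abs(vals.imag) < 1e-9, vals.real, -np.inf)))
    stage = np.abs(np.real(vecs[:, i]))
    stage = stage / stage.sum()
    if np.max(np.abs(stage - agg)) > atol:
        raise AssertionError(
            f"stage-model eigenvector {stage} disagrees with aggregated age "
            f"eigenvector {agg}")
    return stage, agg


@dataclass
class ProjectionSummary:
    lam: float
    lam_ci: tuple[float, float]
    r0: float
    r0_ci: tuple[float, float]
    gen_t: float
    gen_t_ci: tuple[float, float]
    stable_age: np.ndarray
    stable_stage: np.ndarray
    n_iter: int
    n_rejected: int
    replicates: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def monte_carlo_projection(distributions: Mapping[str, BootstrapDistribution | float],
                           n_iter: int = 1000,
                           seed: int | np.random.Generator | None = None,
                           convention: str = "postbreeding",
                           age_rule: AgeClassRule = AgeClassRule()
                           ) -> ProjectionSummary:
    """Propagate vital-rate uncertainty through the Leslie matrix.

    ``distributions`` maps the keys ``s_cub``, ``s_yearling``,
    ``s_subadult``, ``s_adult``, ``m_adult`` to bootstrap distributions
    (or degenerate scalars).  Each iteration draws one replicate per rate
    independently; draws outside [0, 1] for survival rates are rejected
    and redrawn (tallied).  Percentile CIs at 2.5/97.5.
    """
    rng = np.random.default_rng(seed)
    keys = ("s_cub", "s_yearling", "s_subadult", "s_adult", "m_adult")
    missing = [k for k in keys if k not in distributions]
    if missing:
        raise ValueError(f"missing vital-rate distribution(s) {missing}")

    def draw(key: str) -> float:
        d = distributions[key]
        if isinstance(d, BootstrapDistribution):
            return float(d.replicates[rng.integers(0, d.replicates.size)])
        return float(d)

    lams = np.empty(n_iter)
    r0s = np.empty(n_iter)
    gents = np.empty(n_iter)
    ages = np.zeros(N_AGE_CLASSES)
    stages = np.zeros(4)
    n_struct = 0
    rejected = 0
    it = 0
    while it < n_iter:
        vals = {k: draw(k) for k in keys}
        if any(not 0.0 <= vals[k] <= 1.0 for k in keys[:4]) or vals["m_adult"] < 0:
            rejected += 1
            continue
        v = VitalRateSet(**vals, age_rule=age_rule)
        L = build_leslie(v, convention)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lam = growth_rate(L)
        lams[it] = lam
        r0s[it] = net_reproductive_rate(L)
        gents[it] = generation_time(L, lam, r0s[it])
        if lam > 0:  # degenerate zero-fecundity draws carry no stable structure
            ages += stable_age_distribution(L)
            stages += stable_stage_distribution(v, lam, convention)[1]
            n_struct += 1
        it += 1

    def ci(a: np.ndarray) -> tuple[float, float]:
        good = a[np.isfinite(a)]
        lo, hi = np.percentile(good, [2.5, 97.5])
        return (float(lo), float(hi))

    return ProjectionSummary(
        lam=float(lams.mean()), lam_ci=ci(lams),
        r0=float(r0s.mean()), r0_ci=ci(r0s),
        gen_t=float(np.nanmean(gents)), gen_t_ci=ci(gents),
        stable_age=ages / max(n_struct, 1),
        stable_stage=stages / max(n_struct, 1),
        n_iter=n_iter, n_rejected=rejected,
        replicates={"lambda": lams, "R0": r0s, "GenT": gents})
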