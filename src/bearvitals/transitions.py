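"""Reproductive-state transition matrix and its stationary distribution.

An adult female (age >= 6) is observed each spring in one of four
reproductive states: alone (A), with cubs (C), with yearlings (Y), or with
two-year-old-or-older dependents (T).  Between consecutive monitored years
only ten transitions are biologically possible:

    A -> A, A -> C,
    C -> A, C -> C, C -> Y,
    Y -> A, Y -> C, Y -> T,
    T -> A, T -> C.

Survival and detection are prerequisites for observing a transition, so
their probabilities are fixed at 1 and the transition matrix is the
multinomial MLE per originating state: count(s -> s') / count(s -> .).

The stationary reproductive-state distribution is obtained by iterating
pi <- pi T from the all-Alone start vector (1, 0, 0, 0) until the L1
change falls below tolerance; it equals the leading left eigenvector of T,
which :func:`stationary_eigen` computes independently as a cross-check.
For a periodic (deterministic-cycle) chain the pointwise iteration
oscillates; the running Cesaro average still converges to the unique
stationary vector and is returned with ``periodic=True``.

Uncertainty comes from resampling females (each with her full transition
set) with replacement, re-estimating T and recomputing the stationary
distribution per replicate (percentile CIs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import STATES, StateSequence, ValidationError

_IDX = {s: i for i, s in enumerate(STATES)}

PERMITTED_TRANSITIONS = frozenset({
    ("A", "A"), ("A", "C"),
    ("C", "A"), ("C", "C"), ("C", "Y"),
    ("Y", "A"), ("Y", "C"), ("Y", "T"),
    ("T", "A"), ("T", "C"),
})

_PERMITTED_MASK = np.zeros((4, 4), dtype=bool)
for _a, _b in PERMITTED_TRANSITIONS:
    _PERMITTED_MASK[_IDX[_a], _IDX[_b]] = True


class ConvergenceError(RuntimeError):
    pass


@dataclass
class TransitionMatrix:
    """Row-stochastic 4x4 reproductive-state transition matrix.

    ``counts`` holds the observed tallies behind each entry (zero for
    matrices populated directly from probabilities).  Rows whose
    originating state was never observed are inestimable (NaN) and listed
    in ``inestimable_rows``.
    """

    probs: np.ndarray
    counts: np.ndarray = field(default_factory=lambda: np.zeros((4, 4), dtype=int))

    @property
    def inestimable_rows(self) -> list[str]:
        return [STATES[i] for i in range(4) if np.isnan(self.probs[i]).any()]

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "TransitionMatrix":
        counts = np.asarray(counts, dtype=int)
        if counts[~_PERMITTED_MASK].any():
            bad = [(STATES[i], STATES[j])
                   for i, j in zip(*np.nonzero(counts * ~_PERMITTED_MASK))]
            raise ValidationError(f"impossible transition(s) observed: {bad}")
        probs = np.full((4, 4), np.nan)
        totals = counts.sum(axis=1)
        for i in range(4):
            if totals[i] > 0:
                probs[i] = counts[i] / totals[i]
        return cls(probs, counts)

    @classmethod
    def from_probabilities(cls, probs: np.ndarray,
                           atol: float = 0.02) -> "TransitionMatrix":
        """Build from (possibly rounded) published probabilities.

        Rows must sum to 1 within ``atol`` (printed 2-dp entries can be off
        by a cent or two) and are renormalized exactly.
        """
        probs = np.asarray(probs, dtype=float)
        if probs[~_PERMITTED_MASK].any():
            raise ValidationError("nonzero probability on a structurally "
                                  "impossible transition")
        sums = probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > atol):
            raise ValidationError(f"row sums {sums} deviate from 1 beyond {atol}")
        return cls(probs / sums[:, None])


def estimate_transitions(sequences: Sequence[StateSequence],
                         adult_min: int = 6) -> TransitionMatrix:
    """Multinomial MLE of the transition matrix from annual state sequences.

    Only transitions originating in an adult year (age >= ``adult_min``)
    with the destination observed the immediately following year are
    counted.
    """
    counts = np.zeros((4, 4), dtype=int)
    for seq in sequences:
        for a, b in zip(seq.states, seq.states[1:]):
            if b.year != a.year + 1 or a.age < adult_min:
                continue
            if (a.state, b.state) not in PERMITTED_TRANSITIONS:
                raise ValidationError(
                    f"bear {seq.bear_id}: impossible transition "
                    f"{a.state}->{b.state} in {a.year}->{b.year}")
            counts[_IDX[a.state], _IDX[b.state]] += 1
    if counts.sum() == 0:
        raise ValidationError("no adult consecutive-year transitions observed")
    return TransitionMatrix.from_counts(counts)


@dataclass
class StableStateDistribution:
    pi: np.ndarray                      # stationary proportions over (A, C, Y, T)
    iterations_to_converge: int
    periodic: bool = False
    replicates: np.ndarray | None = field(default=None, repr=False)
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    n_redrawn: int = 0

    def __getitem__(self, state: str) -> float:
        return float(self.pi[_IDX[state]])


def stable_state(tm: TransitionMatrix,
                 start: Sequence[float] = (1.0, 0.0, 0.0, 0.0),
                 tol: float = 1e-12,
                 max_iter: int = 100_000) -> StableStateDistribution:
    """Iterate the Markov chain from ``start`` to its stationary distribution."""
    T = np.asarray(tm.probs, dtype=float)
    if np.isnan(T).any():
        raise ValidationError(
            f"inestimable row(s) {tm.inestimable_rows}: cannot iterate")
    pi = np.asarray(start, dtype=float)
    if pi.shape != (4,) or pi.sum() <= 0:
        raise ValueError("start must be a nonnegative 4-vector with positive sum")
    pi = pi / pi.sum()
    history = [pi.copy()]
    for it in range(1, max_iter + 1):
        nxt = pi @ T
        if np.abs(nxt - pi).sum() < tol:
            return StableStateDistribution(nxt / nxt.sum(), it)
        # periodic chain: the iterate revisits an earlier point exactly; the
        # cycle average is then the stationary distribution (Cesaro limit)
        for period in range(2, min(len(history), 8) + 1):
            if np.abs(nxt - history[-period]).sum() < tol:
                cyc = np.mean(history[-period:], axis=0)
                if np.abs(cyc @ T - cyc).sum() < 1e-9:
                    return StableStateDistribution(cyc / cyc.sum(), it,
                                                   periodic=True)
        history.append(nxt.copy())
        if len(history) > 8:
            history.pop(0)
        pi = nxt
    raise ConvergenceError(
        f"no convergence in {max_iter} iterations (last iterate {pi})")


def stationary_eigen(tm: TransitionMatrix) -> np.ndarray:
    """Stationary distribution as the leading left eigenvector (closed form)."""
    T = np.asarray(tm.probs, dtype=float)
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, i])
    v = np.abs(v)
    return v / v.sum()


def reproductive_rate(litter_size: float, pi_C: float,
                      female_fraction: float = 0.5) -> float:
    """Mean reproductive rate m_x = female cubs / adult female / year.

    The product of mean litter size, the stationary proportion of adult
    females with cubs, and the assumed female fraction of cubs (1/2 when
    cub sex is undetermined).
    """
    if not (0.0 <= pi_C <= 1.0 and 0.0 <= female_fraction <= 1.0
            and litter_size >= 0.0):
        raise ValueError("inputs out of range")
    return female_fraction * litter_size * pi_C


def bootstrap_stable_state(sequences: Sequence[StateSequence],
                           B: int = 1000, adult_min: int = 6,
                           seed: int | np.random.Generator | None = None,
                           max_redraws: int = 100_000
                           ) -> StableStateDistribution:
    """Female-level bootstrap of the stationary state distribution.

    Each replicate resamples females with replacement, pools their
    transitions, re-estimates the matrix and recomputes the stationary
    distribution.  Replicates in which an observed originating state has
    no transitions (inestimable row) are redrawn; the redraw count is
    reported.
    """
    point = stable_state(estimate_transitions(sequences, adult_min))
    rng = np.random.default_rng(seed)
    females = list(sequences)
    reps = np.empty((B, 4))
    redrawn = 0
    b = 0
    attempts = 0
    while b < B:
        attempts += 1
        if attempts > B + max_redraws:
            raise ConvergenceError("too many inestimable bootstrap replicates")
        idx = rng.integers(0, len(females), size=len(females))
        sample = [females[i] for i in idx]
        try:
            tm = estimate_transitions(sample, adult_min)
            reps[b] = stable_state(tm).pi
        except (ValidationError, ConvergenceError):
            redrawn += 1
            continue
        b += 1
    lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
    return StableStateDistribution(point.pi, point.iterations_to_converge,
                                   periodic=point.periodic, replicates=reps,
                                   ci_low=lo, ci_high=hi, n_redrawn=redrawn)
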