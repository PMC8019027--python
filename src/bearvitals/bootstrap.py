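"""Shared nonparametric-bootstrap summary container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BootstrapDistribution:
    """Point estimate plus percentile bootstrap replicates of one statistic.

    ``point`` is always the plug-in estimate on the original sample, never
    the replicate mean; the 95% interval is the 2.5/97.5 percentile of the
    replicates.  ``variance_defined`` is False when the data admit no
    spread (e.g. survival with zero observed deaths).
    """

    statistic: str
    point: float
    replicates: np.ndarray = field(repr=False)
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    variance_defined: bool = True

    @classmethod
    def from_replicates(cls, statistic: str, point: float,
                        replicates: np.ndarray,
                        variance_defined: bool = True) -> "BootstrapDistribution":
        reps = np.asarray(replicates, dtype=float)
        lo, hi = np.percentile(reps, [2.5, 97.5]) if reps.size else (np.nan, np.nan)
        return cls(statistic=statistic, point=float(point), replicates=reps,
                   ci_low=float(lo), ci_high=float(hi),
                   variance_defined=variance_defined)

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))
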