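"""Small-sample statistics for phenotypic assays and drive-cross rates.

Covers the exact binomial mate-choice test, the one-sample t-test for the
heterozygous-offspring viability fraction, and the algebra converting
pooled drive-cross offspring counts into inheritance, drive-conversion and
embryo resistance rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AssayCounts",
    "CrossCounts",
    "proportion_with_binomial_test",
    "one_sample_t",
    "drive_rates",
]


@dataclass(frozen=True)
class AssayCounts:
    """Successes out of trials in a binary assay (e.g. mate choice)."""

    successes: int
    trials: int

    def __post_init__(self) -> None:
        if self.trials < 1 or not (0 <= self.successes <= self.trials):
            raise ValueError("need 0 <= successes <= trials, trials >= 1")


@dataclass(frozen=True)
class CrossCounts:
    """Pooled offspring phenotype counts from drive-heterozygote crosses.

    Classes are combinations of the DsRed (drive) and functional-EGFP
    (intact target) markers.
    """

    n_dsred_egfp: int = 0
    n_dsred_only: int = 0
    n_egfp_only: int = 0
    n_neither: int = 0

    def __post_init__(self) -> None:
        if min(self.n_dsred_egfp, self.n_dsred_only,
               self.n_egfp_only, self.n_neither) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return (self.n_dsred_egfp + self.n_dsred_only
                + self.n_egfp_only + self.n_neither)

    def __add__(self, other: "CrossCounts") -> "CrossCounts":
        return CrossCounts(
            self.n_dsred_egfp + other.n_dsred_egfp,
            self.n_dsred_only + other.n_dsred_only,
            self.n_egfp_only + other.n_egfp_only,
            self.n_neither + other.n_neither,
        )


def proportion_with_binomial_test(
    successes: int, trials: int, p0: float = 0.5
) -> tuple[float, float]:
    """Observed proportion and two-sided exact binomial p-value.

    The two-sided p-value follows the small-mass convention: the sum of the
    probabilities of all outcomes no more probable than the observed one
    (with a 1 + 1e-7 relative tolerance against floating-point ties), the
    convention of standard statistical environments.
    """
    AssayCounts(successes, trials)
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    p = float(stats.binomtest(successes, trials, p0).pvalue)
    return successes / trials, min(p, 1.0)


def one_sample_t(
    values: Sequence[float], mu0: float
) -> dict[str, float | bool]:
    """One-sample t-test of the mean against ``mu0``.

    Returns mean, sd, t, df and the two-sided p-value; a zero-variance
    sample is flagged degenerate instead of raising.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    out = {"mean": mean, "sd": sd, "df": float(x.size - 1), "degenerate": False}
    if sd == 0.0:
        out.update(t=math.nan, p=math.nan, degenerate=True)
        return out
    t, p = stats.ttest_1samp(x, mu0)
    out.update(t=float(t), p=float(p))
    return out


def drive_rates(
    crosses: Sequence[CrossCounts], pooled: bool = True
) -> dict[str, float]:
    """Inheritance, drive-conversion and embryo-resistance rates.

    For crosses of drive/EGFP heterozygotes to EGFP homozygotes: the
    inheritance rate i is the DsRed fraction among offspring, the drive
    conversion rate is ``c = 2 i - 1`` (expected drive transmission is
    ``(1 + c) / 2``), and the embryo resistance rate is the fraction of
    DsRed-positive offspring whose paternally inherited EGFP allele lost
    function.  Binomial standard errors accompany each rate.  Counts are
    pooled over crosses (``pooled=False`` is reserved for batch-aware
    analyses and is not implemented here).
    """
    if not pooled:
        raise NotImplementedError("only the pooled analysis is implemented")
    total = CrossCounts()
    for c in crosses:
        total = total + c
    if total.total == 0:
        raise ValueError("zero offspring")
    n = total.total
    n_dsred = total.n_dsred_egfp + total.n_dsred_only
    i = n_dsred / n
    conv = 2.0 * i - 1.0
    out = {
        "inheritance": i,
        "inheritance_se": math.sqrt(i * (1 - i) / n),
        "conversion": conv,
        "conversion_se": 2.0 * math.sqrt(i * (1 - i) / n),
        "n_offspring": float(n),
    }
    if n_dsred > 0:
        er = total.n_dsred_only / n_dsred
        out["embryo_resistance"] = er
        out["embryo_resistance_se"] = math.sqrt(er * (1 - er) / n_dsred)
    else:
        out["embryo_resistance"] = math.nan
        out["embryo_resistance_se"] = math.nan
    return out
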