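"""Two-sample summaries, t-statistics, standardized effect size, and TOST.

The package works on the standardized effect size
``delta = (mu1 - mu2) / sigma`` of a two-group normal model.  All Bayes
factor machinery downstream consumes the pooled (Student) t-statistic,
its degrees of freedom ``nu = n1 + n2 - 2`` and the effective sample size
``n_delta = n1 * n2 / (n1 + n2)``, which together are sufficient for
inference on delta under a common error variance.  Welch's statistic is
provided for description and for the frequentist TOST, which does not
assume equal variances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidDataError, ScaleMismatchError

__all__ = [
    "TwoSampleSummary",
    "TTestResult",
    "EquivalenceRegion",
    "TostResult",
    "summarize",
    "pooled_t",
    "welch_t",
    "cohen_delta",
    "tost",
    "read_two_group_csv",
]


@dataclass(frozen=True)
class TwoSampleSummary:
    """Sufficient statistics of two independent normal samples."""

    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise InvalidDataError("each group needs at least 2 observations")
        if not (self.sd1 > 0 and self.sd2 > 0):
            raise InvalidDataError("group standard deviations must be > 0")
        for name in ("mean1", "mean2", "sd1", "sd2"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidDataError(f"{name} is not finite")


@dataclass(frozen=True)
class TTestResult:
    """A two-sample t-statistic with its degrees of freedom.

    ``effective_n`` is n1*n2/(n1+n2), the factor that maps delta onto the
    noncentrality parameter of the t-distribution: t | delta follows a
    noncentral t with ``df`` degrees of freedom and noncentrality
    sqrt(effective_n)*delta.
    """

    t: float
    df: float
    effective_n: float
    p_two_sided: float
    kind: str  # "pooled" | "welch"


@dataclass(frozen=True)
class EquivalenceRegion:
    """An interval null hypothesis [lower, upper].

    ``scale`` is ``"standardized_effect"`` when the bounds live on the
    delta scale (the Bayesian tests) and ``"raw_difference"`` when they
    bound the raw mean difference (the frequentist TOST).
    """

    lower: float
    upper: float
    scale: str = "standardized_effect"

    def __post_init__(self):
        if not self.lower < self.upper:
            raise InvalidDataError(
                f"region must have lower < upper, got [{self.lower}, {self.upper}]"
            )
        if self.scale not in ("standardized_effect", "raw_difference"):
            raise InvalidDataError(f"unknown region scale {self.scale!r}")

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class TostResult:
    """Decision record of the two-one-sided-tests procedure."""

    p_lower: float
    p_upper: float
    significant_lower: bool
    significant_upper: bool
    equivalence_established: bool


def summarize(group1: Sequence[float], group2: Sequence[float]) -> TwoSampleSummary:
    """Compute per-group counts, sample means and sample SDs (ddof=1)."""
    out = []
    for label, g in (("group1", group1), ("group2", group2)):
        arr = np.asarray(g, dtype=float)
        if arr.ndim != 1:
            raise InvalidDataError(f"{label} must be one-dimensional")
        if arr.size < 2:
            raise InvalidDataError(f"{label} needs at least 2 values")
        if not np.all(np.isfinite(arr)):
            raise InvalidDataError(f"{label} contains non-finite values")
        out.append((arr.size, arr.mean(), arr.std(ddof=1)))
    (n1, m1, s1), (n2, m2, s2) = out
    return TwoSampleSummary(n1=n1, n2=n2, mean1=m1, mean2=m2, sd1=s1, sd2=s2)


def _effective_n(n1: int, n2: int) -> float:
    return n1 * n2 / (n1 + n2)


def pooled_t(s: TwoSampleSummary) -> TTestResult:
    """Student's two-sample t-statistic under a common error variance."""
    df = s.n1 + s.n2 - 2
    sp2 = ((s.n1 - 1) * s.sd1**2 + (s.n2 - 1) * s.sd2**2) / df
    se = np.sqrt(sp2 * (1 / s.n1 + 1 / s.n2))
    t = (s.mean1 - s.mean2) / se
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(t=t, df=float(df), effective_n=_effective_n(s.n1, s.n2),
                       p_two_sided=p, kind="pooled")


def welch_t(s: TwoSampleSummary) -> TTestResult:
    """Welch's t-statistic with Welch-Satterthwaite degrees of freedom."""
    v1 = s.sd1**2 / s.n1
    v2 = s.sd2**2 / s.n2
    t = (s.mean1 - s.mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (s.n1 - 1) + v2**2 / (s.n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(t=t, df=df, effective_n=_effective_n(s.n1, s.n2),
                       p_two_sided=p, kind="welch")


def cohen_delta(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Standardized effect size (mean1-mean2)/sqrt((sd1^2+sd2^2)/2)."""
    if not (sd1 > 0 and sd2 > 0):
        raise InvalidDataError("standard deviations must be > 0")
    return (mean1 - mean2) / np.sqrt((sd1**2 + sd2**2) / 2)


def tost(s: TwoSampleSummary, region: EquivalenceRegion, alpha: float = 0.05) -> TostResult:
    """Frequentist two one-sided tests for equivalence of two means.

    Tests H0: theta < lower or theta > upper against
    H1: lower <= theta <= upper, where theta = mu1 - mu2 on the raw scale,
    via two one-sided Welch tests.  Equivalence is established iff both
    one-sided p-values fall strictly below ``alpha``.
    """
    if region.scale != "raw_difference":
        raise ScaleMismatchError(
            "tost needs a region on the raw mean-difference scale"
        )
    if not 0 < alpha < 1:
        raise InvalidDataError("alpha must lie in (0, 1)")
    v1 = s.sd1**2 / s.n1
    v2 = s.sd2**2 / s.n2
    se = np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (s.n1 - 1) + v2**2 / (s.n2 - 1))
    diff = s.mean1 - s.mean2
    # lower test: H01 theta < lower, rejected for large (diff - lower)/se
    t_lower = (diff - region.lower) / se
    p_lower = stats.t.sf(t_lower, df)
    # upper test: H02 theta > upper, rejected for small (diff - upper)/se
    t_upper = (diff - region.upper) / se
    p_upper = stats.t.cdf(t_upper, df)
    sig_lower = p_lower < alpha
    sig_upper = p_upper < alpha
    return TostResult(
        p_lower=p_lower,
        p_upper=p_upper,
        significant_lower=bool(sig_lower),
        significant_upper=bool(sig_upper),
        equivalence_established=bool(sig_lower and sig_upper),
    )


def read_two_group_csv(
    path,
    col1: str | None = None,
    col2: str | None = None,
    value_col: str | None = None,
    group_col: str | None = None,
) -> TwoSampleSummary:
    """Read two-group data from a CSV file and summarize it.

    Two layouts are supported: wide (one numeric column per group, named by
    ``col1``/``col2``) or long (a ``value_col`` plus a two-level
    ``group_col``).  Decimal separator is always '.'.
    """
    df = pd.read_csv(path)
    if col1 is not None and col2 is not None:
        for c in (col1, col2):
            if c not in df.columns:
                raise InvalidDataError(f"column {c!r} not found in {path}")
        g1 = df[col1].dropna().to_numpy(dtype=float)
        g2 = df[col2].dropna().to_numpy(dtype=float)
    elif value_col is not None and group_col is not None:
        for c in (value_col, group_col):
            if c not in df.columns:
                raise InvalidDataError(f"column {c!r} not found in {path}")
        levels = sorted(df[group_col].dropna().unique().tolist())
        if len(levels) != 2:
            raise InvalidDataError(
                f"group column {group_col!r} must have exactly 2 levels, got {levels}"
            )
        g1 = df.loc[df[group_col] == levels[0], value_col].dropna().to_numpy(dtype=float)
        g2 = df.loc[df[group_col] == levels[1], value_col].dropna().to_numpy(dtype=float)
    else:
        raise InvalidDataError(
            "specify either col1/col2 (wide layout) or value_col/group_col (long layout)"
        )
    return summarize(g1, g2)
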