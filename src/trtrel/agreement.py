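"""Scalar test-retest agreement: ICC(A,1) and Bland-Altman analysis.

The intraclass correlation used throughout is the single-measurement,
absolute-agreement, two-way model (McGraw & Wong's ICC(A,1), what SPSS
labels "two-way mixed, absolute agreement, single measures"):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

with MSR, MSC, MSE the row (subject), column (session) and error mean
squares of the two-way crossed ANOVA, n subjects and k sessions.  The 95%
confidence interval uses the F-distribution construction with a
Satterthwaite approximation for the denominator degrees of freedom, and the
significance test against ICC = 0 is the one-sided F = MSR/MSE test on
(n-1, (n-1)(k-1)) degrees of freedom.

Bland-Altman analysis summarises paired sessions by the mean and SD of the
per-subject differences; the limits of agreement default to the mean
difference +/- 2 SD.  Limits of agreement describe the spread of individual
differences and are distinct from a confidence interval of the mean
difference; this module reports the former and names it so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricTable",
    "ICCResult",
    "BlandAltmanResult",
    "anova_mean_squares",
    "icc_a1",
    "icc_confidence_interval",
    "icc_significance",
    "classify_icc",
    "bland_altman",
]

#: reliability bins: excellent >= 0.75, good [0.60, 0.75), fair [0.40, 0.60), poor < 0.40
ICC_BINS = ((0.75, "excellent"), (0.60, "good"), (0.40, "fair"))


@dataclass
class MetricTable:
    """Subjects x sessions measurements of one scalar metric for one bundle.

    ``values`` is an n x k grid with NaN marking missing cells; analyses use
    only complete rows (subjects measured in every session), mirroring
    pairwise-complete handling of subjects whose bundle could not be
    reconstructed.
    """

    values: np.ndarray
    bundle: str = ""
    metric: str = ""
    subject_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("values must be an n x k grid")
        if self.values.shape[1] < 2:
            raise ValueError("need at least k = 2 sessions")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i+1:02d}" for i in range(self.values.shape[0])]
        if np.any(np.isinf(self.values)):
            raise ValueError("values must be finite or NaN (missing)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @property
    def complete_mask(self) -> np.ndarray:
        return ~np.any(np.isnan(self.values), axis=1)

    @property
    def n_complete(self) -> int:
        return int(self.complete_mask.sum())

    def complete_values(self) -> np.ndarray:
        return self.values[self.complete_mask]


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    msr: float
    msc: float
    mse: float
    n: int
    k: int
    category: str


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    fraction_within: float
    n_outside: int
    good_agreement: bool
    pair_means: np.ndarray
    pair_diffs: np.ndarray
    multiplier: float = 2.0


def _complete(t: MetricTable, min_n: int = 3) -> np.ndarray:
    x = t.complete_values()
    if x.shape[0] < min_n:
        raise ValueError(
            f"need at least {min_n} complete subjects, got {x.shape[0]}")
    return x


def anova_mean_squares(t: MetricTable) -> tuple[float, float, float]:
    """Two-way crossed ANOVA mean squares (rows = subjects, columns = sessions).

    Returns ``(MSR, MSC, MSE)``.  The error sum of squares is the total minus
    row and column components; tiny negative round-off is clamped to zero.
    """
    x = _complete(t)
    n, k = x.shape
    grand = x.mean()
    ssr = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ssc = n * np.sum((x.mean(axis=0) - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    # snap round-off residue to exact zero so degenerate tables (identical
    # sessions, perfect agreement) are recognized as such downstream
    tol = 1e-12 * sst
    if ssc <= tol:
        ssc = 0.0
    if sse <= tol:
        sse = 0.0
    return (float(ssr / (n - 1)), float(ssc / (k - 1)),
            float(sse / ((n - 1) * (k - 1))))


def icc_a1(t: MetricTable, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1) with confidence interval, significance and reliability category."""
    x = _complete(t)
    n, k = x.shape
    msr, msc, mse = anova_mean_squares(t)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("ICC undefined: all cells identical (zero total variance)")
    est = float((msr - mse) / denom)
    lo, hi = icc_confidence_interval(t, alpha=alpha)
    p = icc_significance(t)
    return ICCResult(icc=est, ci_low=lo, ci_high=hi, p_value=p,
                     msr=msr, msc=msc, mse=mse, n=n, k=k,
                     category=classify_icc(est))


def icc_point_estimate(t: MetricTable) -> float:
    """ICC(A,1) point estimate only (no interval or test)."""
    x = _complete(t)
    n, k = x.shape
    msr, msc, mse = anova_mean_squares(t)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("ICC undefined: all cells identical (zero total variance)")
    return float((msr - mse) / denom)


def icc_confidence_interval(t: MetricTable, alpha: float = 0.05
                            ) -> tuple[float, float]:
    """Two-sided (1 - alpha) interval for ICC(A,1).

    Uses the F-based construction with Satterthwaite-approximated
    denominator degrees of freedom (the interval SPSS reports for two-way
    absolute-agreement single measures).  Degenerate tables with no session
    or error variance return [1, 1] with a warning.
    """
    x = _complete(t)
    n, k = x.shape
    msr, msc, mse = anova_mean_squares(t)
    if mse == 0 and msc == 0:
        warnings.warn("no within-subject variance: degenerate CI [1, 1]")
        return (1.0, 1.0)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("ICC undefined: zero total variance")
    r = (msr - mse) / denom
    # Satterthwaite df for the linear combination a*MSC + b*MSE
    a = k * r / (n * (1.0 - r)) if r != 1.0 else np.inf
    b = 1.0 + k * r * (n - 1) / (n * (1.0 - r)) if r != 1.0 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        warnings.warn("ICC estimate at 1: degenerate CI [1, 1]")
        return (1.0, 1.0)
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else (n - 1) * (k - 1)
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (n * (msr - f_u * mse)
             / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr))
    upper = (n * (f_l * msr - mse)
             / (k * msc + (k * n - k - n) * mse + n * f_l * msr))
    return (float(lower), float(upper))


def icc_significance(t: MetricTable) -> float:
    """One-sided p-value of F = MSR/MSE against ICC = 0."""
    x = _complete(t)
    n, k = x.shape
    msr, _, mse = anova_mean_squares(t)
    if mse == 0:
        warnings.warn("zero error mean square: p-value reported as 0")
        return 0.0
    return float(stats.f.sf(msr / mse, n - 1, (n - 1) * (k - 1)))


def classify_icc(icc: float) -> str:
    """Four-level reliability category for an ICC estimate.

    Half-open bins: excellent >= 0.75, good [0.60, 0.75), fair [0.40, 0.60),
    poor < 0.40 (negative estimates are poor).
    """
    if icc > 1:
        raise ValueError(f"ICC estimate {icc} exceeds 1")
    for cutoff, label in ICC_BINS:
        if icc >= cutoff:
            return label
    return "poor"


def bland_altman(t: MetricTable, multiplier: float = 2.0,
                 coverage_rule: float = 0.95) -> BlandAltmanResult:
    """Bland-Altman agreement of the two sessions of a metric table.

    Differences are session 1 minus session 2.  Limits of agreement are
    ``mean_diff +/- multiplier * sd_diff`` with the sample SD (n-1
    denominator).  ``good_agreement`` is True when at least ``coverage_rule``
    of the subjects fall inside the limits; the integer count outside is
    also reported, since with small n the attainable fractions are coarse.
    """
    if t.k != 2:
        raise ValueError("Bland-Altman analysis requires exactly 2 sessions")
    x = _complete(t)
    diffs = x[:, 0] - x[:, 1]
    means = x.mean(axis=1)
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    lo = mean_diff - multiplier * sd_diff
    hi = mean_diff + multiplier * sd_diff
    inside = (diffs >= lo) & (diffs <= hi)
    frac = float(inside.mean())
    return BlandAltmanResult(
        mean_diff=mean_diff, sd_diff=sd_diff, loa_low=float(lo),
        loa_high=float(hi), fraction_within=frac,
        n_outside=int((~inside).sum()),
        good_agreement=frac >= coverage_rule,
        pair_means=means, pair_diffs=diffs, multiplier=multiplier)


def metric_table_from_long(df: pd.DataFrame, bundle: str, metric: str,
                           session_labels=None) -> MetricTable:
    """Build a MetricTable from a long-form frame with columns
    subject, session, bundle, metric, value."""
    sub = df[(df["bundle"] == bundle) & (df["metric"] == metric)]
    if session_labels is None:
        session_labels = sorted(sub["session"].unique())
    subjects = sorted(sub["subject"].unique())
    wide = sub.pivot(index="subject", columns="session", values="value")
    wide = wide.reindex(index=subjects, columns=session_labels)
    return MetricTable(values=wide.to_numpy(), bundle=bundle, metric=metric,
                       subject_ids=list(wide.index))
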