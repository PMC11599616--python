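"""Single-measurement intraclass correlation coefficients.

Consistency and agreement of two (or more) measurement methods applied to the
same participants are quantified with the single-measurement ICCs from the
two-way crossed ANOVA decomposition (rows = participants, columns = methods,
one observation per cell):

* consistency, ICC(C,1) — insensitive to additive per-method offsets; asks
  whether the methods rank and space participants similarly;
* agreement, ICC(A,1) — additionally penalizes systematic between-method
  differences in level.

Definitions and F-based confidence intervals follow the McGraw & Wong (1996)
two-way conventions for single measurements; the agreement interval uses their
Satterthwaite-approximated denominator degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateRatingsError, InsufficientDataError

__all__ = [
    "MeanSquares",
    "ICCEstimate",
    "anova_decompose",
    "icc_consistency",
    "icc_agreement",
    "categorize",
    "pairwise_consistency",
]

logger = logging.getLogger(__name__)

#: Qualitative bands for single-measurement ICCs (Cicchetti & Sparrow).
CATEGORY_EDGES = ((0.4, "poor"), (0.6, "fair"), (0.75, "good"))


@dataclass(frozen=True)
class MeanSquares:
    """Two-way crossed ANOVA mean squares for an n×k ratings matrix."""

    ms_rows: float  # between-participant, df n-1
    ms_cols: float  # between-method, df k-1
    ms_err: float  # residual, df (n-1)(k-1)
    n: int
    k: int


@dataclass(frozen=True)
class ICCEstimate:
    """A single-measurement ICC with its F-based confidence interval."""

    value: float
    ci_low: float
    ci_high: float
    variant: str  # "agreement" | "consistency"
    category: str
    n: int
    k: int


def _as_ratings(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise InsufficientDataError("ratings must be a 2-D participants × methods array")
    n, k = arr.shape
    if n < 2 or k < 2:
        raise InsufficientDataError(
            f"insufficient data: need at least 2 rows and 2 columns, got {n}×{k}"
        )
    if np.isnan(arr).any():
        raise InsufficientDataError("ratings contain missing values; drop incomplete rows first")
    return arr


def anova_decompose(ratings) -> MeanSquares:
    """Two-way crossed ANOVA mean squares (participants × methods, one obs per cell)."""
    arr = _as_ratings(ratings)
    n, k = arr.shape
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    resid = arr - row_means[:, None] - col_means[None, :] + grand
    ss_err = float(np.sum(resid**2))
    return MeanSquares(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_err=ss_err / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def categorize(value: float) -> str:
    """Map an ICC value to its qualitative band.

    Bands are half-open: <0.4 poor, [0.4, 0.6) fair, [0.6, 0.75) good,
    ≥0.75 excellent. Negative estimates fall in "poor".
    """
    if value > 1:
        raise ValueError(f"ICC cannot exceed 1, got {value}")
    for edge, name in CATEGORY_EDGES:
        if value < edge:
            return name
    return "excellent"


def icc_consistency(ratings, conf: float = 0.95) -> ICCEstimate:
    """Single-measurement consistency ICC(C,1) with an F-based CI.

    ICC(C,1) = (MSR − MSE) / (MSR + (k−1)·MSE).  The interval transforms
    F-distribution bounds on F = MSR/MSE with (n−1, (n−1)(k−1)) df.
    """
    ms = anova_decompose(ratings)
    n, k = ms.n, ms.k
    denom = ms.ms_rows + (k - 1) * ms.ms_err
    if denom <= 0:
        raise DegenerateRatingsError("degenerate ratings: no variance in the matrix")
    value = (ms.ms_rows - ms.ms_err) / denom
    alpha = 1.0 - conf
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if ms.ms_err == 0.0:
        lo = hi = 1.0
    else:
        fobs = ms.ms_rows / ms.ms_err
        fl = fobs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = fobs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    return ICCEstimate(value, lo, hi, "consistency", categorize(value), n, k)


def icc_agreement(ratings, conf: float = 0.95) -> ICCEstimate:
    """Single-measurement agreement ICC(A,1) with an F-based CI.

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)).
    The CI uses the McGraw & Wong construction: with
      a = k·icc / (n·(1−icc)),  b = 1 + k·icc·(n−1) / (n·(1−icc)),
    the denominator df is Satterthwaite-approximated as
      v = (a·MSC + b·MSE)² / ((a·MSC)²/(k−1) + (b·MSE)²/((n−1)(k−1)))
    and the bounds are
      lower = n·(MSR − F₁·MSE) / (F₁·(k·MSC + (kn−k−n)·MSE) + n·MSR),
        F₁ = F(1−α/2; n−1, v)
      upper = n·(F₂·MSR − MSE) / (k·MSC + (kn−k−n)·MSE + n·F₂·MSR),
        F₂ = F(1−α/2; v, n−1).
    """
    ms = anova_decompose(ratings)
    n, k = ms.n, ms.k
    denom = ms.ms_rows + (k - 1) * ms.ms_err + (k / n) * (ms.ms_cols - ms.ms_err)
    if denom <= 0:
        raise DegenerateRatingsError("degenerate ratings: no variance in the matrix")
    value = (ms.ms_rows - ms.ms_err) / denom
    alpha = 1.0 - conf
    if ms.ms_err == 0.0 and ms.ms_cols == 0.0:
        lo = hi = 1.0
    else:
        icc_ = value
        if icc_ >= 1.0:  # guard the a/b ratios; interval collapses
            lo = hi = 1.0
        else:
            a = (k * icc_) / (n * (1 - icc_))
            b = 1 + (k * icc_ * (n - 1)) / (n * (1 - icc_))
            num_v = (a * ms.ms_cols + b * ms.ms_err) ** 2
            den_v = (a * ms.ms_cols) ** 2 / (k - 1) + (b * ms.ms_err) ** 2 / (
                (n - 1) * (k - 1)
            )
            v = num_v / den_v if den_v > 0 else 1.0
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (
                n
                * (ms.ms_rows - f1 * ms.ms_err)
                / (f1 * (k * ms.ms_cols + (k * n - k - n) * ms.ms_err) + n * ms.ms_rows)
            )
            hi = (
                n
                * (f2 * ms.ms_rows - ms.ms_err)
                / (k * ms.ms_cols + (k * n - k - n) * ms.ms_err + n * f2 * ms.ms_rows)
            )
    return ICCEstimate(value, lo, hi, "agreement", categorize(value), n, k)


def pairwise_consistency(
    cohort: pd.DataFrame,
    region: str,
    columns: list[tuple[str, str]],
    conf: float = 0.95,
) -> pd.DataFrame:
    """All pairwise consistency ICCs among (method, hemisphere) channels of a region.

    Rows with missing values in any requested column are dropped (complete
    cases) and the number dropped is logged. Returns one row per unordered
    pair, with labels `<method>_<hemisphere>_<region>`.
    """
    names = []
    for method, hemisphere in columns:
        col = f"{method}_{hemisphere}_{region}"
        if col not in cohort.columns:
            raise KeyError(f"unknown region/method/hemisphere column: {col!r}")
        names.append(col)
    sub = cohort[names]
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    if n_dropped:
        logger.info("pairwise_consistency(%s): dropped %d incomplete rows", region, n_dropped)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            est = icc_consistency(complete[[names[i], names[j]]].to_numpy(), conf=conf)
            rows.append(
                {
                    "region": region,
                    "column_a": names[i],
                    "column_b": names[j],
                    "variant": est.variant,
                    "value": est.value,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "category": est.category,
                    "n_used": est.n,
                }
            )
    return pd.DataFrame(rows)
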