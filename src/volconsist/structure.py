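"""Method-vs-method structural comparisons.

Orthogonal (Deming / total least squares) regression for scatter of one
method's volumes against the other's, proportional differences as a scale-free
disagreement index, paired method × hemisphere contrasts on standardized
volumes, and linear confound residualization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import HEMISPHERES, volume_column
from .errors import InsufficientDataError, VolconsistError

__all__ = [
    "OrthoFit",
    "ContrastResult",
    "orthogonal_fit",
    "proportional_difference",
    "size_variability_summary",
    "hemisphere_method_contrast",
    "residualize",
]


@dataclass(frozen=True)
class OrthoFit:
    """Orthogonal-regression line minimizing perpendicular distances."""

    slope: float
    intercept: float


@dataclass(frozen=True)
class ContrastResult:
    label: str
    estimate: float  # standardized units
    p_value: float


def orthogonal_fit(x, y, variance_ratio: float = 1.0) -> OrthoFit:
    """Deming regression of y on x with error-variance ratio δ = var(e_y)/var(e_x).

    At δ = 1 (the default) this is classic total least squares: the slope is
    the direction of the leading eigenvector of the 2×2 sample covariance, and
    the line passes through the means. Unlike ordinary least squares it is not
    attenuated when both variables carry comparable error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise VolconsistError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise InsufficientDataError("orthogonal fit needs at least 3 points")
    sxx = x.var(ddof=1)
    syy = y.var(ddof=1)
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxx == 0 and syy == 0:
        raise VolconsistError("degenerate input: all points identical")
    d = variance_ratio
    if sxy == 0.0:
        if syy > d * sxx:
            raise VolconsistError("orthogonal fit is vertical (infinite slope)")
        slope = 0.0
    else:
        slope = (syy - d * sxx + np.sqrt((syy - d * sxx) ** 2 + 4 * d * sxy**2)) / (2 * sxy)
    intercept = float(y.mean() - slope * x.mean())
    return OrthoFit(slope=float(slope), intercept=intercept)


def proportional_difference(v1, v2) -> np.ndarray:
    """Elementwise (v1 − v2) / ((v1 + v2)/2): difference as a share of the average."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    s = v1 + v2
    if (s <= 0).any():
        raise VolconsistError("proportional difference undefined for non-positive pair sums")
    return (v1 - v2) / (s / 2.0)


def size_variability_summary(
    cohort: pd.DataFrame,
    regions: list[str],
    methods: tuple[str, str] = ("fsl", "freesurfer"),
) -> pd.DataFrame:
    """Per region: mean cross-method average volume and SD of the proportional
    difference (hemispheres pooled), sorted by mean volume ascending.

    The mechanism of interest: under comparable absolute disagreement, smaller
    structures show larger proportional variability.
    """
    if not regions:
        raise VolconsistError("at least one region required")
    rows = []
    for region in regions:
        avgs, pds = [], []
        for hemisphere in HEMISPHERES:
            c1 = volume_column(methods[0], hemisphere, region)
            c2 = volume_column(methods[1], hemisphere, region)
            if c1 not in cohort.columns or c2 not in cohort.columns:
                continue
            v1 = cohort[c1].to_numpy()
            v2 = cohort[c2].to_numpy()
            avgs.append((v1 + v2) / 2.0)
            pds.append(proportional_difference(v1, v2))
        if not avgs:
            raise KeyError(f"no volume columns found for region {region!r}")
        avg = np.concatenate(avgs)
        pd_all = np.concatenate(pds)
        rows.append(
            {
                "region": region,
                "mean_volume": float(avg.mean()),
                "sd_proportional_difference": float(pd_all.std(ddof=1)),
            }
        )
    out = pd.DataFrame(rows).sort_values("mean_volume", ignore_index=True)
    return out


def hemisphere_method_contrast(
    cohort: pd.DataFrame,
    region: str,
    methods: tuple[str, str] = ("fsl", "freesurfer"),
) -> list[ContrastResult]:
    """Left–right contrasts per method and their interaction, standardized.

    The four (method, hemisphere) columns of the region are standardized
    against the pooled four-column mean and SD (per-column standardization
    would erase the very mean differences under test). Each contrast is the
    mean per-participant difference with a paired t-test: left−right within
    each method, and the interaction (left−right, method 1) − (left−right,
    method 2) as a paired test on the double difference.
    """
    cols = {
        (m, h): volume_column(m, h, region) for m in methods for h in HEMISPHERES
    }
    for col in cols.values():
        if col not in cohort.columns:
            raise KeyError(f"missing column {col!r} for region {region!r}")
    sub = cohort[list(cols.values())].dropna()
    if len(sub) < 2:
        raise InsufficientDataError("paired contrasts need at least 2 participants")
    pooled = sub.to_numpy()
    mu, sd = pooled.mean(), pooled.std(ddof=1)
    if sd == 0:
        raise VolconsistError("degenerate region: zero pooled variance")
    z = {key: (sub[col].to_numpy() - mu) / sd for key, col in cols.items()}

    def paired(d: np.ndarray, label: str) -> ContrastResult:
        t, p = stats.ttest_1samp(d, 0.0)
        return ContrastResult(label=label, estimate=float(d.mean()), p_value=float(p))

    d1 = z[(methods[0], "left")] - z[(methods[0], "right")]
    d2 = z[(methods[1], "left")] - z[(methods[1], "right")]
    return [
        paired(d1, f"{methods[0]}: left-right"),
        paired(d2, f"{methods[1]}: left-right"),
        paired(d1 - d2, f"interaction: {methods[0]}-{methods[1]}"),
    ]


def residualize(volumes, confounds) -> np.ndarray:
    """OLS residuals of each volume column on the confounds plus an intercept.

    Complete cases are required. Residual means are 0 by construction, and the
    operation is idempotent. Raises on a rank-deficient design.
    """
    v = np.asarray(volumes, dtype=float)
    c = np.asarray(confounds, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if c.ndim == 1:
        c = c[:, None]
    if np.isnan(v).any() or np.isnan(c).any():
        raise VolconsistError("residualize requires complete cases")
    if v.shape[0] != c.shape[0]:
        raise VolconsistError("volumes and confounds must have equal row counts")
    design = np.column_stack([np.ones(c.shape[0]), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise VolconsistError("rank-deficient confound design (after adding intercept)")
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    resid = v - design @ beta
    return resid if np.asarray(volumes).ndim > 1 else resid[:, 0]
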