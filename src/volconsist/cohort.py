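"""Synthetic cohort generator: a biobank-shaped stand-in for restricted data.

Each participant has a latent "true" volume per region and hemisphere; two
measurement channels (think FSL FIRST vs FreeSurfer ASEG) observe that latent
volume with independent additive Gaussian noise, optional per-method offsets
and hemisphere asymmetries, and linear confound contributions. Phenotypes are
Gaussian variables with a specified correlation to a named latent volume, with
completely-at-random missingness.

The key inversion: for a target population consistency ICC c between the two
channels, with X_m = T + e_m and e_m ~ N(0, σ_e²) independent,
ICC = σ_T² / (σ_T² + σ_e²), hence σ_e = σ_T · sqrt((1−c)/c).  Confound
loadings shared between channels add covariance on top of this, raising the
achieved ICC above the noise-only target; ``empirical_checks`` accounts for
that analytically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reliability
from .errors import VolconsistError

__all__ = [
    "RegionSpec",
    "ConfoundSpec",
    "PhenotypeSpec",
    "CohortSpec",
    "error_sd_for_target_icc",
    "generate_cohort",
    "empirical_checks",
    "volume_column",
    "latent_column",
    "write_cohort_csv",
]

logger = logging.getLogger(__name__)

HEMISPHERES = ("left", "right")


def volume_column(method: str, hemisphere: str, region: str) -> str:
    return f"{method}_{hemisphere}_{region}"


def latent_column(hemisphere: str, region: str) -> str:
    return f"latent_{hemisphere}_{region}"


@dataclass
class RegionSpec:
    """One bilateral brain structure.

    ``hemisphere_asymmetry`` shifts the *latent* left mean up and the right
    mean down by half each (shared by both methods). ``method_asymmetry``
    gives each method its own additional left-minus-right measurement shift,
    which is what creates method × hemisphere interactions.
    ``method_offset`` is the additive bias of method 2 relative to method 1.
    All values in mm³.
    """

    name: str
    mean_volume: float
    between_subject_sd: float
    target_consistency: float = 0.8
    method_offset: float = 0.0
    hemisphere_asymmetry: float = 0.0
    method_asymmetry: tuple[float, float] = (0.0, 0.0)
    hemisphere_correlation: float = 0.8
    #: optional ratio of method-2 to method-1 error SD (1 = equal variances)
    error_sd_ratio: float = 1.0

    def validate(self) -> None:
        if not (0 < self.target_consistency <= 1):
            raise VolconsistError(f"{self.name}: target_consistency must be in (0, 1]")
        if self.between_subject_sd <= 0:
            raise VolconsistError(f"{self.name}: between_subject_sd must be > 0")
        if not (0 <= self.hemisphere_correlation <= 1):
            raise VolconsistError(f"{self.name}: hemisphere_correlation must be in [0, 1]")
        if self.error_sd_ratio <= 0:
            raise VolconsistError(f"{self.name}: error_sd_ratio must be > 0")


@dataclass
class ConfoundSpec:
    """A linear confound; ``loading_per_method`` is the mm³ effect per SD on
    each method's measurement (equal loadings = shared confound)."""

    name: str
    kind: str = "continuous"  # "continuous" | "categorical"
    loading_per_method: tuple[float, float] = (0.0, 0.0)
    n_levels: int = 3  # categorical only

    def validate(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise VolconsistError(f"{self.name}: kind must be continuous or categorical")
        if self.kind == "categorical" and self.n_levels < 2:
            raise VolconsistError(f"{self.name}: categorical confound needs ≥ 2 levels")


@dataclass
class PhenotypeSpec:
    """An outcome variable correlated with one region's latent volume."""

    name: str
    region: str
    true_correlation: float
    hemisphere: str = "left"
    missing_rate: float = 0.0

    def validate(self, region_names: set[str]) -> None:
        if self.region not in region_names:
            raise VolconsistError(f"phenotype {self.name}: unknown region {self.region!r}")
        if not (-1 < self.true_correlation < 1):
            raise VolconsistError(f"phenotype {self.name}: true_correlation must be in (-1, 1)")
        if not (0 <= self.missing_rate < 1):
            raise VolconsistError(f"phenotype {self.name}: missing_rate must be in [0, 1)")
        if self.hemisphere not in HEMISPHERES:
            raise VolconsistError(f"phenotype {self.name}: hemisphere must be left or right")


@dataclass
class CohortSpec:
    n_participants: int
    regions: list[RegionSpec]
    confounds: list[ConfoundSpec] = field(default_factory=list)
    phenotypes: list[PhenotypeSpec] = field(default_factory=list)
    methods: tuple[str, str] = ("fsl", "freesurfer")
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise VolconsistError("n_participants must be > 1")
        if not self.regions:
            raise VolconsistError("at least one region is required")
        names = {r.name for r in self.regions}
        if len(names) != len(self.regions):
            raise VolconsistError("region names must be unique")
        for r in self.regions:
            r.validate()
        for c in self.confounds:
            c.validate()
        for p in self.phenotypes:
            p.validate(names)


def error_sd_for_target_icc(target_icc: float, between_sd: float) -> float:
    """Measurement-error SD giving two independent noisy copies the target ICC."""
    if not (0 < target_icc <= 1):
        raise VolconsistError("target_icc must be in (0, 1]; 0 would need infinite noise")
    if between_sd <= 0:
        raise VolconsistError("between_sd must be > 0")
    return between_sd * math.sqrt((1 - target_icc) / target_icc)


def _redraw_nonpositive(values: np.ndarray, draw, what: str) -> np.ndarray:
    """Redraw cells until strictly positive; rare at realistic mean/SD ratios."""
    total = 0
    for _ in range(100):
        bad = values <= 0
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        total += n_bad
        values[bad] = draw(n_bad)
    else:
        raise VolconsistError(f"{what}: could not draw positive values; check mean/SD")
    if total:
        logger.info("%s: redrew %d non-positive cells", what, total)
    return values


def generate_cohort(spec: CohortSpec, keep_latent: bool = True) -> pd.DataFrame:
    """Generate a cohort table; fully reproducible from ``spec.seed``.

    Columns: ``participant_id``; ``<method>_<hemisphere>_<region>`` volumes
    (mm³); one column per confound; one per phenotype (with NaN for missing);
    and, when ``keep_latent``, ``latent_<hemisphere>_<region>`` oracle columns
    that analysis stages must never consume.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    data: dict[str, np.ndarray] = {"participant_id": np.arange(1, n + 1)}

    # confounds first: their standardized values feed the measurement model
    conf_z: dict[str, np.ndarray] = {}
    for conf in spec.confounds:
        if conf.kind == "continuous":
            vals = rng.standard_normal(n)
            z = vals
        else:
            vals = rng.integers(0, conf.n_levels, size=n).astype(float)
            sd = vals.std()
            z = (vals - vals.mean()) / sd if sd > 0 else np.zeros(n)
        data[conf.name] = vals
        conf_z[conf.name] = z

    latents: dict[tuple[str, str], np.ndarray] = {}
    for region in spec.regions:
        sd_t = region.between_subject_sd
        rho_h = region.hemisphere_correlation
        z_common = rng.standard_normal(n)
        sigma_e1 = error_sd_for_target_icc(region.target_consistency, sd_t)
        sigma_e = (sigma_e1, sigma_e1 * region.error_sd_ratio)
        for hemisphere in HEMISPHERES:
            z_h = rng.standard_normal(n)
            mean_h = region.mean_volume + (
                +region.hemisphere_asymmetry / 2
                if hemisphere == "left"
                else -region.hemisphere_asymmetry / 2
            )

            def draw_latent(m, mean=mean_h):
                # redraws use fresh standard normals; the mixture only shapes
                # the initial draw's cross-hemisphere correlation
                return mean + sd_t * rng.standard_normal(m)

            t = mean_h + sd_t * (math.sqrt(rho_h) * z_common + math.sqrt(1 - rho_h) * z_h)
            t = _redraw_nonpositive(t, draw_latent, f"latent {hemisphere} {region.name}")
            latents[(region.name, hemisphere)] = t
            data[latent_column(hemisphere, region.name)] = t

            s_h = 0.5 if hemisphere == "left" else -0.5
            for m, method in enumerate(spec.methods):
                bias = (region.method_offset if m == 1 else 0.0) + (
                    region.method_asymmetry[m] * s_h
                )
                conf_part = np.zeros(n)
                for conf in spec.confounds:
                    conf_part += conf.loading_per_method[m] * conf_z[conf.name]
                mean_x = t + bias + conf_part
                x = mean_x + sigma_e[m] * rng.standard_normal(n)
                if sigma_e[m] > 0:
                    total = 0
                    for _ in range(100):
                        bad = x <= 0
                        n_bad = int(bad.sum())
                        if n_bad == 0:
                            break
                        total += n_bad
                        x[bad] = mean_x[bad] + sigma_e[m] * rng.standard_normal(n_bad)
                    else:
                        raise VolconsistError(
                            f"{method} {hemisphere} {region.name}: could not draw positive volumes"
                        )
                    if total:
                        logger.info(
                            "%s %s %s: redrew %d non-positive cells",
                            method,
                            hemisphere,
                            region.name,
                            total,
                        )
                elif (x <= 0).any():
                    raise VolconsistError(
                        f"{method} {hemisphere} {region.name}: deterministic non-positive volume"
                    )
                data[volume_column(method, hemisphere, region.name)] = x

    for pheno in spec.phenotypes:
        t = latents[(pheno.region, pheno.hemisphere)]
        z_t = (t - t.mean()) / t.std()
        rho = pheno.true_correlation
        y = rho * z_t + math.sqrt(1 - rho**2) * rng.standard_normal(n)
        if pheno.missing_rate > 0:
            y = y.copy()
            y[rng.random(n) < pheno.missing_rate] = np.nan
        data[pheno.name] = y

    df = pd.DataFrame(data)
    if not keep_latent:
        df = df.drop(columns=[c for c in df.columns if c.startswith("latent_")])
    return df


def _implied_consistency(region: RegionSpec, confounds: list[ConfoundSpec]) -> float:
    """Population consistency ICC implied by the full measurement model.

    cov(X1, X2) = σ_T² + Σ l₁l₂ ;  var(X_m) = σ_T² + σ_em² + Σ l_m².
    ICC(C,1) for k = 2 converges to 2·cov / (var₁ + var₂).
    """
    var_t = region.between_subject_sd**2
    sigma_e1 = error_sd_for_target_icc(region.target_consistency, region.between_subject_sd)
    var_e = (sigma_e1**2, (sigma_e1 * region.error_sd_ratio) ** 2)
    cov = var_t + sum(c.loading_per_method[0] * c.loading_per_method[1] for c in confounds)
    var1 = var_t + var_e[0] + sum(c.loading_per_method[0] ** 2 for c in confounds)
    var2 = var_t + var_e[1] + sum(c.loading_per_method[1] ** 2 for c in confounds)
    return 2 * cov / (var1 + var2)


def empirical_checks(cohort: pd.DataFrame, spec: CohortSpec, tol_se: float = 3.0) -> pd.DataFrame:
    """Compare achieved against model-implied ICCs and phenotype correlations.

    Requires the latent oracle columns. Flags any quantity further than
    ``tol_se`` Monte-Carlo standard errors from its implied value.
    """
    missing = [
        latent_column(h, r.name)
        for r in spec.regions
        for h in HEMISPHERES
        if latent_column(h, r.name) not in cohort.columns
    ]
    if missing:
        raise VolconsistError(f"latent columns absent: {missing}; regenerate with keep_latent")
    n = len(cohort)
    rows = []
    for region in spec.regions:
        implied = _implied_consistency(region, spec.confounds)
        for hemisphere in HEMISPHERES:
            cols = [volume_column(m, hemisphere, region.name) for m in spec.methods]
            est = reliability.icc_consistency(cohort[cols].to_numpy())
            # Fisher-z scale SE for a correlation-like quantity
            se = (1 - implied**2) / math.sqrt(n - 3)
            rows.append(
                {
                    "kind": "icc_consistency",
                    "name": f"{hemisphere}_{region.name}",
                    "target": region.target_consistency,
                    "implied": implied,
                    "achieved": est.value,
                    "se": se,
                    "flag": abs(est.value - implied) > tol_se * se,
                }
            )
    for pheno in spec.phenotypes:
        t = cohort[latent_column(pheno.hemisphere, pheno.region)]
        y = cohort[pheno.name]
        ok = y.notna()
        r = float(np.corrcoef(t[ok], y[ok])[0, 1])
        m = int(ok.sum())
        se = (1 - pheno.true_correlation**2) / math.sqrt(max(m - 3, 1))
        rows.append(
            {
                "kind": "phenotype_correlation",
                "name": pheno.name,
                "target": pheno.true_correlation,
                "implied": pheno.true_correlation,
                "achieved": r,
                "se": se,
                "flag": abs(r - pheno.true_correlation) > tol_se * se,
            }
        )
    return pd.DataFrame(rows)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """UTF-8, LF, header row, no index — the bit-exact CSV convention."""
    cohort.to_csv(path, index=False, lineterminator="\n")
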