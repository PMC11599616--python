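"""YAML configuration for the pipeline stages.

One file describes the synthetic cohort, the artificial-data simulation grid,
the resampling study, and which regions get ICC/comparison summaries. Any
section may be omitted; stage helpers fill documented defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .cohort import CohortSpec, ConfoundSpec, PhenotypeSpec, RegionSpec
from .discordance import SimConfig
from .errors import VolconsistError
from .resampling import ResampleConfig

__all__ = [
    "load_config",
    "cohort_spec_from_config",
    "sim_grid_from_config",
    "resample_configs_from_config",
    "DEMO_CONFIG_PATH",
]

DEMO_CONFIG_PATH = Path(__file__).resolve().parents[2] / "configs" / "demo.yaml"


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise VolconsistError(f"config {path} must be a mapping")
    return cfg


def _pair(value, name: str) -> tuple[float, float]:
    if isinstance(value, (int, float)):
        return (float(value), float(value))
    if isinstance(value, (list, tuple)) and len(value) == 2:
        return (float(value[0]), float(value[1]))
    raise VolconsistError(f"{name} must be a number or a pair of numbers")


def cohort_spec_from_config(cfg: dict, seed: int | None = None) -> CohortSpec:
    c = cfg.get("cohort")
    if c is None:
        raise VolconsistError("config has no 'cohort' section")
    regions = [
        RegionSpec(
            name=r["name"],
            mean_volume=float(r["mean_volume"]),
            between_subject_sd=float(r["between_subject_sd"]),
            target_consistency=float(r.get("target_consistency", 0.8)),
            method_offset=float(r.get("method_offset", 0.0)),
            hemisphere_asymmetry=float(r.get("hemisphere_asymmetry", 0.0)),
            method_asymmetry=_pair(r.get("method_asymmetry", 0.0), "method_asymmetry"),
            hemisphere_correlation=float(r.get("hemisphere_correlation", 0.8)),
            error_sd_ratio=float(r.get("error_sd_ratio", 1.0)),
        )
        for r in c.get("regions", [])
    ]
    confounds = [
        ConfoundSpec(
            name=x["name"],
            kind=x.get("kind", "continuous"),
            loading_per_method=_pair(x.get("loading_per_method", 0.0), "loading_per_method"),
            n_levels=int(x.get("n_levels", 3)),
        )
        for x in c.get("confounds", [])
    ]
    phenotypes = [
        PhenotypeSpec(
            name=p["name"],
            region=p["region"],
            true_correlation=float(p.get("true_correlation", 0.0)),
            hemisphere=p.get("hemisphere", "left"),
            missing_rate=float(p.get("missing_rate", 0.0)),
        )
        for p in c.get("phenotypes", [])
    ]
    spec = CohortSpec(
        n_participants=int(c["n_participants"]),
        regions=regions,
        confounds=confounds,
        phenotypes=phenotypes,
        methods=tuple(c.get("methods", ("fsl", "freesurfer"))),
        seed=int(c.get("seed", 0)) if seed is None else int(seed),
    )
    spec.validate()
    return spec


def sim_grid_from_config(cfg: dict, seed: int | None = None):
    """Returns (iccs, rhos, ns, base SimConfig). Defaults match the study grid:
    rho ∈ {0.01, 0.1, 0.2}, n ∈ {50, 100}, α = 0.05."""
    s = cfg.get("simulate", {})
    iccs = [float(v) for v in s.get("iccs", [0.2, 0.4, 0.6, 0.8, 0.95])]
    rhos = [float(v) for v in s.get("rhos", [0.01, 0.1, 0.2])]
    ns = [int(v) for v in s.get("ns", [50, 100])]
    base = SimConfig(
        icc=iccs[0],
        rho=rhos[0],
        n=ns[0],
        n_experiments=int(s.get("n_experiments", 500)),
        n_batches=int(s.get("n_batches", 200)),
        alpha=float(s.get("alpha", 0.05)),
        correlation_kind=s.get("correlation_kind", "pearson"),
        seed=int(s.get("seed", 0)) if seed is None else int(seed),
    )
    return iccs, rhos, ns, base


def resample_configs_from_config(cfg: dict, seed: int | None = None) -> list[ResampleConfig]:
    """One ResampleConfig per requested subsample size."""
    r = cfg.get("resample", {})
    ns = [int(v) for v in r.get("ns", [50, 100])]
    return [
        ResampleConfig(
            region=r.get("region", "amygdala"),
            hemisphere=r.get("hemisphere", "left"),
            top_k=int(r.get("top_k", 50)),
            n=n,
            n_experiments=int(r.get("n_experiments", 200)),
            n_batches=int(r.get("n_batches", 50)),
            alpha=float(r.get("alpha", 0.05)),
            seed=int(r.get("seed", 0)) if seed is None else int(seed),
            methods=tuple(cfg.get("cohort", {}).get("methods", ("fsl", "freesurfer"))),
        )
        for n in ns
    ]
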