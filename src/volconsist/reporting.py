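"""Report formatting, run manifests, and the end-to-end pipeline driver."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__, cohort, config as cfgmod, reliability, structure
from .cohort import HEMISPHERES, volume_column, write_cohort_csv
from .discordance import run_grid
from .errors import VolconsistError
from .resampling import compare_sample_sizes, run_resampling

__all__ = ["format_estimate", "RunManifest", "full_pipeline", "write_table"]

logger = logging.getLogger(__name__)


def format_estimate(value: float, ci_low: float, ci_high: float, digits: int = 2) -> str:
    """Render an estimate with its interval as e.g. ``0.22 [0.21, 0.23]``.

    Fixed decimal digits with round-half-even; the bracket suffix replaces the
    subscript typography some journals use for uncertainty.
    """
    if not (ci_low <= value <= ci_high):
        raise VolconsistError(
            f"interval ordering violated: need ci_low <= value <= ci_high, "
            f"got ({ci_low}, {value}, {ci_high})"
        )
    fmt = f"{{:.{digits}f}}"
    return f"{fmt.format(value)} [{fmt.format(ci_low)}, {fmt.format(ci_high)}]"


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI/pipeline run."""

    command: str
    config_hash: str
    seed: int
    version: str
    started: str
    finished: str = ""
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    @staticmethod
    def hash_config(cfg: dict) -> str:
        payload = json.dumps(cfg, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def write_table(df: pd.DataFrame, path: Path) -> Path:
    """Header, no index, UTF-8, LF — the deterministic CSV convention."""
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def _derive_seed(base: int, stage: str) -> int:
    digest = hashlib.sha256(f"{base}|{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def full_pipeline(cfg: dict, out_dir, seed: int, command: str = "run-all") -> Path:
    """Run generate → icc → compare → simulate → resample; write a report directory.

    Every stage's output is a CSV under ``out_dir``; a summary text file lists
    the stage outputs and headline numbers, and a manifest records config hash,
    seed and software version. Deterministic from ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        config_hash=RunManifest.hash_config(cfg),
        seed=seed,
        version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )
    outputs: list[Path] = []
    summary: list[str] = []

    def stage(name):
        logger.info("stage: %s", name)
        summary.append(f"== {name} ==")

    try:
        stage("generate")
        spec = cfgmod.cohort_spec_from_config(cfg, seed=_derive_seed(seed, "cohort"))
        table = cohort.generate_cohort(spec)
        cohort_path = out / "cohort.csv"
        write_cohort_csv(table, cohort_path)
        outputs.append(cohort_path)
        checks = cohort.empirical_checks(table, spec)
        outputs.append(write_table(checks, out / "cohort_checks.csv"))
        summary.append(f"cohort: {len(table)} participants, {len(spec.regions)} regions")
        summary.append(f"generator checks flagged: {int(checks['flag'].sum())}")
    except VolconsistError as err:
        raise VolconsistError(f"[generate] {err}") from err

    try:
        stage("icc")
        icc_rows = []
        for region in spec.regions:
            cols = [(m, h) for m in spec.methods for h in HEMISPHERES]
            icc_rows.append(reliability.pairwise_consistency(table, region.name, cols))
        icc_table = pd.concat(icc_rows, ignore_index=True)
        outputs.append(write_table(icc_table, out / "icc.csv"))
        for region in spec.regions:
            cross = icc_table[
                (icc_table.region == region.name)
                & (
                    icc_table.column_a
                    == volume_column(spec.methods[0], "left", region.name)
                )
                & (
                    icc_table.column_b
                    == volume_column(spec.methods[1], "left", region.name)
                )
            ].iloc[0]
            summary.append(
                f"{region.name} left cross-method ICC(C,1): "
                + format_estimate(cross.value, cross.ci_low, cross.ci_high)
                + f" ({cross.category})"
            )
    except VolconsistError as err:
        raise VolconsistError(f"[icc] {err}") from err

    try:
        stage("compare")
        ortho_rows, contrast_rows = [], []
        for region in spec.regions:
            for hemisphere in HEMISPHERES:
                x = table[volume_column(spec.methods[0], hemisphere, region.name)]
                y = table[volume_column(spec.methods[1], hemisphere, region.name)]
                fit = structure.orthogonal_fit(x.to_numpy(), y.to_numpy())
                ortho_rows.append(
                    {
                        "region": region.name,
                        "hemisphere": hemisphere,
                        "slope": fit.slope,
                        "intercept": fit.intercept,
                    }
                )
            for res in structure.hemisphere_method_contrast(
                table, region.name, methods=spec.methods
            ):
                contrast_rows.append(
                    {
                        "region": region.name,
                        "label": res.label,
                        "estimate": res.estimate,
                        "p_value": res.p_value,
                    }
                )
        outputs.append(write_table(pd.DataFrame(ortho_rows), out / "orthogonal_fits.csv"))
        outputs.append(write_table(pd.DataFrame(contrast_rows), out / "contrasts.csv"))
        sizevar = structure.size_variability_summary(
            table, [r.name for r in spec.regions], methods=spec.methods
        )
        outputs.append(write_table(sizevar, out / "size_variability.csv"))
        if spec.confounds:
            conf_mat = table[[c.name for c in spec.confounds]].to_numpy()
            resid_rows = []
            for region in spec.regions:
                for hemisphere in HEMISPHERES:
                    cols = [volume_column(m, hemisphere, region.name) for m in spec.methods]
                    raw = reliability.icc_consistency(table[cols].to_numpy())
                    resid = reliability.icc_consistency(
                        structure.residualize(table[cols].to_numpy(), conf_mat)
                    )
                    resid_rows.append(
                        {
                            "region": region.name,
                            "hemisphere": hemisphere,
                            "icc_raw": raw.value,
                            "icc_residualized": resid.value,
                        }
                    )
            outputs.append(
                write_table(pd.DataFrame(resid_rows), out / "icc_residualized.csv")
            )
        summary.append(f"regions compared: {len(spec.regions)}")
    except VolconsistError as err:
        raise VolconsistError(f"[compare] {err}") from err

    try:
        stage("simulate")
        iccs, rhos, ns, base = cfgmod.sim_grid_from_config(
            cfg, seed=_derive_seed(seed, "simulate")
        )
        grid = run_grid(iccs, rhos, ns, base)
        outputs.append(write_table(grid, out / "discordance_grid.csv"))
        summary.append(f"grid cells: {len(grid)}")
    except VolconsistError as err:
        raise VolconsistError(f"[simulate] {err}") from err

    try:
        stage("resample")
        tables = {}
        pheno_names = [p.name for p in spec.phenotypes]
        for rcfg in cfgmod.resample_configs_from_config(
            cfg, seed=_derive_seed(seed, "resample")
        ):
            res = run_resampling(table, rcfg, phenotype_columns=pheno_names or None)
            tables[rcfg.n] = res
            outputs.append(write_table(res, out / f"resampling_n{rcfg.n}.csv"))
        if len(tables) >= 2:
            sizes = sorted(tables)
            comp = compare_sample_sizes(tables[sizes[0]], tables[sizes[-1]])
            outputs.append(write_table(comp, out / "resampling_sample_size_comparison.csv"))
        summary.append(f"resampling sample sizes: {sorted(tables)}")
    except VolconsistError as err:
        raise VolconsistError(f"[resample] {err}") from err

    summary_path = out / "summary.txt"
    with open(summary_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(summary) + "\n\nOutputs:\n")
        for p in outputs:
            fh.write(f"  {p.name}\n")
    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.outputs = [p.name for p in outputs] + [summary_path.name]
    manifest.write(out / "manifest.json")
    return out
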