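"""Biobank-style resampling study of rank-correlation discordance.

Phenotypes are screened by the absolute Spearman correlation between each
variable and the cross-method average volume of a target structure (default:
left amygdala); the top-k survive. Participants are then restricted to
complete cases over those k variables. Repeated small experiments subsample n
participants without replacement; within each experiment both methods' rank
correlations with every selected variable are tested and the pair classified
with the same categories as the artificial-data engine, so the two pipelines
share one definition of conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import volume_column
from .discordance import CATEGORIES, classify_arrays, corr_pvalues, summarize_batches
from .errors import VolconsistError

__all__ = [
    "ResampleConfig",
    "PhenotypeSelection",
    "select_phenotypes",
    "resample_experiments",
    "summarize_resampling",
    "run_resampling",
    "compare_sample_sizes",
]


@dataclass(frozen=True)
class ResampleConfig:
    region: str = "amygdala"
    hemisphere: str = "left"
    top_k: int = 50
    n: int = 50
    n_experiments: int = 200
    n_batches: int = 50
    alpha: float = 0.05
    seed: int = 0
    methods: tuple[str, str] = ("fsl", "freesurfer")

    def validate(self) -> None:
        if self.top_k < 1:
            raise VolconsistError("top_k must be ≥ 1")
        if self.n < 4:
            raise VolconsistError("n must be ≥ 4")
        if not (0 < self.alpha < 1):
            raise VolconsistError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class PhenotypeSelection:
    """Top-k phenotypes by |rank correlation| with the cross-method average volume."""

    variables: list[str]
    abs_rank_corr: list[float]  # same order as variables, descending
    complete_index: np.ndarray = field(repr=False)  # positional row indices

    @property
    def n_complete(self) -> int:
        return int(self.complete_index.size)


def _phenotype_columns(cohort: pd.DataFrame, config: ResampleConfig) -> list[str]:
    reserved = {"participant_id"}
    out = []
    for col in cohort.columns:
        if col in reserved or col.startswith("latent_"):
            continue
        if any(col.startswith(f"{m}_") for m in config.methods):
            continue
        out.append(col)
    return out


def select_phenotypes(
    cohort: pd.DataFrame,
    config: ResampleConfig,
    phenotype_columns: list[str] | None = None,
) -> PhenotypeSelection:
    """Screen phenotypes against the cross-method average volume.

    Selection-stage Spearman correlations use pairwise-complete observations;
    the returned participant set is the strict complete-case set over the
    selected variables (volumes are always complete by construction).
    """
    config.validate()
    if phenotype_columns is None:
        phenotype_columns = _phenotype_columns(cohort, config)
    if len(phenotype_columns) < config.top_k:
        raise VolconsistError(
            f"only {len(phenotype_columns)} phenotypes available, top_k={config.top_k}"
        )
    c1 = volume_column(config.methods[0], config.hemisphere, config.region)
    c2 = volume_column(config.methods[1], config.hemisphere, config.region)
    for col in (c1, c2):
        if col not in cohort.columns:
            raise KeyError(f"missing volume column {col!r}")
    avg = (cohort[c1].to_numpy() + cohort[c2].to_numpy()) / 2.0
    corrs = []
    for col in phenotype_columns:
        y = cohort[col].to_numpy()
        ok = ~np.isnan(y)
        rho = stats.spearmanr(avg[ok], y[ok]).statistic
        corrs.append((col, abs(float(rho))))
    corrs.sort(key=lambda item: item[1], reverse=True)
    selected = corrs[: config.top_k]
    names = [c for c, _ in selected]
    complete = ~np.isnan(cohort[names].to_numpy()).any(axis=1)
    return PhenotypeSelection(
        variables=names,
        abs_rank_corr=[r for _, r in selected],
        complete_index=np.flatnonzero(complete),
    )


def resample_experiments(
    cohort: pd.DataFrame,
    selection: PhenotypeSelection,
    config: ResampleConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-variable category tallies over all batches.

    Each experiment draws one subsample of n participants (without
    replacement) from the complete-case set and evaluates all selected
    variables on that same draw. Returns an (n_batches, n_variables, 4)
    integer array of counts indexed by ``discordance.CATEGORIES``.
    """
    config.validate()
    if selection.n_complete < config.n:
        raise VolconsistError(
            f"complete-case set ({selection.n_complete}) smaller than n={config.n}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    c1 = volume_column(config.methods[0], config.hemisphere, config.region)
    c2 = volume_column(config.methods[1], config.hemisphere, config.region)
    v1 = cohort[c1].to_numpy()[selection.complete_index]
    v2 = cohort[c2].to_numpy()[selection.complete_index]
    phen = cohort[selection.variables].to_numpy()[selection.complete_index]
    n_pool = v1.size
    n, k = config.n, len(selection.variables)
    tallies = np.zeros((config.n_batches, k, 4), dtype=np.int64)
    for b in range(config.n_batches):
        idx = np.empty((config.n_experiments, n), dtype=np.intp)
        for e in range(config.n_experiments):
            idx[e] = rng.choice(n_pool, size=n, replace=False, shuffle=False)
        rv1 = stats.rankdata(v1[idx], axis=1)[:, :, None]  # (m, n, 1)
        rv2 = stats.rankdata(v2[idx], axis=1)[:, :, None]
        rp = stats.rankdata(phen[idx], axis=1)  # (m, n, k)

        def rcorr(a, bmat):
            ac = a - a.mean(axis=1, keepdims=True)
            bc = bmat - bmat.mean(axis=1, keepdims=True)
            num = (ac * bc).sum(axis=1)
            den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
            return num / den

        r1 = rcorr(rv1, rp)  # (m, k)
        r2 = rcorr(rv2, rp)
        p1 = corr_pvalues(r1, n)
        p2 = corr_pvalues(r2, n)
        codes = classify_arrays(r1, p1, r2, p2, config.alpha)  # (m, k)
        for c in range(4):
            tallies[b, :, c] = (codes == c).sum(axis=0)
    return tallies


def summarize_resampling(
    tallies: np.ndarray,
    selection: PhenotypeSelection,
    config: ResampleConfig,
) -> pd.DataFrame:
    """Per-variable conflict-rate summary, sorted by |rank correlation| descending."""
    rows = []
    for j, (var, corr) in enumerate(zip(selection.variables, selection.abs_rank_corr)):
        batch_tallies = [
            {cat: int(tallies[b, j, c]) for c, cat in enumerate(CATEGORIES)}
            for b in range(tallies.shape[0])
        ]
        res = summarize_batches(batch_tallies)
        counts = res.counts
        any_sig = (
            counts["one_significant"] + counts["both_same_sign"] + counts["both_opposite_sign"]
        )
        both = counts["both_same_sign"] + counts["both_opposite_sign"]
        rows.append(
            {
                "variable": var,
                "abs_rank_corr": corr,
                "n": config.n,
                "p_sig_discord": res.p_sig_discord,
                "sig_discord_lo": res.sig_discord_lo,
                "sig_discord_hi": res.sig_discord_hi,
                "p_sign_conflict": res.p_sign_conflict,
                "sign_conflict_lo": res.sign_conflict_lo,
                "sign_conflict_hi": res.sign_conflict_hi,
                "sig_discord_denominator": res.sig_discord_denominator,
                "sign_conflict_denominator": res.sign_conflict_denominator,
                "pooled_sig_discord": (
                    counts["one_significant"] / any_sig if any_sig else np.nan
                ),
                "pooled_sign_conflict": (
                    counts["both_opposite_sign"] / both if both else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def run_resampling(
    cohort: pd.DataFrame,
    config: ResampleConfig,
    phenotype_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Select, resample, summarize — the full stage as one call."""
    selection = select_phenotypes(cohort, config, phenotype_columns=phenotype_columns)
    tallies = resample_experiments(cohort, selection, config)
    return summarize_resampling(tallies, selection, config)


def compare_sample_sizes(table_small: pd.DataFrame, table_large: pd.DataFrame) -> pd.DataFrame:
    """Side-by-side per-variable sign-conflict rates at two sample sizes.

    Flags variables whose sign-conflict proportion *increased* at the larger
    n — the counterintuitive pattern that more data does not always reduce
    this conflict.
    """
    a = table_small.set_index("variable")
    b = table_large.set_index("variable")
    common = a.index.intersection(b.index)
    out = pd.DataFrame(
        {
            "abs_rank_corr": a.loc[common, "abs_rank_corr"],
            "n_small": a.loc[common, "n"],
            "sign_conflict_small": a.loc[common, "p_sign_conflict"],
            "n_large": b.loc[common, "n"],
            "sign_conflict_large": b.loc[common, "p_sign_conflict"],
        }
    )
    out["increased_with_n"] = out["sign_conflict_large"] > out["sign_conflict_small"]
    return out.reset_index().sort_values("abs_rank_corr", ascending=False, ignore_index=True)
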