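"""Monte-Carlo engine for method-discordance rates under measurement noise.

Each simulated experiment draws a latent variable T ~ N(0, 1), two noisy
measurements X_m = T + e_m with e_m ~ N(0, (1−icc)/icc) independently (so the
population consistency ICC of X1 with X2 is exactly ``icc``), and an outcome
Y = ρ·T + sqrt(1−ρ²)·ε.  Both measurements are tested for correlation with Y,
and the pair of outcomes is classified:

* ``one_significant`` — the methods land on opposite sides of the α threshold;
* ``both_opposite_sign`` — both significant, with conflicting signs (the most
  severe discordance);
* ``both_same_sign`` / ``none_significant`` — concordant outcomes.

Two conditional conflict rates summarize a batch: the significance-discordance
rate P(exactly one significant | at least one significant) and the
sign-conflict rate P(opposite signs | both significant). Uncertainty is shown
as the median and 95% equal-tailed interval of the per-batch rates.

Measurement noise attenuates the observable signal: corr(X_m, Y) = ρ·√icc.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from math import sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, VolconsistError

__all__ = [
    "CATEGORIES",
    "SimConfig",
    "TestOutcome",
    "SimResult",
    "simulate_triplet",
    "test_correlation",
    "classify_experiment",
    "run_batch",
    "summarize_batches",
    "run_grid",
    "derive_cell_seed",
]

CATEGORIES = ("none_significant", "one_significant", "both_same_sign", "both_opposite_sign")


@dataclass(frozen=True)
class SimConfig:
    icc: float
    rho: float
    n: int
    n_experiments: int = 500
    n_batches: int = 200
    alpha: float = 0.05
    correlation_kind: str = "pearson"
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.icc <= 1):
            raise VolconsistError("icc must be in (0, 1]")
        if not (-1 < self.rho < 1):
            raise VolconsistError("rho must be in (-1, 1)")
        if self.n < 4:
            raise VolconsistError("n must be ≥ 4")
        if self.n_experiments < 1 or self.n_batches < 1:
            raise VolconsistError("n_experiments and n_batches must be ≥ 1")
        if not (0 < self.alpha < 1):
            raise VolconsistError("alpha must be in (0, 1)")
        if self.correlation_kind not in ("pearson", "spearman"):
            raise VolconsistError("correlation_kind must be pearson or spearman")


@dataclass(frozen=True)
class TestOutcome:
    r: float
    p: float
    significant: bool
    sign: int  # -1, 0, +1


@dataclass(frozen=True)
class SimResult:
    """Medians and 95% equal-tailed intervals of the two conflict rates."""

    p_sig_discord: float | None
    sig_discord_lo: float | None
    sig_discord_hi: float | None
    p_sign_conflict: float | None
    sign_conflict_lo: float | None
    sign_conflict_hi: float | None
    sig_discord_denominator: int
    sign_conflict_denominator: int
    sig_discord_batches_excluded: int
    sign_conflict_batches_excluded: int
    counts: dict = field(default_factory=dict)


def simulate_triplet(icc: float, rho: float, n: int, rng: np.random.Generator):
    """Draw one experiment's (X1, X2, Y), each of length n."""
    if not (0 < icc <= 1):
        raise VolconsistError("icc must be in (0, 1]")
    t = rng.standard_normal(n)
    noise_sd = sqrt((1 - icc) / icc)
    x1 = t + noise_sd * rng.standard_normal(n)
    x2 = t + noise_sd * rng.standard_normal(n)
    y = rho * t + sqrt(1 - rho**2) * rng.standard_normal(n)
    return x1, x2, y


def test_correlation(x, y, alpha: float = 0.05, kind: str = "pearson") -> TestOutcome:
    """Correlation test with a two-sided p-value; significance is strict p < α."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("correlation test needs length ≥ 4")
    if x.std() == 0 or y.std() == 0:
        raise VolconsistError("zero-variance input to correlation test")
    if kind == "pearson":
        res = stats.pearsonr(x, y)
    elif kind == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise VolconsistError("kind must be pearson or spearman")
    r, p = float(res.statistic), float(res.pvalue)
    return TestOutcome(r=r, p=p, significant=p < alpha, sign=int(np.sign(r)))


def classify_experiment(o1: TestOutcome, o2: TestOutcome) -> str:
    """Classify a pair of correlation tests from the same experiment.

    A both-significant pair containing an exactly-zero coefficient (a
    measure-zero event under continuous sampling) counts as same-sign.
    """
    if not o1.significant and not o2.significant:
        return "none_significant"
    if o1.significant != o2.significant:
        return "one_significant"
    if o1.sign != 0 and o2.sign != 0 and o1.sign != o2.sign:
        return "both_opposite_sign"
    return "both_same_sign"


# --- vectorized internals -------------------------------------------------


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r along axis 1 of two (m, n) arrays."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    return num / den


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=1)


def corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values via the t-approximation, t = r·√((n−2)/(1−r²))."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p[np.isnan(t) | np.isinf(t)] = 0.0  # |r| = 1 exactly
    return p


def classify_arrays(
    r1: np.ndarray, p1: np.ndarray, r2: np.ndarray, p2: np.ndarray, alpha: float
) -> np.ndarray:
    """Vectorized classifier; index into CATEGORIES. Matches classify_experiment."""
    s1 = p1 < alpha
    s2 = p2 < alpha
    out = np.zeros(r1.shape, dtype=np.int64)  # none_significant
    out[s1 != s2] = 1
    both = s1 & s2
    sign1, sign2 = np.sign(r1), np.sign(r2)
    opposite = both & (sign1 != 0) & (sign2 != 0) & (sign1 != sign2)
    out[both] = 2
    out[opposite] = 3
    return out


def run_batch(config: SimConfig, rng: np.random.Generator) -> dict:
    """Run one batch of independent experiments; returns category counts."""
    config.validate()
    m, n = config.n_experiments, config.n
    t = rng.standard_normal((m, n))
    noise_sd = sqrt((1 - config.icc) / config.icc)
    x1 = t + noise_sd * rng.standard_normal((m, n))
    x2 = t + noise_sd * rng.standard_normal((m, n))
    y = config.rho * t + sqrt(1 - config.rho**2) * rng.standard_normal((m, n))
    if config.correlation_kind == "spearman":
        x1, x2, y = _rank_rows(x1), _rank_rows(x2), _rank_rows(y)
    r1 = _rowwise_corr(x1, y)
    r2 = _rowwise_corr(x2, y)
    if config.icc == 1.0:
        r2 = r1  # identical measurements: identical tests, bit-exactly
    p1 = corr_pvalues(r1, n)
    p2 = corr_pvalues(r2, n)
    codes = classify_arrays(r1, p1, r2, p2, config.alpha)
    counts = np.bincount(codes, minlength=4)
    return {cat: int(c) for cat, c in zip(CATEGORIES, counts)}


def _equal_tailed(values: list[float]) -> tuple[float, float, float]:
    arr = np.asarray(values, dtype=float)
    return (
        float(np.median(arr)),
        float(np.percentile(arr, 2.5)),
        float(np.percentile(arr, 97.5)),
    )


def summarize_batches(tallies: list[dict]) -> SimResult:
    """Median and 95% equal-tailed interval of each conditional conflict rate.

    Batches whose denominator for a statistic is zero are excluded from that
    statistic's percentiles and counted in the exclusion tally. If every batch
    is excluded the statistic is reported as missing (None).
    """
    if not tallies:
        raise VolconsistError("at least one batch required")
    totals = {cat: sum(t[cat] for t in tallies) for cat in CATEGORIES}
    discord_rates, conflict_rates = [], []
    discord_excl = conflict_excl = 0
    for t in tallies:
        any_sig = t["one_significant"] + t["both_same_sign"] + t["both_opposite_sign"]
        if any_sig > 0:
            discord_rates.append(t["one_significant"] / any_sig)
        else:
            discord_excl += 1
        both = t["both_same_sign"] + t["both_opposite_sign"]
        if both > 0:
            conflict_rates.append(t["both_opposite_sign"] / both)
        else:
            conflict_excl += 1
    discord = _equal_tailed(discord_rates) if discord_rates else (None, None, None)
    conflict = _equal_tailed(conflict_rates) if conflict_rates else (None, None, None)
    return SimResult(
        p_sig_discord=discord[0],
        sig_discord_lo=discord[1],
        sig_discord_hi=discord[2],
        p_sign_conflict=conflict[0],
        sign_conflict_lo=conflict[1],
        sign_conflict_hi=conflict[2],
        sig_discord_denominator=totals["one_significant"]
        + totals["both_same_sign"]
        + totals["both_opposite_sign"],
        sign_conflict_denominator=totals["both_same_sign"] + totals["both_opposite_sign"],
        sig_discord_batches_excluded=discord_excl,
        sign_conflict_batches_excluded=conflict_excl,
        counts=totals,
    )


def run_cell(config: SimConfig) -> SimResult:
    """All batches of one grid cell, from the cell's own seeded stream."""
    rng = np.random.default_rng(config.seed)
    tallies = [run_batch(config, rng) for _ in range(config.n_batches)]
    return summarize_batches(tallies)


def derive_cell_seed(base_seed: int, icc: float, rho: float, n: int) -> int:
    """Stable per-cell seed: adding grid cells never perturbs existing ones."""
    label = f"{base_seed}|icc={icc!r}|rho={rho!r}|n={n!r}"
    digest = hashlib.sha256(label.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_grid(
    iccs: list[float],
    rhos: list[float],
    ns: list[int],
    base_config: SimConfig,
) -> pd.DataFrame:
    """One SimResult per (icc, rho, n) cell, as a tidy table."""
    if not iccs or not rhos or not ns:
        raise VolconsistError("grid axes must be nonempty")
    rows = []
    for icc in iccs:
        for rho in rhos:
            for n in ns:
                cell = replace(
                    base_config,
                    icc=icc,
                    rho=rho,
                    n=n,
                    seed=derive_cell_seed(base_config.seed, icc, rho, n),
                )
                res = run_cell(cell)
                rows.append(
                    {
                        "icc": icc,
                        "rho": rho,
                        "n": n,
                        "p_sig_discord": res.p_sig_discord,
                        "sig_discord_lo": res.sig_discord_lo,
                        "sig_discord_hi": res.sig_discord_hi,
                        "p_sign_conflict": res.p_sign_conflict,
                        "sign_conflict_lo": res.sign_conflict_lo,
                        "sign_conflict_hi": res.sign_conflict_hi,
                        "sig_discord_denominator": res.sig_discord_denominator,
                        "sign_conflict_denominator": res.sign_conflict_denominator,
                        "sig_discord_batches_excluded": res.sig_discord_batches_excluded,
                        "sign_conflict_batches_excluded": res.sign_conflict_batches_excluded,
                    }
                )
    return pd.DataFrame(rows)
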