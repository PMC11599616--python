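"""Monte-Carlo discordance engine: generative model, tests, classification,
batching, and the grid driver."""

import numpy as np
import pytest
from scipy import stats

from volconsist import discordance
from volconsist.discordance import (
    CATEGORIES,
    SimConfig,
    classify_arrays,
    classify_experiment,
    corr_pvalues,
    derive_cell_seed,
    run_batch,
    run_cell,
    run_grid,
    simulate_triplet,
    summarize_batches,
)
from volconsist.errors import InsufficientDataError, VolconsistError

# aliases: the library names collide with pytest's collection conventions
correlation_test = discordance.test_correlation
Outcome = discordance.TestOutcome


class TestSimulateTriplet:
    def test_perfect_icc_gives_identical_measurements(self):
        x1, x2, _ = simulate_triplet(1.0, 0.1, 500, np.random.default_rng(0))
        assert np.array_equal(x1, x2)

    def test_null_rho_gives_independent_outcome(self):
        x1, _, y = simulate_triplet(0.5, 0.0, 100_000, np.random.default_rng(1))
        assert abs(np.corrcoef(x1, y)[0, 1]) < 3 / np.sqrt(100_000)

    def test_closed_form_attenuation(self):
        x1, x2, y = simulate_triplet(0.2, 0.1, 100_000, np.random.default_rng(2))
        assert np.corrcoef(x1, x2)[0, 1] == pytest.approx(0.2, abs=0.01)
        assert np.corrcoef(x1, y)[0, 1] == pytest.approx(0.1 * np.sqrt(0.2), abs=0.01)

    def test_zero_icc_rejected(self):
        with pytest.raises(VolconsistError):
            simulate_triplet(0.0, 0.1, 10, np.random.default_rng(3))


class TestTestCorrelation:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        out = correlation_test(x, x)
        assert out.r == pytest.approx(1.0)
        assert out.significant and out.sign == 1

    def test_perfect_negative(self):
        x = np.arange(10.0)
        out = correlation_test(x, -x)
        assert out.r == pytest.approx(-1.0)
        assert out.sign == -1

    def test_matches_reference_routine(self):
        out = correlation_test([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert out.r == pytest.approx(0.8219949365267865, abs=1e-10)
        assert out.p == pytest.approx(0.08770664700806553, abs=1e-10)
        assert not out.significant

    def test_spearman_kind(self):
        out = correlation_test([1, 2, 3, 4, 5], [2, 1, 4, 3, 6], kind="spearman")
        assert out.r == pytest.approx(0.8, abs=1e-10)
        assert out.p == pytest.approx(0.10408803866182788, abs=1e-10)

    def test_zero_variance_raises(self):
        with pytest.raises(VolconsistError):
            correlation_test([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            correlation_test([1, 2, 3], [1, 2, 3])


def _outcome(r, p, alpha=0.05):
    return Outcome(r=r, p=p, significant=p < alpha, sign=int(np.sign(r)))


class TestClassifyExperiment:
    @pytest.mark.parametrize(
        "o1, o2, expected",
        [
            (_outcome(0.5, 0.01), _outcome(0.1, 0.5), "one_significant"),
            (_outcome(0.5, 0.01), _outcome(-0.4, 0.02), "both_opposite_sign"),
            (_outcome(0.1, 0.5), _outcome(-0.1, 0.6), "none_significant"),
            (_outcome(0.5, 0.01), _outcome(0.4, 0.02), "both_same_sign"),
            (_outcome(0.0, 0.01), _outcome(0.4, 0.02), "both_same_sign"),  # zero sign
        ],
    )
    def test_categories(self, o1, o2, expected):
        assert classify_experiment(o1, o2) == expected

    def test_vectorized_classifier_matches_scalar(self):
        """The batch engine's array classifier and the per-experiment function
        are the same definition (shared across both simulation pipelines)."""
        rng = np.random.default_rng(9)
        r1, r2 = rng.uniform(-1, 1, 500), rng.uniform(-1, 1, 500)
        p1, p2 = rng.uniform(0, 0.2, 500), rng.uniform(0, 0.2, 500)
        codes = classify_arrays(r1, p1, r2, p2, alpha=0.05)
        for i in range(500):
            o1 = _outcome(r1[i], p1[i])
            o2 = _outcome(r2[i], p2[i])
            assert CATEGORIES[codes[i]] == classify_experiment(o1, o2)

    def test_pvalue_t_approximation_matches_scipy(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((50, 30))
        y = rng.standard_normal((50, 30))
        r = np.array([stats.pearsonr(a, b).statistic for a, b in zip(x, y)])
        p_ref = np.array([stats.pearsonr(a, b).pvalue for a, b in zip(x, y)])
        assert np.allclose(corr_pvalues(r, 30), p_ref, atol=1e-12)


class TestRunBatch:
    def test_perfect_icc_never_conflicts(self):
        cfg = SimConfig(icc=1.0, rho=0.1, n=50, n_experiments=2000, n_batches=1, seed=1)
        tally = run_batch(cfg, np.random.default_rng(1))
        assert tally["one_significant"] == 0
        assert tally["both_opposite_sign"] == 0

    def test_type_i_calibration(self):
        cfg = SimConfig(icc=1.0, rho=0.0, n=50, n_experiments=20_000, n_batches=1, seed=2)
        tally = run_batch(cfg, np.random.default_rng(2))
        sig = tally["both_same_sign"] + tally["both_opposite_sign"]
        assert sig / 20_000 == pytest.approx(0.05, abs=0.005)

    def test_deterministic(self):
        cfg = SimConfig(icc=0.3, rho=0.1, n=50, n_experiments=1000, n_batches=1, seed=3)
        t1 = run_batch(cfg, np.random.default_rng(3))
        t2 = run_batch(cfg, np.random.default_rng(3))
        assert t1 == t2

    def test_null_sign_symmetry(self):
        """At rho = 0, significant correlations are + or − with equal probability."""
        cfg = SimConfig(icc=1.0, rho=0.0, n=50, n_experiments=50_000, n_batches=1, seed=4)
        m, n = cfg.n_experiments, cfg.n
        rng = np.random.default_rng(4)
        t = rng.standard_normal((m, n))
        y = rng.standard_normal((m, n))
        tc = t - t.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (tc * yc).sum(axis=1) / np.sqrt((tc**2).sum(axis=1) * (yc**2).sum(axis=1))
        p = corr_pvalues(r, n)
        signs = np.sign(r[p < 0.05])
        k = int((signs > 0).sum())
        assert stats.binomtest(k, len(signs), 0.5).pvalue > 0.01

    def test_attenuation_of_mean_absolute_r(self):
        """Mean observed |r| across experiments tracks rho·sqrt(icc)."""
        icc, rho, n = 0.5, 0.3, 200
        rng = np.random.default_rng(5)
        rs = []
        for _ in range(2000):
            x1, _, y = simulate_triplet(icc, rho, n, rng)
            rs.append(np.corrcoef(x1, y)[0, 1])
        assert np.mean(rs) == pytest.approx(rho * np.sqrt(icc), abs=0.01)


class TestSummarizeBatches:
    def test_identical_batches_degenerate_interval(self):
        tally = {
            "none_significant": 80,
            "one_significant": 10,
            "both_same_sign": 8,
            "both_opposite_sign": 2,
        }
        res = summarize_batches([tally] * 5)
        assert res.p_sig_discord == res.sig_discord_lo == res.sig_discord_hi == 0.5
        assert res.p_sign_conflict == 0.2

    def test_single_batch(self):
        tally = {
            "none_significant": 90,
            "one_significant": 5,
            "both_same_sign": 5,
            "both_opposite_sign": 0,
        }
        res = summarize_batches([tally])
        assert res.p_sig_discord == 0.5
        assert res.p_sign_conflict == 0.0
        assert res.sig_discord_lo == res.sig_discord_hi == 0.5

    def test_zero_denominators_reported_missing(self):
        tally = {
            "none_significant": 100,
            "one_significant": 0,
            "both_same_sign": 0,
            "both_opposite_sign": 0,
        }
        res = summarize_batches([tally] * 3)
        assert res.p_sig_discord is None
        assert res.p_sign_conflict is None
        assert res.sig_discord_batches_excluded == 3

    def test_interval_brackets_median(self):
        res = run_cell(SimConfig(icc=0.4, rho=0.1, n=50, n_experiments=200, n_batches=40, seed=6))
        assert res.sig_discord_lo <= res.p_sig_discord <= res.sig_discord_hi


class TestRunGrid:
    def test_single_cell(self):
        base = SimConfig(icc=0.5, rho=0.1, n=50, n_experiments=100, n_batches=5, seed=7)
        grid = run_grid([0.5], [0.1], [50], base)
        assert len(grid) == 1

    def test_cardinality(self):
        base = SimConfig(icc=0.5, rho=0.1, n=50, n_experiments=50, n_batches=2, seed=8)
        grid = run_grid([0.2, 0.8], [0.01, 0.1, 0.2], [50, 100], base)
        assert len(grid) == 12

    def test_adding_cells_does_not_perturb_existing(self):
        base = SimConfig(icc=0.5, rho=0.1, n=50, n_experiments=100, n_batches=5, seed=9)
        small = run_grid([0.5], [0.1], [50], base)
        large = run_grid([0.3, 0.5], [0.1], [50], base)
        row_small = small.iloc[0]
        row_large = large[large.icc == 0.5].iloc[0]
        assert row_small.p_sig_discord == row_large.p_sig_discord

    def test_cell_seed_derivation_stable_and_bounded(self):
        s = derive_cell_seed(7, 0.2, 0.1, 50)
        assert s == derive_cell_seed(7, 0.2, 0.1, 50)
        assert 0 <= s < 2**31
        assert s != derive_cell_seed(8, 0.2, 0.1, 50)

    def test_low_icc_discord_exceeds_high_icc(self):
        base = SimConfig(icc=0.5, rho=0.1, n=50, n_experiments=500, n_batches=20, seed=10)
        grid = run_grid([0.2, 0.9], [0.1], [50], base)
        lo = grid[grid.icc == 0.2].p_sig_discord.iloc[0]
        hi = grid[grid.icc == 0.9].p_sig_discord.iloc[0]
        assert lo > hi
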