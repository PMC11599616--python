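"""Orthogonal regression, proportional differences, contrasts, residualization."""

import numpy as np
import pytest
from hypothesis import assume, given, strategies as st

from volconsist.cohort import CohortSpec, ConfoundSpec, RegionSpec, generate_cohort
from volconsist.errors import InsufficientDataError, VolconsistError
from volconsist.reliability import icc_consistency
from volconsist.structure import (
    hemisphere_method_contrast,
    orthogonal_fit,
    proportional_difference,
    residualize,
    size_variability_summary,
)

finite_floats = st.floats(-1e6, 1e6, allow_nan=False)


class TestOrthogonalFit:
    def test_collinear_points(self):
        fit = orthogonal_fit([0, 1, 2], [0, 2, 4])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0)

    def test_symmetric_noise_is_not_attenuated(self):
        """With equal noise on both axes TLS recovers slope 1 where OLS would shrink it."""
        rng = np.random.default_rng(5)
        latent = rng.uniform(0, 10, 1000)
        x = latent + rng.normal(0, 0.5, 1000)
        y = latent + rng.normal(0, 0.5, 1000)
        slope = orthogonal_fit(x, y).slope
        assert 0.95 <= slope <= 1.05
        # OLS on the same data attenuates
        ols = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        assert ols < slope

    @given(st.integers(0, 5000))
    def test_axis_swap_gives_reciprocal_slope(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        s = orthogonal_fit(x, y).slope
        assume(abs(s) > 1e-8)
        assert orthogonal_fit(y, x).slope == pytest.approx(1 / s, rel=1e-8)

    @given(st.integers(0, 5000), finite_floats, finite_floats)
    def test_shift_equivariance(self, seed, dx, dy):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = 2 * x + rng.normal(size=20)
        base = orthogonal_fit(x, y)
        shifted = orthogonal_fit(x + dx, y + dy)
        assert shifted.slope == pytest.approx(base.slope, rel=1e-6, abs=1e-9)
        assert shifted.intercept == pytest.approx(
            base.intercept + dy - base.slope * dx, rel=1e-6, abs=1e-6
        )

    def test_degenerate_points_raise(self):
        with pytest.raises(VolconsistError):
            orthogonal_fit([1, 1, 1], [2, 2, 2])

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            orthogonal_fit([1, 2], [1, 2])


class TestProportionalDifference:
    def test_equal_inputs_give_zero(self):
        assert np.allclose(proportional_difference([3, 5], [3, 5]), 0.0)

    def test_arithmetic(self):
        assert proportional_difference([3.0], [1.0])[0] == pytest.approx(1.0)

    @given(
        st.lists(st.floats(0.1, 1e5), min_size=1, max_size=10),
        st.lists(st.floats(0.1, 1e5), min_size=1, max_size=10),
    )
    def test_antisymmetry(self, a, b):
        m = min(len(a), len(b))
        v1, v2 = np.array(a[:m]), np.array(b[:m])
        assert np.allclose(
            proportional_difference(v1, v2), -proportional_difference(v2, v1)
        )

    def test_nonpositive_sum_raises(self):
        with pytest.raises(VolconsistError):
            proportional_difference([1.0], [-1.0])


def _two_region_cohort(n=20_000, seed=11):
    """Small vs large region with identical generative parameters except the
    mean volume — equal between-subject SD and target, hence equal absolute
    error SD for both regions."""
    spec = CohortSpec(
        n_participants=n,
        regions=[
            RegionSpec("amygdala", 1200.0, 150.0, target_consistency=0.5),
            RegionSpec("putamen", 4800.0, 150.0, target_consistency=0.5),
        ],
        seed=seed,
    )
    return spec, generate_cohort(spec)


class TestSizeVariability:
    def test_single_region_single_row(self, demo_cohort):
        _, cohort = demo_cohort
        table = size_variability_summary(cohort, ["amygdala"])
        assert len(table) == 1

    def test_smaller_region_has_more_variable_proportional_difference(self):
        _, cohort = _two_region_cohort()
        table = size_variability_summary(cohort, ["amygdala", "putamen"])
        assert list(table.region) == ["amygdala", "putamen"]  # sorted by size
        small, big = table.sd_proportional_difference
        assert small > big

    def test_sorted_by_mean_volume(self, demo_cohort):
        _, cohort = demo_cohort
        table = size_variability_summary(cohort, ["hippocampus", "amygdala"])
        assert table.mean_volume.is_monotonic_increasing


class TestHemisphereMethodContrast:
    def test_null_case_interaction_near_zero(self):
        spec = CohortSpec(
            n_participants=20_000,
            regions=[RegionSpec("amygdala", 1500.0, 200.0, target_consistency=0.5)],
            seed=13,
        )
        results = hemisphere_method_contrast(generate_cohort(spec), "amygdala")
        interaction = results[2]
        assert abs(interaction.estimate) < 0.05
        assert interaction.p_value > 0.001

    def test_opposing_asymmetries_recovered(self):
        a = 60.0
        spec = CohortSpec(
            n_participants=20_000,
            regions=[
                RegionSpec(
                    "amygdala",
                    1500.0,
                    200.0,
                    target_consistency=0.5,
                    method_asymmetry=(a, -a),
                )
            ],
            seed=14,
        )
        cohort = generate_cohort(spec)
        results = hemisphere_method_contrast(cohort, "amygdala")
        pooled_sd = (
            cohort[[c for c in cohort.columns if "amygdala" in c and "latent" not in c]]
            .to_numpy()
            .std(ddof=1)
        )
        expected = 2 * a / pooled_sd
        interaction = results[2]
        assert interaction.estimate == pytest.approx(expected, rel=0.15)
        assert interaction.p_value < 0.001

    def test_planted_opposing_lateralization_contrasts(self, demo_cohort):
        """The demo cohort's amygdala shows opposite-sign left-right effects."""
        _, cohort = demo_cohort
        r1, r2, inter = hemisphere_method_contrast(cohort, "amygdala")
        assert r1.estimate > 0 > r2.estimate
        assert inter.estimate == pytest.approx(r1.estimate - r2.estimate, abs=1e-12)
        assert max(r1.p_value, r2.p_value, inter.p_value) < 0.001

    def test_single_participant_errors(self, demo_cohort):
        _, cohort = demo_cohort
        with pytest.raises(InsufficientDataError):
            hemisphere_method_contrast(cohort.iloc[:1], "amygdala")

    def test_missing_column_errors(self, demo_cohort):
        _, cohort = demo_cohort
        with pytest.raises(KeyError):
            hemisphere_method_contrast(cohort, "thalamus")


class TestResidualize:
    def test_orthogonal_confound_returns_centered_column(self):
        rng = np.random.default_rng(17)
        v = rng.normal(size=200)
        conf = rng.normal(size=(200, 1))
        conf -= conf.mean()
        # orthogonalize v against conf so the regression coefficient is 0
        v = v - conf[:, 0] * (v @ conf[:, 0]) / (conf[:, 0] @ conf[:, 0])
        resid = residualize(v, conf)
        assert np.allclose(resid, v - v.mean(), atol=1e-10)

    def test_exact_linear_function_gives_zero_residuals(self):
        rng = np.random.default_rng(18)
        conf = rng.normal(size=(100, 2))
        v = 3.0 + conf @ np.array([1.5, -2.0])
        assert np.allclose(residualize(v, conf), 0.0, atol=1e-9)

    def test_residual_means_zero_and_idempotent(self):
        rng = np.random.default_rng(19)
        v = rng.normal(size=(300, 3))
        conf = rng.normal(size=(300, 2))
        resid = residualize(v, conf)
        assert np.allclose(resid.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(residualize(resid, conf), resid, atol=1e-10)

    def test_rank_deficient_design_raises(self):
        conf = np.ones((50, 1))  # collinear with the intercept
        with pytest.raises(VolconsistError):
            residualize(np.arange(50.0), conf)

    def test_shared_confound_inflates_consistency(self):
        """Residualizing out a shared confound lowers the cross-method ICC:
        an apparent-consistency boost from a common driver, not the methods."""
        spec = CohortSpec(
            n_participants=20_000,
            regions=[RegionSpec("amygdala", 1500.0, 150.0, target_consistency=0.3)],
            confounds=[ConfoundSpec("head_size", loading_per_method=(120.0, 120.0))],
            seed=21,
        )
        cohort = generate_cohort(spec)
        cols = ["fsl_left_amygdala", "freesurfer_left_amygdala"]
        raw = icc_consistency(cohort[cols].to_numpy()).value
        resid = icc_consistency(
            residualize(cohort[cols].to_numpy(), cohort[["head_size"]].to_numpy())
        ).value
        assert resid < raw
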