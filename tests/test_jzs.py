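"""JZS t-test Bayes factors, delta posteriors and the variance-explained map."""

import numpy as np
import pytest
from conftest import bf10_gmixture, random_ttest_summaries

import repbayes as rb
from repbayes.posterior import summarize_grid


class TestValidation:
    def test_summary_invariants(self):
        with pytest.raises(ValueError):
            rb.TTestSummary(t=1.0, n1=1)
        with pytest.raises(ValueError):
            rb.TTestSummary(t=1.0, n1=5, n2=1)
        with pytest.raises(ValueError):
            rb.TTestSummary(t=1.0, n1=5, predicted_direction=0)
        one = rb.TTestSummary(t=1.0, n1=20)
        assert one.nu == 19 and one.n_eff == 20.0
        two = rb.TTestSummary(t=1.0, n1=18, n2=69)
        assert two.nu == 85 and two.n_eff == pytest.approx(18 * 69 / 87)

    def test_prior_invariants(self):
        with pytest.raises(ValueError):
            rb.PriorSpec(width_r=-0.1)
        with pytest.raises(ValueError):
            rb.PriorSpec(side="up")
        folded = rb.PriorSpec(width_r=0.7, side="positive")
        # folding doubles the density on the kept sign, kills the other
        assert folded.logpdf(0.5) == pytest.approx(
            rb.PriorSpec(width_r=0.7).logpdf(0.5) + np.log(2)
        )
        assert folded.logpdf(-0.5) == -np.inf

    def test_bf_result_invariants(self):
        with pytest.raises(ValueError):
            rb.BayesFactorResult(0.0, "10", rb.PriorSpec())
        res = rb.BayesFactorResult(4.0, "10", rb.PriorSpec())
        assert res.reciprocal == pytest.approx(0.25)


class TestBayesFactors:
    def test_point_null_width_gives_exactly_one(self):
        for s in random_ttest_summaries(5, seed=11):
            assert rb.bf10_ttest(s, rb.PriorSpec(width_r=0.0)).value == 1.0
            assert rb.bf_onesided_ttest(s, rb.PriorSpec(width_r=0.0)).value == 1.0

    def test_null_data_favour_null_and_match_gmixture_oracle(self):
        s = rb.TTestSummary(t=0.0, n1=50)
        bf = rb.bf10_ttest(s).value
        assert bf < 1.0
        assert bf == pytest.approx(bf10_gmixture(0.0, 50, 0, 2**-0.5), rel=1e-8)

    def test_two_sided_bf_is_symmetric_in_t(self, anchor):
        flipped = rb.TTestSummary(t=-anchor.t, n1=anchor.n1, n2=anchor.n2)
        assert rb.bf10_ttest(anchor).value == pytest.approx(
            rb.bf10_ttest(flipped).value, rel=1e-9
        )

    def test_sign_decomposition_identity(self):
        """BF+0 + BF-0 = 2 BF10: the alternative splits over the sign of delta."""
        for s in random_ttest_summaries(8, seed=3):
            prior = rb.PriorSpec(width_r=0.9)
            b10 = rb.bf10_ttest(s, prior).value
            bp = rb.bf_onesided_ttest(s, prior, side="positive").value
            bm = rb.bf_onesided_ttest(s, prior, side="negative").value
            assert bp + bm == pytest.approx(2 * b10, rel=1e-8)

    def test_directional_prediction_is_rewarded(self):
        """When the effect lands on the predicted side, BF+0 > BF10."""
        s = rb.TTestSummary(t=3.0, n1=30, n2=30)
        assert rb.bf_onesided_ttest(s, side="positive").value > rb.bf10_ttest(s).value

    def test_bf_nondecreasing_in_abs_t(self):
        vals = [
            rb.bf10_ttest(rb.TTestSummary(t=t, n1=25, n2=25)).value
            for t in np.linspace(0.0, 5.0, 11)
        ]
        assert np.all(np.diff(vals) > 0)

    def test_symmetric_posterior_at_t_zero_equates_sided_and_two_sided(self):
        s = rb.TTestSummary(t=0.0, n1=40)
        assert rb.bf_onesided_ttest(s, side="positive").value == pytest.approx(
            rb.bf10_ttest(s).value, rel=1e-8
        )


class TestDeltaPosterior:
    def test_matches_printed_worked_example(self, anchor):
        post = rb.delta_posterior(anchor)
        assert post.median == pytest.approx(1.00, abs=0.02)
        assert post.ci_low == pytest.approx(0.47, abs=0.02)
        assert post.ci_high == pytest.approx(1.56, abs=0.02)

    def test_symmetric_about_zero_for_null_t(self):
        post = rb.delta_posterior(rb.TTestSummary(t=0.0, n1=60))
        assert post.median == pytest.approx(0.0, abs=1e-3)
        assert post.ci_low == pytest.approx(-post.ci_high, abs=1e-3)

    def test_median_nondecreasing_in_t(self):
        meds = [
            rb.delta_posterior(rb.TTestSummary(t=t, n1=30, n2=40)).median
            for t in np.linspace(-3, 3, 7)
        ]
        assert np.all(np.diff(meds) > 0)

    def test_one_sided_truncation_renormalizes(self):
        post = rb.delta_posterior(
            rb.TTestSummary(t=1.0, n1=20), rb.PriorSpec(side="positive")
        )
        assert post.grid[0] >= 0.0
        assert np.trapezoid(post.density, post.grid) == pytest.approx(1.0, abs=1e-9)

    def test_width_zero_has_no_posterior(self):
        with pytest.raises(ValueError):
            rb.delta_posterior(rb.TTestSummary(t=1.0, n1=20), rb.PriorSpec(width_r=0.0))


class TestRho2:
    def test_matches_printed_worked_example(self, anchor):
        rng = np.random.default_rng(0)
        draws = rb.delta_posterior(anchor).sample(100_000, rng)
        post = rb.rho2_from_delta(draws, anchor.n1, anchor.n2)
        assert post.median == pytest.approx(0.14, abs=0.02)
        assert post.ci_low == pytest.approx(0.03, abs=0.02)
        assert post.ci_high == pytest.approx(0.29, abs=0.02)

    def test_closed_form_points(self):
        # equal groups, delta = 2: p1 p2 delta^2 = 1 -> rho^2 = 1/2
        post = rb.rho2_from_delta(np.array([2.0]), 50, 50)
        assert post.median == 0.5
        zero = rb.rho2_from_delta(np.zeros(10), 30, 0)
        assert zero.median == 0.0 and zero.ci_high == 0.0

    def test_bounds_and_validation(self):
        draws = np.random.default_rng(1).normal(0, 3, 1000)
        post = rb.rho2_from_delta(draws, 10, 90)
        assert np.all((post.draws >= 0) & (post.draws < 1))
        assert post.meta["convention"] == "two_sample"
        assert rb.rho2_from_delta(draws, 10).meta["convention"] == "one_sample_analogue"
        with pytest.raises(ValueError):
            rb.rho2_from_delta([], 10, 10)


class TestRobustnessCurve:
    def test_zero_width_entry_is_exactly_one(self, anchor):
        curve = rb.robustness_curve(anchor, r_grid=np.linspace(0, 1.5, 31))
        assert curve.bf_values[0] == 1.0
        assert np.all(np.isfinite(curve.bf_values) & (curve.bf_values > 0))

    def test_max_dominates_default_width(self, anchor):
        curve = rb.robustness_curve(anchor, r_grid=np.linspace(0.05, 1.5, 60))
        at_default = rb.bf_onesided_ttest(
            anchor, rb.PriorSpec(width_r=2**-0.5), side="positive"
        ).value
        assert curve.max_bf >= at_default * 0.999

    def test_curve_consistent_with_pointwise_bf(self, anchor):
        """The vectorized curve agrees with the adaptive-quadrature BF."""
        curve = rb.robustness_curve(anchor, r_grid=np.array([0.3, 0.7071, 1.2]))
        for r, val in zip(curve.r_values, curve.bf_values):
            direct = rb.bf_onesided_ttest(
                anchor, rb.PriorSpec(width_r=float(r)), side="positive"
            ).value
            assert val == pytest.approx(direct, rel=1e-5)

    def test_rejects_bad_grid(self, anchor):
        with pytest.raises(ValueError):
            rb.robustness_curve(anchor, r_grid=np.array([0.5, 0.2]))
        with pytest.raises(ValueError):
            rb.robustness_curve(anchor, r_grid=np.array([-0.1, 0.5]))


class TestPosteriorContainer:
    def test_summarize_grid_quantiles_against_closed_form(self):
        x = np.linspace(-6, 6, 10_001)
        post = summarize_grid(x, np.exp(-0.5 * x * x))
        assert post.median == pytest.approx(0.0, abs=1e-6)
        assert post.ci_low == pytest.approx(-1.959964, abs=1e-3)
        assert post.ci_high == pytest.approx(1.959964, abs=1e-3)

    def test_inverse_cdf_sampling_reproduces_density(self):
        x = np.linspace(-8, 8, 4001)
        post = summarize_grid(x, np.exp(-0.5 * (x - 1.0) ** 2))
        draws = post.sample(50_000, np.random.default_rng(7))
        assert draws.mean() == pytest.approx(1.0, abs=0.02)
        assert draws.std() == pytest.approx(1.0, abs=0.02)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            rb.PosteriorSummary(median=1.0, ci_low=2.0, ci_high=3.0)
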