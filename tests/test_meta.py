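"""Hierarchical random-effects meta-analysis: correctness, determinism, shrinkage."""

import numpy as np
import pytest
from scipy import stats

import repbayes as rb

SMALL_CFG = dict(chains=2, draws=2000)


@pytest.fixture(scope="module")
def small_set():
    rng = np.random.default_rng(17)
    studies = []
    for i, (t, n1, n2) in enumerate(
        [(2.1, 40, 45), (0.3, 60, 0), (-0.8, 35, 30), (1.2, 80, 75), (0.9, 25, 0)]
    ):
        studies.append(rb.TTestSummary(t=t, n1=n1, n2=n2, study_id=f"s{i}"))
    return rb.StudySet(tuple(studies))


@pytest.fixture(scope="module")
def small_fit(small_set):
    return rb.fit_meta(small_set, rb.HierarchicalConfig(seed=3, **SMALL_CFG))


def hyper_quadrature_oracle(studies, theta_nodes, tau_nodes, tau_scale=0.5,
                            theta_scale=0.5, m=256):
    """Tensor-quadrature posterior of (theta, tau), independent of fit_meta.

    Marginalizes each study's delta with the Gaussian quantile midpoint rule

        int lik(theta + tau z) phi(z) dz  ~  mean_q lik(theta + tau z_q),
        z_q = Phi^-1((q - 1/2) / m),

    whose nodes track tau, so narrow and wide hierarchies are handled alike.
    Study likelihoods come from a dense scipy tabulation; no FFT convolution
    or code shared with the package's sampler.
    """
    z = stats.norm.ppf((np.arange(m) + 0.5) / m)
    logpost = np.zeros((len(tau_nodes), len(theta_nodes)))
    for s in studies.studies:
        xs = np.linspace(-5.0, 6.0, 20_001)
        lik = np.exp(stats.nct.logpdf(s.t, s.nu, xs * np.sqrt(s.n_eff)))
        for k, tau in enumerate(tau_nodes):
            d = theta_nodes[:, None] + tau * z[None, :]
            vals = np.interp(d, xs, lik, left=0.0, right=0.0).mean(axis=1)
            logpost[k] += np.log(np.maximum(vals, 1e-300))
    logpost += -np.log1p((theta_nodes[None, :] / theta_scale) ** 2)
    logpost += -np.log1p((tau_nodes[:, None] / tau_scale) ** 2)
    post = np.exp(logpost - logpost.max())
    return post / post.sum()


def marginal_quantiles(x, p, qs=(0.025, 0.5, 0.975)):
    c = np.cumsum(p)
    c /= c[-1]
    return np.interp(qs, c, x)


class TestAgainstQuadratureOracle:
    def test_theta_and_tau_marginals(self, small_set, small_fit):
        theta_nodes = np.linspace(-0.8, 1.0, 241)
        tau_nodes = np.linspace(1e-3, 1.2, 300)
        post = hyper_quadrature_oracle(small_set, theta_nodes, tau_nodes)
        th_lo, th_med, th_hi = marginal_quantiles(theta_nodes, post.sum(axis=0))
        ta_lo, ta_med, ta_hi = marginal_quantiles(tau_nodes, post.sum(axis=1))
        fit_th = small_fit.theta_summary()
        fit_ta2 = small_fit.tau2_summary()
        assert fit_th.median == pytest.approx(th_med, abs=0.015)
        assert fit_th.ci_low == pytest.approx(th_lo, abs=0.02)
        assert fit_th.ci_high == pytest.approx(th_hi, abs=0.02)
        assert np.sqrt(fit_ta2.median) == pytest.approx(ta_med, abs=0.02)
        assert np.sqrt(fit_ta2.ci_high) == pytest.approx(ta_hi, abs=0.03)


class TestSamplerContracts:
    def test_bit_reproducible(self, small_set, small_fit):
        again = rb.fit_meta(small_set, rb.HierarchicalConfig(seed=3, **SMALL_CFG))
        assert np.array_equal(small_fit.theta_draws, again.theta_draws)
        assert np.array_equal(small_fit.tau2_draws, again.tau2_draws)
        assert np.array_equal(small_fit.delta_draws, again.delta_draws)

    def test_study_exchangeability(self, small_set, small_fit):
        """Permuting studies permutes delta draws and leaves theta/tau alone."""
        order = [3, 0, 4, 1, 2]
        perm = rb.StudySet(tuple(small_set.studies[i] for i in order))
        fit_p = rb.fit_meta(perm, rb.HierarchicalConfig(seed=3, **SMALL_CFG))
        assert np.array_equal(small_fit.theta_draws, fit_p.theta_draws)
        assert np.array_equal(small_fit.tau2_draws, fit_p.tau2_draws)
        for new_pos, old_pos in enumerate(order):
            assert np.array_equal(
                small_fit.delta_draws[:, old_pos], fit_p.delta_draws[:, new_pos]
            )

    def test_diagnostics_reported_and_converged(self, small_fit):
        d = small_fit.diagnostics
        assert d["rhat"]["theta"] < 1.01
        assert d["ess"]["theta"] > 400
        assert small_fit.converged

    def test_requires_two_studies(self):
        lone = rb.StudySet((rb.TTestSummary(t=1.0, n1=20, study_id="a"),))
        with pytest.raises(ValueError):
            rb.fit_meta(lone)

    def test_unique_ids_enforced(self):
        s = rb.TTestSummary(t=1.0, n1=20, study_id="a")
        with pytest.raises(ValueError):
            rb.StudySet((s, s))

    def test_recode_positive_flips_negative_predictions(self):
        s = rb.TTestSummary(t=-2.0, n1=20, predicted_direction=-1, study_id="a")
        flipped = rb.StudySet((s,)).recode_positive().studies[0]
        assert flipped.t == 2.0 and flipped.predicted_direction == 1


class TestLimits:
    def test_homogeneous_high_information_studies(self):
        """Identical large-n studies: theta pins to the common effect and the
        heterogeneity posterior piles onto its lower bound."""
        studies = rb.StudySet(
            tuple(
                rb.TTestSummary(t=25.0, n1=5000, n2=5000, study_id=f"big{i}")
                for i in range(4)
            )
        )
        d_hat = 25.0 / np.sqrt(2500.0)  # = 0.5
        post = rb.fit_meta(studies, rb.HierarchicalConfig(seed=1, **SMALL_CFG))
        th = post.theta_summary()
        assert th.median == pytest.approx(d_hat, abs=0.02)
        # heterogeneity mass piles up near zero, far below the effect scale
        assert np.median(post.tau2_draws) < 1e-3
        assert np.quantile(post.tau2_draws, 0.9) < 0.02

    def test_no_pooling_limit_matches_individual_posteriors(self):
        """tau pinned at ~100 turns the hierarchy off: the conditional for
        each delta is its own likelihood with an essentially flat prior."""
        studies = rb.StudySet(
            (
                rb.TTestSummary(t=3.0, n1=100, n2=100, study_id="a"),
                rb.TTestSummary(t=-1.0, n1=120, study_id="b"),
            )
        )
        cfg = rb.HierarchicalConfig(
            tau_prior="as_printed", tau_lower_bound=99.0, tau_upper_bound=101.0,
            seed=2, **SMALL_CFG,
        )
        post = rb.fit_meta(studies, cfg)
        for idx, s in enumerate(studies.studies):
            hier = post.delta_summary(idx)
            ind = rb.delta_posterior(s)
            assert hier.median == pytest.approx(ind.median, abs=0.03)


class TestShrinkage:
    def test_pull_is_toward_group_mean(self, small_set, small_fit):
        indiv = [rb.delta_posterior(s) for s in small_set.studies]
        table = rb.shrinkage_table(small_fit, indiv)
        theta_hat = float(np.median(small_fit.theta_draws))
        between = 0
        for _, row in table.iterrows():
            lo, hi = sorted((row.indiv_median, theta_hat))
            between += lo - 0.01 <= row.hier_median <= hi + 0.01
        assert between >= int(np.ceil(0.95 * len(table)))
        assert ((table.shrinkage >= 0) & (table.shrinkage <= 1)).all()

    def test_hierarchical_intervals_are_shorter_on_average(self, small_set, small_fit):
        indiv = [rb.delta_posterior(s) for s in small_set.studies]
        table = rb.shrinkage_table(small_fit, indiv)
        hier_w = (table.hier_hi - table.hier_lo).mean()
        ind_w = (table.indiv_hi - table.indiv_lo).mean()
        assert hier_w < ind_w

    def test_length_mismatch_rejected(self, small_fit):
        with pytest.raises(ValueError):
            rb.shrinkage_table(small_fit, [])
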