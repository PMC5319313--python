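"""Bayesian random-effects meta-analysis of standardized effect sizes.

Each study contributes only its t-test summary (t, nu, n_eff); the
likelihood is the noncentral-t sufficiency reduction used throughout the
package.  The hierarchy places delta_s ~ Normal(theta, tau^2) over the
per-study standardized effects, a Cauchy(0, 1/2) prior on the group mean
theta, and a configurable prior on the heterogeneity scale tau.

The joint posterior factorizes as

    p(theta, tau, delta | data)
        = p(theta, tau | data) * prod_s p(delta_s | theta, tau, t_s),

so instead of MCMC the sampler works by composition, which yields exact
independent draws:

1.  marginalize every delta_s out of the likelihood by convolving its
    tabulated noncentral-t likelihood with the Normal(0, tau^2) kernel,
    giving log p(theta, tau | data) on an adaptively refined
    (theta, log tau) grid;
2.  draw (theta, tau) pairs from that grid (multinomial over cells with
    within-cell jitter);
3.  draw each delta_s from its one-dimensional conditional, which is the
    product of the study likelihood and the Normal(theta, tau^2) density.

There is consequently no warmup, no autocorrelation and no funnel
pathology; the convergence diagnostics required of a sampling interface
are still computed (across independent seeded chains) and gated.

Floating-point study order must not matter, so per-study log-likelihood
planes are sorted before summation and each study's conditional draws come
from a stream keyed by its id: permuting the studies permutes the
per-study draws and leaves the theta/tau^2 draws bit-identical.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import fftconvolve

from .jzs import TTestSummary
from .likelihoods import noncentral_t_logpdf
from .posterior import PosteriorSummary, summarize_draws

__all__ = [
    "StudySet",
    "HierarchicalConfig",
    "HierarchicalPosterior",
    "fit_meta",
    "shrinkage_table",
    "noncentral_t_logpdf",
]


@dataclass(frozen=True)
class StudySet:
    """Ordered collection of t-test summaries with unique study ids."""

    studies: tuple[TTestSummary, ...]

    def __post_init__(self) -> None:
        studies = tuple(self.studies)
        ids = [s.study_id for s in studies]
        if len(set(ids)) != len(ids):
            raise ValueError("study ids must be unique")
        object.__setattr__(self, "studies", studies)

    def __len__(self) -> int:
        return len(self.studies)

    @property
    def study_ids(self) -> list[str]:
        return [s.study_id for s in self.studies]

    def recode_positive(self) -> "StudySet":
        """Flip t-statistics so every study's predicted direction is +1."""
        out = []
        for s in self.studies:
            if s.predicted_direction == -1:
                s = replace(s, t=-s.t, predicted_direction=1)
            out.append(s)
        return StudySet(tuple(out))


@dataclass(frozen=True)
class HierarchicalConfig:
    """Priors and sampler settings for the random-effects model.

    ``tau_prior``: ``"half_cauchy"`` (default) puts a half-Cauchy with scale
    ``tau_scale`` on tau; ``"as_printed"`` uses the improper p(tau) ∝ tau^-2
    truncated to [tau_lower_bound, tau_upper_bound] (kept for fidelity to
    the published analysis, but its mass piles up at the lower bound, so it
    is not the default).  ``draws`` is the number of posterior draws per
    chain; chains are independent seeded streams.  ``warmup`` is accepted
    for sampler-interface compatibility; the composition sampler draws
    independently and does not use it.
    """

    theta_prior_scale: float = 0.5
    tau_prior: str = "half_cauchy"
    tau_scale: float = 0.5
    chains: int = 4
    warmup: int = 1000
    draws: int = 10_000
    seed: int = 0
    tau_lower_bound: float = 1e-3
    tau_upper_bound: float = 10.0

    def __post_init__(self) -> None:
        if self.theta_prior_scale <= 0 or self.tau_scale <= 0:
            raise ValueError("prior scales must be positive")
        if self.tau_prior not in ("half_cauchy", "as_printed"):
            raise ValueError("tau_prior must be 'half_cauchy' or 'as_printed'")
        if self.chains < 1 or self.warmup < 1 or self.draws < 1000:
            raise ValueError("need chains >= 1, warmup >= 1, draws >= 1000 per chain")
        if not 0 < self.tau_lower_bound < self.tau_upper_bound:
            raise ValueError("invalid tau bounds")


@dataclass(frozen=True)
class HierarchicalPosterior:
    """Joint posterior draws of theta, tau^2 and the per-study deltas."""

    theta_draws: np.ndarray
    tau2_draws: np.ndarray
    delta_draws: np.ndarray  # shape (n_draws, n_studies)
    study_ids: list[str]
    diagnostics: dict = field(repr=False)
    config: HierarchicalConfig = field(repr=False, default=HierarchicalConfig())

    def __post_init__(self) -> None:
        n = len(self.theta_draws)
        if len(self.tau2_draws) != n or self.delta_draws.shape[0] != n:
            raise ValueError("draw collections must have equal length")
        if not np.all(self.tau2_draws > 0):
            raise ValueError("tau^2 draws must be positive")

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def theta_summary(self, level: float = 0.95) -> PosteriorSummary:
        return summarize_draws(self.theta_draws, level=level, parameter="theta")

    def tau2_summary(self, level: float = 0.95) -> PosteriorSummary:
        return summarize_draws(self.tau2_draws, level=level, parameter="tau2")

    def delta_summary(self, index: int, level: float = 0.95) -> PosteriorSummary:
        return summarize_draws(
            self.delta_draws[:, index], level=level,
            parameter=f"delta[{self.study_ids[index]}]",
        )


# ---------------------------------------------------------------------------
# likelihood tabulation and marginalization


def _interp_uniform(x: np.ndarray, lo: float, h: float, ys: np.ndarray) -> np.ndarray:
    """Linear interpolation on a uniform grid (edge-clamped), no search."""
    idx = np.clip((x - lo) / h, 0.0, len(ys) - 1.000001)
    i = idx.astype(np.intp)
    f = idx - i
    return ys[i] * (1.0 - f) + ys[i + 1] * f


def _likelihood_grids(studies: tuple[TTestSummary, ...]):
    """Per-study log-likelihood of delta tabulated on a wide fine grid.

    Off-grid values are continued with a steep quadratic so interpolation
    never produces NaN; the continuation region carries negligible posterior
    mass (the grid spans the likelihood center +/- 12 standard errors and at
    least [-8, 8]).
    """
    grids = []
    for s in studies:
        d_hat = s.t / math.sqrt(s.n_eff)
        se = math.sqrt(1.0 / s.n_eff + d_hat * d_hat / (2.0 * s.nu))
        lo = min(d_hat - 12 * se, -8.0)
        hi = max(d_hat + 12 * se, 8.0)
        xs = np.linspace(lo, hi, 4001)
        ll = np.asarray(noncentral_t_logpdf(s.t, s.nu, xs * math.sqrt(s.n_eff)))
        bad = ~np.isfinite(ll)
        if np.any(bad):
            ll[bad] = -1e6 - (xs[bad] - d_hat) ** 2
        grids.append({"xs": xs, "ll": ll, "d_hat": d_hat, "se": se})
    return grids


def _smoothed_loglik(grid: dict, theta: np.ndarray, tau: float) -> np.ndarray:
    """log integral lik_s(delta) N(delta; theta, tau^2) d delta, all theta at once."""
    xs, ll = grid["xs"], grid["ll"]
    h = xs[1] - xs[0]
    shift = ll.max()
    lik = np.exp(ll - shift)
    span = xs[-1] - xs[0]
    if tau < 2.0 * h:
        # kernel narrower than the tabulation step: likelihood locally flat
        sm = lik
    elif tau > span / 4.0:
        # kernel wider than the tabulated support: dense evaluation is cheaper
        dens = np.exp(-0.5 * ((xs[None, :] - theta[:, None]) / tau) ** 2)
        dens /= tau * math.sqrt(2.0 * math.pi)
        val = dens @ lik * h
        return np.log(np.maximum(val, 1e-300)) + shift
    else:
        m = int(math.ceil(6.0 * tau / h))
        u = np.arange(-m, m + 1) * h
        ker = np.exp(-0.5 * (u / tau) ** 2)
        ker /= ker.sum()
        sm = fftconvolve(lik, ker, mode="same")
    val = np.interp(theta, xs, sm, left=0.0, right=0.0)
    return np.log(np.maximum(val, 1e-300)) + shift


def _log_tau_prior(tau: np.ndarray, ltau: np.ndarray, config: HierarchicalConfig):
    """Log prior density of log tau (Jacobian included), up to a constant."""
    if config.tau_prior == "half_cauchy":
        return -np.log1p((tau / config.tau_scale) ** 2) + ltau
    lb, ub = math.log(config.tau_lower_bound), math.log(config.tau_upper_bound)
    out = -ltau  # tau^-2 density times the tau = exp(ltau) Jacobian
    return np.where((ltau >= lb - 1e-12) & (ltau <= ub + 1e-12), out, -np.inf)


def _hyper_log_posterior(grids, theta_g, ltau_g, config):
    """log p(theta, log tau | data) on the grid, shape (n_ltau, n_theta)."""
    tau_g = np.exp(ltau_g)
    planes = np.empty((len(grids), len(ltau_g), len(theta_g)))
    for i, grid in enumerate(grids):
        for k, tau in enumerate(tau_g):
            planes[i, k] = _smoothed_loglik(grid, theta_g, tau)
    planes.sort(axis=0)  # study-order-independent summation
    lp = planes.sum(axis=0)
    lp += -np.log1p((theta_g[None, :] / config.theta_prior_scale) ** 2)
    lp += _log_tau_prior(tau_g, ltau_g, config)[:, None]
    return lp


def _refine_window(grid_vals, lp, margin=40.0, pad=1):
    """Smallest grid interval holding all points within ``margin`` of the peak."""
    prof = lp.max(axis=tuple(i for i in range(lp.ndim) if i != 0)) if lp.ndim > 1 else lp
    keep = np.flatnonzero(prof > prof.max() - margin)
    lo = max(keep.min() - pad, 0)
    hi = min(keep.max() + pad, len(grid_vals) - 1)
    return grid_vals[lo], grid_vals[hi]


def _hyper_grid(grids, config):
    """Adaptively refined (theta, log tau) grid with its log posterior."""
    d_hats = np.array([g["d_hat"] for g in grids])
    ses = np.array([g["se"] for g in grids])
    t_lo = float(min(d_hats.min() - 2 * ses.max(), -1.0))
    t_hi = float(max(d_hats.max() + 2 * ses.max(), 1.0))
    l_lo = math.log(config.tau_lower_bound)
    l_hi = math.log(config.tau_upper_bound)

    theta_g = np.linspace(t_lo, t_hi, 101)
    ltau_g = np.linspace(l_lo, l_hi, 61)
    for n_t, n_l in ((161, 91), (241, 121)):
        lp = _hyper_log_posterior(grids, theta_g, ltau_g, config)
        t_lo, t_hi = _refine_window(theta_g, lp.T)
        l_lo2, l_hi2 = _refine_window(ltau_g, lp)
        theta_g = np.linspace(t_lo, t_hi, n_t)
        ltau_g = np.linspace(l_lo2, l_hi2, n_l)
    lp = _hyper_log_posterior(grids, theta_g, ltau_g, config)
    return theta_g, ltau_g, lp


def _sample_hyper(theta_g, ltau_g, lp, n, rng):
    """Multinomial draws over grid cells with uniform within-cell jitter."""
    p = np.exp(lp - lp.max()).ravel()
    p /= p.sum()
    idx = rng.choice(p.size, size=n, p=p)
    k, j = np.unravel_index(idx, lp.shape)
    dt = theta_g[1] - theta_g[0]
    dl = ltau_g[1] - ltau_g[0]
    theta = theta_g[j] + rng.uniform(-0.5, 0.5, n) * dt
    ltau = np.clip(
        ltau_g[k] + rng.uniform(-0.5, 0.5, n) * dl, ltau_g[0], ltau_g[-1]
    )
    return theta, np.exp(ltau)


_COND_NODES = np.linspace(-8.0, 8.0, 49)


def _sample_delta(grid, theta, tau, rng):
    """Draw delta_s | theta, tau, t_s for every (theta, tau) pair at once.

    The conditional is lik_s(delta) * N(delta; theta, tau^2); nodes are laid
    across the precision-weighted product of the likelihood's normal pilot
    and the hierarchical kernel, then sampled by inverse CDF with linear
    jitter inside the chosen cell.
    """
    prec = 1.0 / grid["se"] ** 2 + 1.0 / tau**2
    w = 1.0 / np.sqrt(prec)
    c = (grid["d_hat"] / grid["se"] ** 2 + theta / tau**2) / prec
    nodes = c[:, None] + w[:, None] * _COND_NODES[None, :]
    xs = grid["xs"]
    logp = _interp_uniform(nodes, xs[0], xs[1] - xs[0], grid["ll"])
    logp += -0.5 * ((nodes - theta[:, None]) / tau[:, None]) ** 2
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    cdf = np.cumsum(p, axis=1)
    cdf /= cdf[:, -1:]
    u = rng.uniform(size=len(theta))
    pos = (cdf < u[:, None]).sum(axis=1)
    pos = np.clip(pos, 1, cdf.shape[1] - 1)
    c_hi = np.take_along_axis(cdf, pos[:, None], 1)[:, 0]
    c_lo = np.take_along_axis(cdf, (pos - 1)[:, None], 1)[:, 0]
    frac = np.where(c_hi > c_lo, (u - c_lo) / np.maximum(c_hi - c_lo, 1e-300), 0.5)
    x_hi = np.take_along_axis(nodes, pos[:, None], 1)[:, 0]
    x_lo = np.take_along_axis(nodes, (pos - 1)[:, None], 1)[:, 0]
    return x_lo + frac * (x_hi - x_lo)


def fit_meta(studies: StudySet, config: HierarchicalConfig | None = None) -> HierarchicalPosterior:
    """Sample the joint posterior of (theta, tau^2, delta_1..S).

    Draws ``config.chains`` independent streams of ``config.draws`` exact
    composition samples each.  Convergence gates (split-R-hat <= 1.01,
    effective sample size >= 400 on every reported parameter) are checked
    across chains and reported in ``diagnostics``; violations raise a
    warning but still return the draws.
    """
    config = config or HierarchicalConfig()
    if len(studies) < 2:
        raise ValueError("heterogeneity needs at least 2 studies")
    S = len(studies)
    grids = _likelihood_grids(studies.studies)
    theta_g, ltau_g, lp = _hyper_grid(grids, config)

    chain_theta, chain_tau, chain_delta = [], [], []
    for chain in range(config.chains):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, chain, 0]))
        theta, tau = _sample_hyper(theta_g, ltau_g, lp, config.draws, rng)
        delta = np.empty((config.draws, S))
        for j, (sid, grid) in enumerate(zip(studies.study_ids, grids)):
            key = zlib.crc32(str(sid).encode())
            srng = np.random.default_rng(
                np.random.SeedSequence([config.seed, chain, 1, key])
            )
            delta[:, j] = _sample_delta(grid, theta, tau, srng)
        chain_theta.append(theta)
        chain_tau.append(tau)
        chain_delta.append(delta)

    theta_c = np.stack(chain_theta)  # (chains, draws)
    tau_c = np.stack(chain_tau)
    delta_c = np.stack(chain_delta)  # (chains, draws, S)

    diagnostics = _diagnose(theta_c, np.log(tau_c), delta_c, config)
    post = HierarchicalPosterior(
        theta_draws=theta_c.reshape(-1),
        tau2_draws=(tau_c**2).reshape(-1),
        delta_draws=delta_c.reshape(-1, S),
        study_ids=studies.study_ids,
        diagnostics=diagnostics,
        config=config,
    )
    if not post.converged:
        warnings.warn(
            "hierarchical fit failed convergence gates: "
            + "; ".join(diagnostics["warnings"]),
            RuntimeWarning,
            stacklevel=2,
        )
    return post


def _diagnose(theta_c, ltau_c, delta_c, config):
    """Split-R-hat and effective sample size across independent chains."""
    rhat = {
        name: float(np.asarray(az.rhat(az.convert_to_dataset(arr))["x"].values))
        for name, arr in (("theta", theta_c), ("log_tau", ltau_c))
    }
    if delta_c.shape[0] > 1 or delta_c.shape[1] > 1:
        rhat["delta_max"] = float(
            np.max(az.rhat(az.convert_to_dataset(delta_c))["x"].values)
        )
    ess = {
        name: float(np.asarray(az.ess(az.convert_to_dataset(arr))["x"].values))
        for name, arr in (("theta", theta_c), ("log_tau", ltau_c))
    }
    msgs = [f"R-hat({k}) = {v:.3f} > 1.01" for k, v in rhat.items() if v > 1.01]
    msgs += [f"ESS({k}) = {v:.0f} < 400" for k, v in ess.items() if v < 400]
    return {
        "rhat": rhat,
        "ess": ess,
        "converged": not msgs,
        "warnings": msgs,
        "sampler": "grid-composition",
        "tau_prior": config.tau_prior,
        "seed": config.seed,
    }


def shrinkage_table(
    post: HierarchicalPosterior, individual: list[PosteriorSummary]
) -> pd.DataFrame:
    """Pair hierarchical and individual per-study summaries.

    The shrinkage fraction is 1 - |hier_median - theta_hat| /
    |indiv_median - theta_hat| with theta_hat the posterior median of the
    group mean (0 when the individual median already sits on theta_hat):
    1 means fully pulled onto the group mean, 0 means no pooling.
    """
    if len(individual) != len(post.study_ids):
        raise ValueError("one individual summary per study is required")
    theta_hat = float(np.median(post.theta_draws))
    rows = []
    for idx, (sid, ind) in enumerate(zip(post.study_ids, individual)):
        hier = post.delta_summary(idx)
        denom = abs(ind.median - theta_hat)
        shrink = 0.0 if denom < 1e-6 else 1.0 - abs(hier.median - theta_hat) / denom
        rows.append(
            {
                "study_id": sid,
                "indiv_median": ind.median,
                "indiv_lo": ind.ci_low,
                "indiv_hi": ind.ci_high,
                "hier_median": hier.median,
                "hier_lo": hier.ci_low,
                "hier_hi": hier.ci_high,
                "shrinkage": shrink,
            }
        )
    return pd.DataFrame(rows)
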