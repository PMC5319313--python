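"""Shared fixtures and independent numerical oracles.

The oracles deliberately avoid the code paths they check: the Bayes-factor
oracle integrates over the inverse-gamma mixing representation of the
Cauchy prior (never touching the noncentral-t density), and the posterior
oracle is a plain random-walk Metropolis sampler.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import integrate, stats

import repbayes as rb


@pytest.fixture(scope="session")
def anchor():
    """The worked-example study: t(85) = 4.178 from groups of 18 and 69."""
    return rb.TTestSummary(t=4.178, n1=18, n2=69)


def bf10_gmixture(t: float, n1: int, n2: int, r: float) -> float:
    """JZS BF10 via the g-mixture route: delta | g ~ N(0, g r^2),
    g ~ InvGamma(1/2, 1/2).

    Marginalizing delta analytically gives a closed form for p(t | g), so
    this path never evaluates a noncentral-t density -- it is independent
    of the implementation's likelihood-times-prior quadrature.
    """
    nu = n1 + n2 - 2 if n2 > 0 else n1 - 1
    neff = n1 * n2 / (n1 + n2) if n2 > 0 else float(n1)

    def p_t_given_v(v: float) -> float:
        a = 1.0 + neff * v
        return a**-0.5 * (1.0 + t * t / (nu * a)) ** (-(nu + 1) / 2)

    def f(g: float) -> float:
        ig = g**-1.5 * math.exp(-1.0 / (2.0 * g)) / math.sqrt(2.0 * math.pi)
        return p_t_given_v(g * r * r) * ig

    val, _ = integrate.quad(f, 0.0, np.inf, epsabs=0.0, epsrel=1e-11, limit=400)
    return val / p_t_given_v(0.0)


def rwm_delta_draws(summary: rb.TTestSummary, width_r: float, n_draws: int,
                    seed: int) -> np.ndarray:
    """Random-walk Metropolis draws from the delta posterior (MCMC oracle).

    Runs 50 parallel chains with a Gaussian proposal; returns the pooled
    post-warmup draws (>= n_draws of them).
    """
    rng = np.random.default_rng(seed)
    n_chains = 50
    d_hat = summary.t / math.sqrt(summary.n_eff)
    se = math.sqrt(1.0 / summary.n_eff + d_hat * d_hat / (2.0 * summary.nu))
    step = 2.4 * se

    def logpost(d: np.ndarray) -> np.ndarray:
        return (
            stats.nct.logpdf(summary.t, summary.nu, d * math.sqrt(summary.n_eff))
            + stats.cauchy.logpdf(d, scale=width_r)
        )

    warmup = 500
    steps = warmup + math.ceil(n_draws / n_chains)
    cur = d_hat + rng.normal(0.0, se, n_chains)
    cur_lp = logpost(cur)
    out = []
    for it in range(steps):
        prop = cur + rng.normal(0.0, step, n_chains)
        prop_lp = logpost(prop)
        accept = np.log(rng.uniform(size=n_chains)) < prop_lp - cur_lp
        cur = np.where(accept, prop, cur)
        cur_lp = np.where(accept, prop_lp, cur_lp)
        if it >= warmup:
            out.append(cur.copy())
    return np.concatenate(out)


def random_ttest_summaries(n: int, seed: int, t_max: float = 6.0,
                           n_max: int = 200) -> list[rb.TTestSummary]:
    """Randomized small t-test instances for identity/oracle sweeps."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        t = float(rng.uniform(-t_max, t_max))
        if rng.random() < 0.5:
            out.append(rb.TTestSummary(t=t, n1=int(rng.integers(5, n_max + 1))))
        else:
            out.append(
                rb.TTestSummary(
                    t=t,
                    n1=int(rng.integers(5, n_max // 2 + 1)),
                    n2=int(rng.integers(5, n_max // 2 + 1)),
                )
            )
    return out
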