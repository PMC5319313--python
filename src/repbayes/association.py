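"""Posteriors and Bayes factors for correlations, and Cramér's phi^2 for tables.

Correlations use the exact (Fisher) sampling density of the observed Pearson
r given the population correlation rho and sample size n, combined with a
stretched-beta prior on rho of width ``kappa`` (kappa = 1 is uniform on
(-1, 1)), the default-Bayes-factor family for correlation tests.

Contingency tables get a posterior for Cramér's phi^2 by Monte Carlo: cell
probabilities are drawn from the Dirichlet posterior under a joint
multinomial scheme, and phi^2 is computed per draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

from .posterior import PosteriorSummary, summarize_draws, summarize_grid

__all__ = [
    "CorrelationSummary",
    "ContingencyTable",
    "rho_posterior",
    "bf_correlation",
    "phi2_posterior",
    "cramers_phi2",
]


@dataclass(frozen=True)
class CorrelationSummary:
    """Observed Pearson correlation with its sample size."""

    r_obs: float
    n: int
    predicted_direction: int = 1
    study_id: str = ""

    def __post_init__(self) -> None:
        if not -1.0 < self.r_obs < 1.0:
            raise ValueError("observed correlation must lie in (-1, 1)")
        if self.n < 3:
            raise ValueError("need n >= 3 observations")
        if self.predicted_direction not in (-1, 1):
            raise ValueError("predicted_direction must be +1 or -1")


@dataclass(frozen=True)
class ContingencyTable:
    """R x C table of nonnegative integer counts (R, C >= 2)."""

    counts: np.ndarray
    study_id: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("table must be at least 2x2")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if counts.sum() < 1:
            raise ValueError("table has no observations")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def sample_corr_logpdf(r, rho, n: int):
    """Exact log-density of the sample correlation of n bivariate-normal pairs.

    Uses the hypergeometric form with argument (1 + rho*r)/2, which stays in
    (0, 1) and is numerically tame for n up to the thousands.  Broadcasts
    over ``r`` and ``rho``.
    """
    r = np.asarray(r, dtype=float)
    rho = np.asarray(rho, dtype=float)
    lognum = (
        math.log(n - 2)
        + special.gammaln(n - 1)
        + (n - 1) / 2.0 * np.log1p(-rho * rho)
        + (n - 4) / 2.0 * np.log1p(-r * r)
    )
    logden = (
        0.5 * math.log(2 * math.pi)
        + special.gammaln(n - 0.5)
        + (n - 1.5) * np.log1p(-rho * r)
    )
    out = lognum - logden + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2))
    return float(out) if out.ndim == 0 else out


def _stretched_beta_logpdf(rho, kappa: float) -> np.ndarray:
    """Stretched-beta prior on rho in (-1, 1): rho = 2B - 1, B ~ Beta(1/k, 1/k)."""
    a = 1.0 / kappa
    rho = np.asarray(rho, dtype=float)
    return stats.beta.logpdf((rho + 1.0) / 2.0, a, a) - math.log(2.0)


def _rho_grid(n_grid: int = 8001) -> np.ndarray:
    eps = 5e-7
    return np.linspace(-1.0 + eps, 1.0 - eps, n_grid)


def rho_posterior(
    summary: CorrelationSummary, kappa: float = 1.0, side: str = "both",
    level: float = 0.95,
) -> PosteriorSummary:
    """Grid-quadrature posterior of the population correlation rho."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    grid = _rho_grid()
    logp = sample_corr_logpdf(summary.r_obs, grid, summary.n) + _stretched_beta_logpdf(
        grid, kappa
    )
    if side == "positive":
        logp = np.where(grid >= 0, logp, -np.inf)
    elif side == "negative":
        logp = np.where(grid <= 0, logp, -np.inf)
    elif side != "both":
        raise ValueError("side must be 'both', 'positive' or 'negative'")
    logp = logp - logp.max()
    return summarize_grid(
        grid, np.exp(logp), level=level, parameter="rho", kappa=kappa, side=side
    )


def bf_correlation(
    summary: CorrelationSummary, kappa: float = 1.0, side: str = "both"
) -> float:
    """Default Bayes factor for a nonzero correlation against rho = 0.

    BF10 integrates the exact r-density against the stretched-beta prior and
    divides by the density at rho = 0; one-sided variants use the posterior
    mass-ratio identity with prior sign probability 1/2.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    log_shift = float(sample_corr_logpdf(summary.r_obs, 0.0, summary.n))

    def f(rho: float) -> float:
        return math.exp(
            float(sample_corr_logpdf(summary.r_obs, rho, summary.n)) - log_shift
            + float(_stretched_beta_logpdf(rho, kappa))
        )

    m_neg, _ = integrate.quad(f, -1.0, 0.0, epsabs=0.0, epsrel=1e-10, limit=300)
    m_pos, _ = integrate.quad(f, 0.0, 1.0, epsabs=0.0, epsrel=1e-10, limit=300)
    m1 = m_neg + m_pos
    bf10 = m1  # the shift is exactly the null log-density
    if side == "both":
        return float(bf10)
    if side == "positive":
        return float(bf10 * (m_pos / m1) / 0.5)
    if side == "negative":
        return float(bf10 * (m_neg / m1) / 0.5)
    raise ValueError("side must be 'both', 'positive' or 'negative'")


def cramers_phi2(p: np.ndarray) -> np.ndarray:
    """Cramér's phi^2 of one or many probability tables.

    ``p`` has shape (..., R, C); each slice must sum to 1.  phi^2 is the
    chi-square-style divergence of the joint from independence, scaled to
    [0, 1] by min(R, C) - 1.
    """
    p = np.asarray(p, dtype=float)
    rows = p.sum(axis=-1, keepdims=True)
    cols = p.sum(axis=-2, keepdims=True)
    expected = rows * cols
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, (p - expected) ** 2 / expected, 0.0)
    k = min(p.shape[-1], p.shape[-2]) - 1
    return cells.sum(axis=(-1, -2)) / k


def phi2_posterior(
    table: ContingencyTable, alpha: float = 1.0, n_draws: int = 50_000,
    seed: int | np.random.Generator = 0, level: float = 0.95,
) -> PosteriorSummary:
    """Monte-Carlo posterior of Cramér's phi^2 under a Dirichlet prior.

    Joint multinomial sampling scheme: the flattened cell-probability vector
    gets a symmetric Dirichlet(alpha) prior, so the posterior is
    Dirichlet(counts + alpha); phi^2 is evaluated per draw.
    """
    if alpha <= 0:
        raise ValueError("Dirichlet concentration alpha must be positive")
    if n_draws < 1:
        raise ValueError("need at least one draw")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = table.counts.shape
    conc = table.counts.ravel() + alpha
    draws = rng.dirichlet(conc, size=n_draws).reshape(n_draws, *shape)
    phi2 = cramers_phi2(draws)
    return summarize_draws(
        phi2, level=level, parameter="phi2", alpha=alpha, scheme="joint_multinomial"
    )
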