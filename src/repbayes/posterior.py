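"""Posterior summaries for scalar effect-size parameters.

A posterior is reported the same way everywhere in this package: by its
median and a central (equal-tail) credible interval, together with the
grid or draws it was computed from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PosteriorSummary", "summarize_grid", "summarize_draws"]


@dataclass(frozen=True)
class PosteriorSummary:
    """Median + central credible interval for one scalar parameter.

    ``grid``/``density`` hold a normalized grid representation when the
    posterior was computed by quadrature; ``draws`` holds Monte-Carlo
    samples when it was computed by simulation.  Exactly one of the two
    representations is populated.
    """

    median: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    grid: np.ndarray | None = field(default=None, repr=False)
    density: np.ndarray | None = field(default=None, repr=False)
    draws: np.ndarray | None = field(default=None, repr=False)
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.median <= self.ci_high):
            raise ValueError("require ci_low <= median <= ci_high")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` samples (inverse-CDF on the grid, or resample draws)."""
        if self.draws is not None:
            return rng.choice(self.draws, size=n, replace=True)
        if self.grid is None or self.density is None:
            raise ValueError("no grid or draws stored")
        cdf = _grid_cdf(self.grid, self.density)
        u = rng.uniform(cdf[0], cdf[-1], size=n)
        return np.interp(u, cdf, self.grid)


def _grid_cdf(x: np.ndarray, pdf: np.ndarray) -> np.ndarray:
    dx = np.diff(x)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * dx)])
    return cdf / cdf[-1]


def summarize_grid(
    x: np.ndarray, density: np.ndarray, level: float = 0.95, **meta
) -> PosteriorSummary:
    """Summarize a density known on an ordered grid.

    The density is renormalized by the trapezoid rule; quantiles are read
    off the interpolated CDF (which also breaks ties for the median).
    """
    x = np.asarray(x, float)
    density = np.asarray(density, float)
    if x.ndim != 1 or x.shape != density.shape or x.size < 3:
        raise ValueError("grid and density must be matching 1-D arrays, size >= 3")
    norm = np.trapezoid(density, x)
    if not norm > 0:
        raise ValueError("density does not normalize")
    density = density / norm
    cdf = _grid_cdf(x, density)
    alpha = (1.0 - level) / 2.0
    lo, med, hi = np.interp([alpha, 0.5, 1.0 - alpha], cdf, x)
    return PosteriorSummary(
        median=float(med),
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        grid=x,
        density=density,
        meta=meta,
    )


def summarize_draws(draws: np.ndarray, level: float = 0.95, **meta) -> PosteriorSummary:
    """Summarize Monte-Carlo draws by empirical quantiles."""
    draws = np.asarray(draws, float).ravel()
    if draws.size == 0:
        raise ValueError("empty draw set")
    alpha = (1.0 - level) / 2.0
    lo, med, hi = np.quantile(draws, [alpha, 0.5, 1.0 - alpha])
    return PosteriorSummary(
        median=float(med),
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        draws=draws,
        meta=meta,
    )
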