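"""Synthetic study sets with the generative structure the hierarchy assumes.

Each simulated study draws its true standardized effect from
Normal(theta, tau^2), picks a design (one- or two-sample) and group sizes,
and then draws an observed t-statistic from the noncentral-t sampling
distribution with noncentrality delta * sqrt(n_eff).  The hidden truths are
returned separately from the observable summaries so recovery tests cannot
accidentally leak them into a pipeline.

Defaults mirror the setting the package targets: 38 modestly powered
social-psychology replication t-tests (group sizes 20-120, mostly
independent-groups designs) with a small group mean (theta = 0.05) and
small heterogeneity (tau = 0.14, i.e. tau^2 ~ 0.02).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .jzs import TTestSummary
from .meta import StudySet

__all__ = ["SimulationConfig", "simulate_studies", "fixture_special_issue_like"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for a synthetic set of t-test studies."""

    n_studies: int = 38
    theta: float = 0.05
    tau: float = 0.14
    design_mix: float = 0.8  # probability of a two-sample design
    n_range: tuple[int, int] = (20, 120)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("need at least one study")
        if self.tau < 0:
            raise ValueError("heterogeneity tau must be >= 0")
        if not 0.0 <= self.design_mix <= 1.0:
            raise ValueError("design_mix is a probability")
        lo, hi = self.n_range
        if not (3 <= lo <= hi <= 10_000):
            raise ValueError("group sizes must lie within [3, 10000]")


def simulate_studies(config: SimulationConfig | None = None) -> tuple[StudySet, pd.DataFrame]:
    """Draw a study set plus its hidden truth record; deterministic given seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.n_range
    studies, truths = [], []
    for s in range(config.n_studies):
        delta = config.theta + config.tau * rng.standard_normal()
        two_sample = rng.random() < config.design_mix
        if two_sample:
            n1 = int(rng.integers(lo, hi + 1))
            n2 = int(rng.integers(lo, hi + 1))
        else:
            n1 = int(rng.integers(lo, hi + 1))
            n2 = 0
        summary = TTestSummary(t=0.0, n1=n1, n2=n2, study_id=f"sim_{s + 1:03d}")
        t = float(
            stats.nct.rvs(summary.nu, delta * np.sqrt(summary.n_eff), random_state=rng)
        )
        studies.append(
            TTestSummary(t=t, n1=n1, n2=n2, predicted_direction=1,
                         study_id=summary.study_id)
        )
        truths.append(
            {"study_id": summary.study_id, "delta_true": delta,
             "n1": n1, "n2": n2, "theta": config.theta, "tau": config.tau}
        )
    return StudySet(tuple(studies)), pd.DataFrame(truths)


#: Worked-example anchor: t(85) = 4.178 from an 18 vs 69 two-group comparison.
ANCHOR_STUDY = TTestSummary(t=4.178, n1=18, n2=69, predicted_direction=1,
                            study_id="ijzerman_study1")


def fixture_special_issue_like() -> StudySet:
    """Deterministic 38-study t-test set shaped like the replication corpus.

    The first entry is the worked-example anchor study (t = 4.178, n1 = 18,
    n2 = 69); the remaining 37 are fixed draws from the hierarchical
    generative model at theta = 0.05, tau = 0.14 with group sizes 20-130.
    """
    cfg = SimulationConfig(
        n_studies=37, theta=0.05, tau=0.14, design_mix=0.8, n_range=(20, 130),
        seed=160426,
    )
    rest, _ = simulate_studies(cfg)
    return StudySet((ANCHOR_STUDY,) + rest.studies)
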