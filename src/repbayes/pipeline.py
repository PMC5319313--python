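"""Batch runner: read study summaries, analyse each, tally the evidence.

The input is one CSV row per analysis (t-test, correlation or contingency
table).  Every row gets the default-prior Bayes factor in its predicted
direction (where defined), effect-size posteriors on the directed and the
variance-explained scale, and interval flags; the report aggregates the
flags and the Jeffreys evidence categories.  Failures are isolated per row:
one malformed study must not kill a 60-analysis batch.
"""

from __future__ import annotations

import enum
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    ContingencyTable,
    CorrelationSummary,
    bf_correlation,
    phi2_posterior,
    rho_posterior,
)
from .jzs import (
    DEFAULT_PRIOR_WIDTH,
    BayesFactorResult,
    PriorSpec,
    TTestSummary,
    bf_onesided_ttest,
    delta_posterior,
    rho2_from_delta,
)
from .meta import HierarchicalConfig, StudySet, fit_meta, shrinkage_table
from .posterior import summarize_draws

__all__ = [
    "StudyRecord",
    "EvidenceCategory",
    "PipelineConfig",
    "ReportTable",
    "classify_evidence",
    "read_studies_csv",
    "write_studies_csv",
    "records_from_studies",
    "studyset_from_records",
    "run_pipeline",
]

TEST_TYPES = ("one_sample_t", "two_sample_t", "correlation", "contingency")

_REQUIRED = {
    "one_sample_t": ("t", "n1"),
    "two_sample_t": ("t", "n1", "n2"),
    "correlation": ("r_obs", "n1"),
    "contingency": ("table",),
}


@dataclass(frozen=True)
class StudyRecord:
    """One analysis row; only the fields its test type needs are set."""

    study_id: str
    test_type: str
    t: float | None = None
    n1: int | None = None
    n2: int | None = None
    r_obs: float | None = None
    table: np.ndarray | None = None
    direction: int = 1

    def __post_init__(self) -> None:
        if self.test_type not in TEST_TYPES:
            raise ValueError(f"{self.study_id}: unknown test_type {self.test_type!r}")
        if self.direction not in (-1, 1):
            raise ValueError(f"{self.study_id}: direction must be +1 or -1")
        for col in _REQUIRED[self.test_type]:
            if getattr(self, col) is None:
                raise ValueError(
                    f"{self.study_id}: test_type {self.test_type} requires column {col!r}"
                )


class EvidenceCategory(enum.Enum):
    """Jeffreys evidence bands with symmetric boundaries {1, 3, 10, 30, 100}."""

    EXTREME_H1 = "extreme_H1"
    VERY_STRONG_H1 = "very_strong_H1"
    STRONG_H1 = "strong_H1"
    MODERATE_H1 = "moderate_H1"
    ANECDOTAL_H1 = "anecdotal_H1"
    NONE = "none"
    ANECDOTAL_H0 = "anecdotal_H0"
    MODERATE_H0 = "moderate_H0"
    STRONG_H0 = "strong_H0"
    VERY_STRONG_H0 = "very_strong_H0"
    EXTREME_H0 = "extreme_H0"


_H1_BANDS = [(100.0, EvidenceCategory.EXTREME_H1),
             (30.0, EvidenceCategory.VERY_STRONG_H1),
             (10.0, EvidenceCategory.STRONG_H1),
             (3.0, EvidenceCategory.MODERATE_H1),
             (1.0, EvidenceCategory.ANECDOTAL_H1)]


def classify_evidence(bf: float | BayesFactorResult) -> EvidenceCategory:
    """Map a Bayes factor to its Jeffreys category.

    Boundary values go to the weaker (closer to 'none') category: BF = 3 is
    still anecdotal for H1, BF = 1/3 still anecdotal for H0; BF = 1 is exact
    indifference.
    """
    value = bf.value if isinstance(bf, BayesFactorResult) else float(bf)
    if not value > 0:
        raise ValueError("Bayes factor must be positive")
    if value == 1.0:
        return EvidenceCategory.NONE
    flip = value < 1.0
    v = 1.0 / value if flip else value
    for bound, cat in _H1_BANDS:
        if v > bound:
            return EvidenceCategory[cat.name.replace("_H1", "_H0")] if flip else cat
    return EvidenceCategory.ANECDOTAL_H0 if flip else EvidenceCategory.ANECDOTAL_H1


# ---------------------------------------------------------------------------
# CSV I/O

_COLUMNS = ["study_id", "test_type", "t", "n1", "n2", "r_obs", "table", "direction"]


def _parse_table(text: str) -> np.ndarray:
    """Parse counts: rows separated by '|', cells by ';' (plain 'a;b;c;d' = 2x2)."""
    if "|" in text:
        rows = [[int(v) for v in row.split(";")] for row in text.split("|")]
    else:
        vals = [int(v) for v in text.split(";")]
        if len(vals) != 4:
            raise ValueError("flat table must have 4 cells (2x2 row-major)")
        rows = [vals[:2], vals[2:]]
    return np.asarray(rows, dtype=int)


def _format_table(table: np.ndarray) -> str:
    return "|".join(";".join(str(int(v)) for v in row) for row in np.asarray(table))


def read_studies_csv(path) -> list[StudyRecord]:
    """Read and validate study records; errors cite the row id and column."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("study_id", "test_type") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records, errors = [], []
    for i, row in df.iterrows():
        sid = row.get("study_id", f"row {i + 2}")
        try:
            def cell(col, cast):
                val = row.get(col)
                if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
                    return None
                return cast(val)

            records.append(
                StudyRecord(
                    study_id=str(sid),
                    test_type=str(row["test_type"]),
                    t=cell("t", float),
                    n1=cell("n1", lambda v: int(float(v))),
                    n2=cell("n2", lambda v: int(float(v))),
                    r_obs=cell("r_obs", float),
                    table=cell("table", _parse_table),
                    direction=cell("direction", lambda v: int(float(v))) or 1,
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {i + 2} (study_id={sid}): {exc}")
    if errors:
        raise ValueError("invalid study rows:\n" + "\n".join(errors))
    return records


def write_studies_csv(records: list[StudyRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "test_type": r.test_type,
                "t": r.t,
                "n1": r.n1,
                "n2": r.n2,
                "r_obs": r.r_obs,
                "table": _format_table(r.table) if r.table is not None else None,
                "direction": r.direction,
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def records_from_studies(studies: StudySet) -> list[StudyRecord]:
    """Represent a t-test study set as pipeline records."""
    out = []
    for s in studies.studies:
        out.append(
            StudyRecord(
                study_id=s.study_id,
                test_type="two_sample_t" if s.two_sample else "one_sample_t",
                t=s.t,
                n1=s.n1,
                n2=s.n2 if s.two_sample else None,
                direction=s.predicted_direction,
            )
        )
    return out


def studyset_from_records(records: list[StudyRecord]) -> StudySet:
    """Collect the t-test rows of a record list into a StudySet."""
    studies = []
    for r in records:
        if r.test_type not in ("one_sample_t", "two_sample_t"):
            continue
        studies.append(
            TTestSummary(
                t=r.t, n1=r.n1, n2=r.n2 or 0,
                predicted_direction=r.direction, study_id=r.study_id,
            )
        )
    return StudySet(tuple(studies))


# ---------------------------------------------------------------------------
# the batch run


@dataclass(frozen=True)
class PipelineConfig:
    """Settings shared by every row of a batch run."""

    prior_width: float = DEFAULT_PRIOR_WIDTH
    kappa: float = 1.0
    alpha: float = 1.0
    level: float = 0.95
    n_draws: int = 20_000
    seed: int = 0
    with_meta: bool = False
    meta: HierarchicalConfig | None = None


@dataclass(frozen=True)
class ReportTable:
    """Per-study rows plus aggregate tallies and run metadata."""

    rows: pd.DataFrame
    tallies: dict
    metadata: dict = field(default_factory=dict)

    def check_consistency(self) -> None:
        """Every aggregate count must equal the sum of its row indicators."""
        ok = self.rows[self.rows["error"].isna()]
        for flag in ("ci_excludes_zero", "rho2_above_0_05", "rho2_above_0_10"):
            expect = int((ok[flag] == True).sum())  # noqa: E712 - column may hold None
            if self.tallies[f"n_{flag}"] != expect:
                raise AssertionError(f"tally n_{flag} inconsistent with rows")
        cats = ok["category"].dropna().value_counts().to_dict()
        if self.tallies["categories"] != cats:
            raise AssertionError("category tallies inconsistent with rows")

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def to_json(self, path=None):
        payload = {
            "tallies": self.tallies,
            "metadata": self.metadata,
            "rows": json.loads(self.rows.to_json(orient="records")),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def _row_rng(seed: int, study_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(study_id.encode())])
    )


def _analyse_ttest(rec: StudyRecord, cfg: PipelineConfig, rng) -> dict:
    # recode so the predicted direction is positive (forest-plot convention)
    summary = TTestSummary(
        t=rec.t * rec.direction, n1=rec.n1, n2=rec.n2 or 0, study_id=rec.study_id
    )
    prior = PriorSpec(width_r=cfg.prior_width)
    bf = bf_onesided_ttest(summary, prior, side="positive")
    post = delta_posterior(summary, prior, level=cfg.level)
    draws = post.sample(cfg.n_draws, rng)
    rho2 = rho2_from_delta(draws, summary.n1, summary.n2, level=cfg.level)
    return {
        "bf": bf.value,
        "bf_pair": bf.pair,
        "es_median": post.median,
        "es_lo": post.ci_low,
        "es_hi": post.ci_high,
        "rho2_median": rho2.median,
        "rho2_lo": rho2.ci_low,
        "rho2_hi": rho2.ci_high,
        "ci_excludes_zero": bool(post.ci_low > 0),
    }


def _analyse_correlation(rec: StudyRecord, cfg: PipelineConfig, rng) -> dict:
    summary = CorrelationSummary(
        r_obs=rec.r_obs * rec.direction, n=rec.n1, study_id=rec.study_id
    )
    bf = bf_correlation(summary, kappa=cfg.kappa, side="positive")
    post = rho_posterior(summary, kappa=cfg.kappa, level=cfg.level)
    rho_draws = post.sample(cfg.n_draws, rng)
    rho2 = summarize_draws(rho_draws**2, level=cfg.level, parameter="rho2")
    return {
        "bf": bf,
        "bf_pair": "+0",
        "es_median": post.median,
        "es_lo": post.ci_low,
        "es_hi": post.ci_high,
        "rho2_median": rho2.median,
        "rho2_lo": rho2.ci_low,
        "rho2_hi": rho2.ci_high,
        "ci_excludes_zero": bool(post.ci_low > 0),
    }


def _analyse_contingency(rec: StudyRecord, cfg: PipelineConfig, rng) -> dict:
    table = ContingencyTable(rec.table, study_id=rec.study_id)
    post = phi2_posterior(
        table, alpha=cfg.alpha, n_draws=cfg.n_draws, seed=rng, level=cfg.level
    )
    # phi^2 is undirected and its default Bayes factor is out of scope here
    return {
        "bf": np.nan,
        "bf_pair": None,
        "es_median": np.nan,
        "es_lo": np.nan,
        "es_hi": np.nan,
        "rho2_median": post.median,
        "rho2_lo": post.ci_low,
        "rho2_hi": post.ci_high,
        "ci_excludes_zero": None,
    }


_DISPATCH = {
    "one_sample_t": _analyse_ttest,
    "two_sample_t": _analyse_ttest,
    "correlation": _analyse_correlation,
    "contingency": _analyse_contingency,
}


def run_pipeline(records: list[StudyRecord], config: PipelineConfig | None = None) -> ReportTable:
    """Analyse every record, classify evidence, aggregate flag tallies.

    Per-row failures land in the ``error`` column instead of aborting the
    batch, and the tallies count successful rows only.  With
    ``config.with_meta`` the t-test subset additionally gets hierarchical
    (shrinkage) columns from the random-effects fit.
    """
    config = config or PipelineConfig()
    if not records:
        raise ValueError("need at least one study record")
    rows = []
    for rec in records:
        base = {"study_id": rec.study_id, "test_type": rec.test_type, "error": None}
        try:
            rng = _row_rng(config.seed, rec.study_id)
            res = _DISPATCH[rec.test_type](rec, config, rng)
            bf = res["bf"]
            res["category"] = (
                classify_evidence(bf).value if np.isfinite(bf) else None
            )
            base.update(res)
        except Exception as exc:  # noqa: BLE001 - row isolation is the contract
            base["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(base)
    df = pd.DataFrame(rows)
    for col in ("bf", "es_median", "es_lo", "es_hi",
                "rho2_median", "rho2_lo", "rho2_hi"):
        if col not in df:
            df[col] = np.nan
    for col in ("ci_excludes_zero", "category"):
        if col not in df:
            df[col] = None
    ok_row = df["error"].isna()
    df["rho2_above_0_05"] = np.where(ok_row, df["rho2_hi"] > 0.05, None)
    df["rho2_above_0_10"] = np.where(ok_row, df["rho2_hi"] > 0.10, None)

    meta_diag = None
    if config.with_meta:
        tset = studyset_from_records(
            [r for r in records if r.test_type.endswith("_t")]
        ).recode_positive()
        if len(tset) >= 2:
            mcfg = config.meta or HierarchicalConfig(seed=config.seed)
            post = fit_meta(tset, mcfg)
            indiv = [
                delta_posterior(s, PriorSpec(width_r=config.prior_width),
                                level=config.level)
                for s in tset.studies
            ]
            shrink = shrinkage_table(post, indiv).drop(
                columns=["indiv_median", "indiv_lo", "indiv_hi"]
            )
            df = df.merge(shrink, on="study_id", how="left")
            meta_diag = post.diagnostics

    ok = df[df["error"].isna()]
    tallies = {
        "n_rows": int(len(df)),
        "n_failed": int(df["error"].notna().sum()),
        "n_ci_excludes_zero": int((ok["ci_excludes_zero"] == True).sum()),  # noqa: E712
        "n_rho2_above_0_05": int((ok["rho2_above_0_05"] == True).sum()),  # noqa: E712
        "n_rho2_above_0_10": int((ok["rho2_above_0_10"] == True).sum()),  # noqa: E712
        "categories": ok["category"].dropna().value_counts().to_dict(),
    }
    metadata = {
        "package_version": __version__,
        "prior_width": config.prior_width,
        "kappa": config.kappa,
        "alpha": config.alpha,
        "level": config.level,
        "seed": config.seed,
        "with_meta": bool(config.with_meta),
        "meta_diagnostics": meta_diag,
    }
    report = ReportTable(rows=df, tallies=tallies, metadata=metadata)
    report.check_consistency()
    return report
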