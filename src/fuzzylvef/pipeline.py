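"""End-to-end study orchestration.

Reproduces the study design on synthetic (or user-supplied) cohorts:

* interval comparison — which post-admission window (first hour, 0-6 h,
  6-12 h, ...) best predicts severely depressed LVEF;
* full study — equal-size feature-selection / model-assessment split,
  repeated SFS with consensus on the FS half, repeated stratified CV of
  the consensus model on the MA half, and a final serialized model.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .cohort import CohortSpec, default_cohort_spec, generate_cohort, generate_timed_measurements
from .evaluation import CVReport, repeated_stratified_cv, two_sample_ttest
from .logistic import LogisticClassifier
from .preprocessing import (
    CohortTable,
    aggregate_interval,
    filter_physiologic_outliers,
    fs_ma_split,
    min_max_normalize,
)
from .selection import consensus_features, run_repeated_sfs, selection_frequencies
from .ts import TakagiSugenoClassifier

__all__ = [
    "StudyConfig",
    "StudyReport",
    "make_builder",
    "run_interval_comparison",
    "run_full_study",
    "study_config_schema",
    "EXPLORATORY_VITALS",
    "DEMOGRAPHIC_CONSTANTS",
]

logger = logging.getLogger("fuzzylvef")

#: The five most regularly acquired vitals used for interval comparison,
#: plus the two demographic constants available at every admission.
EXPLORATORY_VITALS = (
    "heart_rate",
    "diastolic_nbp",
    "systolic_nbp",
    "respiratory_rate",
    "oxygen_saturation",
)
DEMOGRAPHIC_CONSTANTS = ("age", "weight")

BASELINE_INTERVAL = (0.0, 6.0)


class StudyConfig(BaseModel):
    """Configuration of one study run.

    The six-hour windows must be nonoverlapping and ordered; the separate
    first-hour model is toggled by ``first_hour`` (it deliberately overlaps
    the 0-6 h window, as in the original design).
    """

    model_config = ConfigDict(frozen=True)

    cohort_csv: Optional[str] = None
    n_patients: int = 936
    intervals: tuple[tuple[float, float], ...] = (
        (0.0, 6.0),
        (6.0, 12.0),
        (12.0, 18.0),
        (18.0, 24.0),
        (24.0, 30.0),
    )
    first_hour: bool = True
    model_family: str = "fuzzy"  # "fuzzy" | "logistic"
    clusters: int = 2
    fuzziness_m: float = 2.0
    folds: int = 5
    repetitions_fs: int = 50
    repetitions_ma: int = 50
    sfs_max_features: Optional[int] = None
    consensus_quota: float = 0.5
    normalization: str = "per-fold"  # "per-fold" | "global"
    threshold_criterion: str = "youden"

    @model_validator(mode="after")
    def _check(self) -> "StudyConfig":
        if self.model_family not in ("fuzzy", "logistic"):
            raise ValueError("model_family must be 'fuzzy' or 'logistic'")
        if self.normalization not in ("per-fold", "global"):
            raise ValueError("normalization must be 'per-fold' or 'global'")
        if self.folds < 2 or self.repetitions_fs < 1 or self.repetitions_ma < 1:
            raise ValueError("folds >= 2 and repetitions >= 1 required")
        ordered = sorted(self.intervals)
        for (s0, e0), (s1, e1) in zip(ordered, ordered[1:]):
            if e0 > s1:
                raise ValueError("six-hour intervals must be nonoverlapping")
        for s, e in self.intervals:
            if s >= e:
                raise ValueError("each interval needs start < end")
        return self

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


def study_config_schema() -> dict:
    return StudyConfig.model_json_schema()


def make_builder(config: StudyConfig) -> Callable[[CohortTable, int], object]:
    """Model-fitting procedure for CV/SFS: (train table, seed) -> results.

    Normalization is refit inside the builder (on training folds only)
    unless the config requests the literal-replication global mode, in
    which case the caller normalizes once up front.
    """
    normalize = config.normalization == "per-fold"
    if config.model_family == "fuzzy":

        def build(table: CohortTable, seed: int):
            return TakagiSugenoClassifier.from_cohort(
                table,
                n_rules=config.clusters,
                m=config.fuzziness_m,
                normalize=normalize,
            ).fit(seed=seed)

    else:

        def build(table: CohortTable, seed: int):
            return LogisticClassifier.from_cohort(table, normalize=normalize).fit()

    return build


def _interval_label(start: float, end: float) -> str:
    return f"{start:g}-{end:g}h"


def _interval_table(
    measurements: pd.DataFrame,
    cohort: CohortTable,
    start: float,
    end: float,
    vitals: tuple[str, ...] = EXPLORATORY_VITALS,
) -> Optional[CohortTable]:
    agg = aggregate_interval(measurements, start, end)
    cols = [v for v in vitals if v in agg.columns]
    if not cols:
        return None
    frame = agg[cols].join(cohort.data[list(DEMOGRAPHIC_CONSTANTS)], how="inner")
    frame = frame.dropna()
    if frame.empty:
        return None
    labels = cohort.labels.loc[frame.index]
    return CohortTable(data=frame, labels=labels, variables=cohort.variables)


def run_interval_comparison(
    config: StudyConfig,
    seed: int = 0,
    spec: Optional[CohortSpec] = None,
    measurements: Optional[pd.DataFrame] = None,
    cohort: Optional[CohortTable] = None,
) -> pd.DataFrame:
    """Compare predictive performance across post-admission time windows.

    For each configured window, per-patient interval means of the
    exploratory vitals (joined with the demographic constants) feed the
    configured model family under repeated stratified CV. The report gives
    mean +- SD of AUC/accuracy/sensitivity/specificity per window, plus the
    two-sample t-test p value of each window's per-repetition AUC means
    against the 0-6 h baseline window. Windows without usable data are
    skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    s_cohort, s_stream, s_cv = (int(v) for v in rng.integers(2**31 - 1, size=3))
    if spec is None:
        spec = default_cohort_spec(n_patients=config.n_patients)
    if cohort is None:
        cohort = generate_cohort(spec, seed=s_cohort)
    if measurements is None:
        horizon = max(e for _, e in config.intervals)
        measurements = generate_timed_measurements(
            cohort, spec, horizon_h=horizon, seed=s_stream
        )
    kept, n_removed = filter_physiologic_outliers(measurements, spec.bounds_table())
    if n_removed:
        logger.info("interval comparison: removed %d out-of-bounds measurements", n_removed)

    windows = list(config.intervals)
    if config.first_hour:
        windows = [(0.0, 1.0), *windows]
    builder = make_builder(config)

    rows = {}
    rep_aucs: dict[str, pd.Series] = {}
    for start, end in sorted(windows):
        label = _interval_label(start, end)
        table = _interval_table(kept, cohort, start, end)
        if table is None or min(np.bincount(table.y, minlength=2)) < config.folds:
            warnings.warn(
                f"interval {label}: not enough data; skipped", RuntimeWarning, stacklevel=2
            )
            continue
        report = repeated_stratified_cv(
            builder, table, k=config.folds, repetitions=config.repetitions_ma, seed=s_cv
        )
        summary = report.summary()
        rows[label] = {
            "start_h": start,
            "end_h": end,
            "n_patients": table.n_patients,
            **{
                f"{metric}_{stat}": float(summary.loc[metric, stat])
                for metric in ("auc", "accuracy", "sensitivity", "specificity")
                for stat in ("mean", "std")
            },
        }
        rep_aucs[label] = report.repetition_means("auc")

    base_label = _interval_label(*BASELINE_INTERVAL)
    for label, row in rows.items():
        p = np.nan
        if (
            base_label in rep_aucs
            and label != base_label
            and len(rep_aucs[label]) >= 2
        ):
            _, p = two_sample_ttest(rep_aucs[label], rep_aucs[base_label])
        row["p_vs_baseline"] = p
    return pd.DataFrame.from_dict(rows, orient="index").sort_values("start_h")


@dataclass
class StudyReport:
    """Artifacts of a full study run."""

    consensus: list[str]
    frequencies: pd.Series
    cv_report: CVReport
    model_json: str
    config_hash: str
    seed: int
    traces: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return self.cv_report.summary()

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "model.json").write_text(self.model_json, encoding="utf-8")
        self.cv_report.to_csv(out / "cv_report.csv")
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "consensus_features": self.consensus,
            "selection_frequencies": {k: float(v) for k, v in self.frequencies.items()},
            "cv_summary": self.cv_report.summary_dict(),
        }
        (out / "study_summary.json").write_text(
            json.dumps(payload, indent=1), encoding="utf-8"
        )
        for i, trace in enumerate(self.traces):
            (out / f"sfs_trace_{i}.json").write_text(trace.to_json(), encoding="utf-8")


def run_full_study(
    config: StudyConfig,
    seed: int = 0,
    table: Optional[CohortTable] = None,
) -> StudyReport:
    """FS/MA split -> repeated SFS with consensus -> repeated CV -> final model.

    Deterministic given (config, seed): one master seed spawns per-stage
    substreams. Every artifact carries the config hash.
    """
    rng = np.random.default_rng(seed)
    s_cohort, s_split, s_sfs, s_cv, s_fit = (int(v) for v in rng.integers(2**31 - 1, size=5))

    if table is None:
        if config.cohort_csv is not None:
            table = CohortTable.from_csv(config.cohort_csv)
        else:
            spec = default_cohort_spec(n_patients=config.n_patients)
            table = generate_cohort(spec, seed=s_cohort)
    if config.normalization == "global":
        table, _ = min_max_normalize(table)

    logger.info("full study: splitting %d patients into FS/MA halves", table.n_patients)
    fs_half, ma_half = fs_ma_split(table, seed=s_split)

    builder = make_builder(config)
    traces = run_repeated_sfs(
        builder,
        fs_half,
        repetitions=config.repetitions_fs,
        seed=s_sfs,
        k=config.folds,
        max_features=config.sfs_max_features,
    )
    freq = selection_frequencies(traces)
    consensus = consensus_features(traces, quota=config.consensus_quota)
    if not consensus:
        # degenerate: no feature clears the quota; keep the most frequent one
        consensus = [freq.idxmax()]
        warnings.warn(
            "no feature exceeded the consensus quota; keeping the most frequent",
            RuntimeWarning,
            stacklevel=2,
        )
    logger.info("full study: consensus feature set %s", consensus)

    ma_table = ma_half.select(consensus)
    cv_report = repeated_stratified_cv(
        builder, ma_table, k=config.folds, repetitions=config.repetitions_ma, seed=s_cv
    )
    final = builder(ma_table, s_fit)
    model_json = (
        final.ts_model.to_json()
        if config.model_family == "fuzzy"
        else final.fitted.to_json()
    )
    return StudyReport(
        consensus=consensus,
        frequencies=freq,
        cv_report=cv_report,
        model_json=model_json,
        config_hash=config.config_hash(),
        seed=seed,
        traces=traces,
    )
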