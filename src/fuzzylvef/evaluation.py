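"""Model evaluation: ROC/AUC, threshold metrics, repeated stratified
cross-validation, the two-sample t-test and the Pearson-system family
check used for cohort statistics.

Two independent AUC routes are provided on purpose: :func:`auc` uses the
Mann-Whitney rank identity (ties counted 1/2) while :class:`ROCResult`
integrates its stored curve by the trapezoid rule; the two agree to
floating-point precision, which the test-suite exploits as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import CohortTable

__all__ = [
    "ROCResult",
    "CVReport",
    "roc_curve",
    "auc",
    "select_threshold",
    "metrics_at",
    "repeated_stratified_cv",
    "two_sample_ttest",
    "pearson_system_family",
]


def _check_binary(labels: np.ndarray) -> tuple[int, int]:
    pos = int((labels == 1).sum())
    neg = int((labels == 0).sum())
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present")
    return pos, neg


@dataclass
class ROCResult:
    """ROC curve sampled at every distinct score threshold (>= convention).

    ``thresholds`` is stored ascending (the final entry is a +inf sentinel
    at which nothing is predicted positive); along it sensitivity is
    non-increasing and specificity non-decreasing. ``auc`` is the
    trapezoidal area of the stored curve.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_curve(scores, labels) -> ROCResult:
    """Empirical ROC of continuous scores against binary labels."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    n_pos, n_neg = _check_binary(y)
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # collapse tied scores: evaluate at the last index of each tie group
    last = np.r_[np.diff(s_sorted) != 0, True]
    thr_desc = s_sorted[last]
    tpr = tps[last] / n_pos
    fpr = fps[last] / n_neg
    # sentinel threshold above every score: (fpr, tpr) = (0, 0)
    thr_desc = np.r_[np.inf, thr_desc]
    tpr = np.r_[0.0, tpr]
    fpr = np.r_[0.0, fpr]
    area = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        thresholds=thr_desc[::-1].copy(),
        sensitivity=tpr[::-1].copy(),
        specificity=(1.0 - fpr)[::-1].copy(),
        auc=area,
    )


def auc(scores, labels) -> float:
    """AUC via the Mann-Whitney identity: the probability that a random
    positive outscores a random negative, ties counted one half."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    n_pos, n_neg = _check_binary(y)
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def select_threshold(roc: ROCResult, criterion: str = "youden") -> float:
    """Classification cut-off balancing sensitivity and specificity.

    ``youden`` maximizes J = sensitivity + specificity - 1 (default);
    ``closest`` minimizes the distance to the perfect corner (0, 1). Ties
    are broken toward higher sensitivity.
    """
    finite = np.isfinite(roc.thresholds)
    sens = roc.sensitivity[finite]
    spec = roc.specificity[finite]
    thr = roc.thresholds[finite]
    if len(thr) == 0:
        raise ValueError("degenerate ROC curve")
    if criterion == "youden":
        objective = sens + spec - 1.0
    elif criterion == "closest":
        objective = -np.hypot(1.0 - sens, 1.0 - spec)
    else:
        raise ValueError("criterion must be 'youden' or 'closest'")
    best = objective.max()
    candidates = np.flatnonzero(objective >= best - 1e-12)
    winner = candidates[np.argmax(sens[candidates])]
    return float(thr[winner])


def metrics_at(scores, labels, threshold: float) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) of thresholded scores, with the
    >= convention (score at the threshold predicts the positive class)."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    n_pos, n_neg = _check_binary(y)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    return (
        (tp + tn) / len(y),
        tp / n_pos,
        tn / n_neg,
    )


@dataclass
class CVReport:
    """Per-repetition, per-fold metric records from repeated stratified CV."""

    records: pd.DataFrame  # columns: repetition, fold, auc, accuracy, sensitivity, specificity
    config: dict = field(default_factory=dict)

    _METRICS = ("auc", "accuracy", "sensitivity", "specificity")

    def summary(self) -> pd.DataFrame:
        """mean +- SD of each metric over all fold records."""
        return self.records[list(self._METRICS)].agg(["mean", "std"]).T

    def repetition_means(self, metric: str = "auc") -> pd.Series:
        return self.records.groupby("repetition")[metric].mean()

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def summary_dict(self) -> dict:
        s = self.summary()
        return {
            m: {"mean": float(s.loc[m, "mean"]), "sd": float(s.loc[m, "std"])}
            for m in self._METRICS
        }


def _stratified_fold_ids(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    fold = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls} has fewer members ({len(idx)}) than folds ({k})")
        perm = rng.permutation(idx)
        fold[perm] = np.arange(len(perm)) % k
    return fold


def repeated_stratified_cv(
    builder: Callable[[CohortTable, int], object],
    table: CohortTable,
    k: int = 5,
    repetitions: int = 1,
    seed: int = 0,
) -> CVReport:
    """Repeated stratified k-fold cross-validation of a model builder.

    ``builder(train_table, seed)`` must return a fitted results object
    exposing ``predict_score(exog)`` and ``threshold`` (both Results classes
    in this package qualify); any normalization is refit inside the builder
    on the training folds only. Validation metrics use the threshold
    calibrated on the training folds; per-fold AUCs are averaged rather
    than pooled. A builder emitting constant scores yields fold AUC 0.5 by
    the tie convention of :func:`auc`.
    """
    rng = np.random.default_rng(seed)
    y = table.y
    rows = []
    for rep in range(repetitions):
        fold_ids = _stratified_fold_ids(y, k, rng)
        fit_seed = int(rng.integers(2**31 - 1))
        for fold in range(k):
            val_mask = fold_ids == fold
            train = table.subset(table.data.index[~val_mask])
            val = table.subset(table.data.index[val_mask])
            result = builder(train, fit_seed + fold)
            scores = np.asarray(result.predict_score(val.data), dtype=float)
            acc, sens, spec = metrics_at(scores, val.y, result.threshold)
            rows.append(
                {
                    "repetition": rep,
                    "fold": fold,
                    "auc": auc(scores, val.y),
                    "accuracy": acc,
                    "sensitivity": sens,
                    "specificity": spec,
                }
            )
    records = pd.DataFrame(rows)
    return CVReport(records=records, config={"k": k, "repetitions": repetitions, "seed": seed})


def two_sample_ttest(a, b, welch: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test for equal means.

    Welch's unequal-variance form by default; ``welch=False`` gives the
    pooled-variance form. Two identical zero-variance samples return
    (0.0, 1.0) rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.std() == 0.0 and b.std() == 0.0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


_PEARSON_LABELS = {
    "normal": "normal",
    "I": "I (beta)",
    "II": "II (symmetric beta)",
    "III": "III (gamma)",
    "IV": "IV",
    "V": "V (inverse gamma)",
    "VI": "VI (beta prime)",
    "VII": "VII (Student t)",
}


def pearson_system_family(
    sample, tol: float = 0.1, boundary_tol: float = 0.25
) -> str:
    """Classify a sample's distribution family within the Pearson system.

    Uses the sample's squared skewness b1 and (non-excess) kurtosis b2 and
    the standard kappa discriminant

        kappa = b1 (b2 + 3)^2 / [4 (4 b2 - 3 b1)(2 b2 - 3 b1 - 6)].

    ``tol`` is the band around (b1, b2) = (0, 3) declared normal (and
    around b1 = 0 for types II/VII); ``boundary_tol`` is the band around
    the type III and V boundary curves. Moments are location/scale
    invariant, so affine transforms of a sample classify identically.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 8:
        raise ValueError("need at least 8 observations")
    if x.std() == 0.0:
        raise ValueError("zero-variance sample has undefined shape moments")
    b1 = float(stats.skew(x)) ** 2
    b2 = float(stats.kurtosis(x, fisher=False))

    if b1 < tol:
        if abs(b2 - 3.0) < tol:
            return _PEARSON_LABELS["normal"]
        return _PEARSON_LABELS["II"] if b2 < 3.0 else _PEARSON_LABELS["VII"]

    d = 2.0 * b2 - 3.0 * b1 - 6.0
    if abs(d) < boundary_tol:
        return _PEARSON_LABELS["III"]
    kappa = b1 * (b2 + 3.0) ** 2 / (4.0 * (4.0 * b2 - 3.0 * b1) * d)
    if kappa < 0.0:
        return _PEARSON_LABELS["I"]
    if abs(kappa - 1.0) < boundary_tol:
        return _PEARSON_LABELS["V"]
    if kappa < 1.0:
        return _PEARSON_LABELS["IV"]
    return _PEARSON_LABELS["VI"]
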