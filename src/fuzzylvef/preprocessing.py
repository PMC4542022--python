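"""Cohort preprocessing: class dichotomization, physiologic outlier
filtering, interval-mean aggregation, min-max normalization, and the
equal-size feature-selection / model-assessment split."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Mapping, Optional

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import VariableSpec

__all__ = [
    "CohortTable",
    "MinMaxNormalizer",
    "label_classes",
    "filter_physiologic_outliers",
    "aggregate_interval",
    "min_max_normalize",
    "fs_ma_split",
]


@dataclass
class CohortTable:
    """Patient-by-variable numeric matrix with binary LVEF class labels.

    ``labels`` is 1 for the severely depressed class (LVEF <= 25%) and 0
    otherwise. ``normalization_ranges`` records per-column (min, max) once
    the table has been min-max normalized, enabling exact inversion and the
    (clipped) transform of unseen samples.
    """

    data: pd.DataFrame
    labels: pd.Series
    variables: Optional[Mapping[str, "VariableSpec"]] = None
    normalization_ranges: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.labels.index):
            raise ValueError("data and labels must share an index")
        lab = self.labels.to_numpy()
        if not np.isin(lab, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("cohort table must not contain non-finite values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)

    def select(self, features: list[str]) -> "CohortTable":
        ranges = self.normalization_ranges
        if ranges is not None:
            ranges = ranges.loc[[f for f in features if f in ranges.index]]
        return replace(self, data=self.data[features], normalization_ranges=ranges)

    def subset(self, index) -> "CohortTable":
        return replace(
            self,
            data=self.data.loc[index],
            labels=self.labels.loc[index],
        )

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out["lvef_class"] = self.labels
        out.to_csv(path, index=True)

    @classmethod
    def from_csv(cls, path, label_column: str = "lvef_class") -> "CohortTable":
        frame = pd.read_csv(path, index_col="patient_id")
        labels = frame.pop(label_column).astype(int)
        return cls(data=frame, labels=labels)


def label_classes(lvef_values, cutoff: float = 25.0) -> np.ndarray:
    """Dichotomize LVEF into 1 = severely depressed (LVEF <= cutoff), 0 = other.

    The boundary value itself is labelled positive (class defined as
    LVEF <= 25%). Values outside (0, 100] are rejected as non-physiologic.
    """
    values = np.asarray(lvef_values, dtype=float)
    if not np.isfinite(values).all() or (values <= 0).any() or (values > 100).any():
        raise ValueError("LVEF values must be finite percentages in (0, 100]")
    return (values <= cutoff).astype(int)


def filter_physiologic_outliers(
    measurements: pd.DataFrame,
    bounds: Mapping[str, tuple[float, float]],
) -> tuple[pd.DataFrame, int]:
    """Drop measurements outside the physiologically possible range.

    ``measurements`` is the tidy timed frame (``patient_id, variable,
    t_hours, value``). Values with ``low <= value <= high`` for their
    variable are kept, order preserved; returns ``(kept, n_removed)``.
    Every variable present must have bounds configured.
    """
    if measurements.empty:
        return measurements.copy(), 0
    present = measurements["variable"].unique()
    missing = [v for v in present if v not in bounds]
    if missing:
        raise KeyError(f"no physiologic bounds configured for: {missing}")
    lows = measurements["variable"].map({v: bounds[v][0] for v in present})
    highs = measurements["variable"].map({v: bounds[v][1] for v in present})
    keep = (measurements["value"] >= lows) & (measurements["value"] <= highs)
    kept = measurements.loc[keep]
    return kept, int((~keep).sum())


def aggregate_interval(
    measurements: pd.DataFrame,
    start_h: float,
    end_h: float,
) -> pd.DataFrame:
    """Per-patient per-variable mean over the half-open window [start_h, end_h).

    Returns a patient x variable frame; patient/variable pairs with no
    measurement in the window are NaN (absent), never zero. The half-open
    convention makes consecutive equal-width windows nonoverlapping.
    """
    if start_h >= end_h:
        raise ValueError("start_h must be < end_h")
    window = measurements[
        (measurements["t_hours"] >= start_h) & (measurements["t_hours"] < end_h)
    ]
    return window.pivot_table(
        index="patient_id", columns="variable", values="value", aggfunc="mean"
    )


@dataclass(frozen=True)
class MinMaxNormalizer:
    """Column-wise linear rescaling: observed min -> 0, observed max -> 1.

    Fitted ranges are stored so that unseen samples can be transformed
    consistently (clipped to [0, 1]) and training values inverted exactly.
    """

    ranges: pd.DataFrame = field(default_factory=pd.DataFrame)  # columns: min, max

    @classmethod
    def fit(cls, data: pd.DataFrame) -> "MinMaxNormalizer":
        mins = data.min(axis=0)
        maxs = data.max(axis=0)
        degenerate = maxs[(maxs - mins) <= 0].index.tolist()
        if degenerate:
            raise ValueError(
                f"cannot min-max normalize constant column(s): {degenerate}"
            )
        return cls(ranges=pd.DataFrame({"min": mins, "max": maxs}))

    def transform(self, data: pd.DataFrame, clip: bool = True) -> pd.DataFrame:
        mins = self.ranges["min"]
        span = self.ranges["max"] - self.ranges["min"]
        out = (data[self.ranges.index] - mins) / span
        return out.clip(0.0, 1.0) if clip else out

    def inverse(self, normalized: pd.DataFrame) -> pd.DataFrame:
        mins = self.ranges["min"]
        span = self.ranges["max"] - self.ranges["min"]
        return normalized[self.ranges.index] * span + mins


def min_max_normalize(table: CohortTable) -> tuple[CohortTable, pd.DataFrame]:
    """Min-max normalize every column of a cohort table.

    Returns the normalized table (values in [0, 1], fitted ranges attached)
    and the per-column (min, max) frame.
    """
    scaler = MinMaxNormalizer.fit(table.data)
    normalized = scaler.transform(table.data, clip=False)
    out = replace(table, data=normalized, normalization_ranges=scaler.ranges)
    return out, scaler.ranges


def fs_ma_split(table: CohortTable, seed: int) -> tuple[CohortTable, CohortTable]:
    """Split into equal-size feature-selection and model-assessment halves.

    Stratified by class so both halves keep the cohort prevalence; halves
    are disjoint, their union is the input, sizes differ by at most one.
    """
    rng = np.random.default_rng(seed)
    y = table.y
    first: list[np.ndarray] = []
    second: list[np.ndarray] = []
    n_first = n_second = 0
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members; cannot stratify")
        perm = rng.permutation(idx)
        half = len(perm) // 2
        # odd class: give the spare row to whichever half is running short,
        # keeping the overall halves within one patient of each other
        if len(perm) % 2 and n_first <= n_second:
            half += 1
        first.append(perm[:half])
        second.append(perm[half:])
        n_first += half
        n_second += len(perm) - half
    fs_idx = table.data.index[np.sort(np.concatenate(first))]
    ma_idx = table.data.index[np.sort(np.concatenate(second))]
    return table.subset(fs_idx), table.subset(ma_idx)
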