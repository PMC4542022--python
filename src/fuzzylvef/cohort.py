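"""Synthetic ICU cohort generator.

Emulates the tabular structure of an early-ICU cohort used to predict
severely depressed left ventricular ejection fraction (LVEF <= 25%):
one row per ICU stay, 16 continuous physiologic/demographic variables
plus gender, and a binary class label with ~12.3% prevalence of the
severely depressed class.

Each continuous variable is drawn from a class-conditional truncated
normal distribution. The location of the underlying normal is calibrated
(root-finding) so that the *post-truncation* mean equals the published
class-conditional mean; the scale is the published class SD. Without this
calibration, variables whose physiologic lower bound sits within ~2 SD of
the mean (admission weight, glucose, oxygen saturation against its 100%
ceiling) would be biased by several percent of an SD.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import stats
from scipy.optimize import brentq

from .preprocessing import CohortTable

__all__ = [
    "VariableSpec",
    "CohortSpec",
    "default_cohort_spec",
    "default_table1_spec",
    "generate_cohort",
    "generate_timed_measurements",
    "cohort_spec_schema",
    "TIMED_CSV_COLUMNS",
]

TIMED_CSV_COLUMNS = ["patient_id", "variable", "t_hours", "value"]


class VariableSpec(BaseModel):
    """Statistical and acquisition metadata for one cohort variable.

    Parameters
    ----------
    name : identifier used as the CSV column name.
    unit : measurement unit (informational).
    physiologic_bounds : (low, high) — values outside are impossible and
        are filtered as outliers; generation truncates to this range.
    class_means, class_sds : (positive class, negative class) moments,
        where "positive" means severely depressed LVEF.
    acquisition_period_h : hours between bedside measurements (vitals ~1 h,
        labs ~24 h); ``None`` marks a demographic constant recorded once
        at admission.
    normal_range : optional clinically normal (low, high), informational.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    unit: str
    physiologic_bounds: tuple[float, float]
    class_means: tuple[float, float]
    class_sds: tuple[float, float]
    acquisition_period_h: Optional[float] = None
    normal_range: Optional[tuple[float, float]] = None

    @model_validator(mode="after")
    def _check(self) -> "VariableSpec":
        lo, hi = self.physiologic_bounds
        if not lo < hi:
            raise ValueError(f"{self.name}: physiologic_bounds must satisfy low < high")
        if self.normal_range is not None and not self.normal_range[0] < self.normal_range[1]:
            raise ValueError(f"{self.name}: normal_range must satisfy low < high")
        if min(self.class_sds) <= 0:
            raise ValueError(f"{self.name}: class SDs must be positive")
        if self.acquisition_period_h is not None and self.acquisition_period_h <= 0:
            raise ValueError(f"{self.name}: acquisition_period_h must be positive")
        return self


class CohortSpec(BaseModel):
    """Full recipe for one synthetic cohort."""

    model_config = ConfigDict(frozen=True)

    variables: tuple[VariableSpec, ...]
    prevalence: float
    n_patients: int = 936
    male_fraction: tuple[float, float] = (0.644, 0.526)
    correlation: Optional[tuple[tuple[float, ...], ...]] = None

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if not 0.0 < self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in (0, 1]")
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10")
        if self.correlation is not None:
            r = np.asarray(self.correlation, dtype=float)
            p = len(self.variables)
            if r.shape != (p, p):
                raise ValueError("correlation must be p x p for p variables")
            if not np.allclose(r, r.T):
                raise ValueError("correlation must be symmetric")
            if not np.allclose(np.diag(r), 1.0):
                raise ValueError("correlation must have unit diagonal")
            if np.linalg.eigvalsh(r).min() < -1e-10:
                raise ValueError("correlation must be positive semidefinite")
        return self

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def bounds_table(self) -> dict[str, tuple[float, float]]:
        return {v.name: v.physiologic_bounds for v in self.variables}


def cohort_spec_schema() -> dict:
    """JSON schema for the structured-text cohort-spec config."""
    return CohortSpec.model_json_schema()


# (name, unit, bounds, mean_pos, sd_pos, mean_neg, sd_neg, period_h, normal_range)
# Class moments are the published first-6-hour group statistics of the
# severely depressed (LVEF <= 25%, n=115) vs non-severely depressed (n=821)
# cohorts; normal ranges are the reference clinical ranges.
_TABLE1 = [
    ("heart_rate", "beats/min", (20.0, 300.0), 88.6, 17.8, 84.2, 19.2, 1.0, None),
    ("diastolic_nbp", "mmHg", (20.0, 200.0), 59.2, 12.0, 60.8, 13.6, 1.0, None),
    ("systolic_nbp", "mmHg", (40.0, 300.0), 110.2, 16.9, 120.1, 20.2, 1.0, (90.0, 119.0)),
    ("respiratory_rate", "breaths/min", (4.0, 80.0), 21.0, 4.8, 19.2, 4.6, 1.0, (12.0, 24.0)),
    ("oxygen_saturation", "%", (50.0, 100.0), 96.8, 3.9, 97.2, 2.9, 1.0, None),
    ("temperature", "degC", (25.0, 45.0), 36.6, 0.8, 36.7, 0.8, 1.0, None),
    ("bun", "mg/dL", (1.0, 300.0), 37.6, 26.4, 28.9, 22.3, 24.0, (7.0, 21.0)),
    ("co2", "mmol/L", (5.0, 60.0), 22.9, 5.0, 23.4, 5.0, 24.0, None),
    ("glucose", "mg/dL", (20.0, 1000.0), 172.2, 78.1, 151.9, 65.7, 24.0, None),
    ("hemoglobin", "mmol/L", (2.0, 25.0), 11.9, 2.4, 11.4, 2.0, 24.0, (8.56, 11.17)),
    ("platelets", "1e3 cells/uL", (1.0, 1500.0), 244.2, 112.5, 235.2, 108.3, 24.0, None),
    ("potassium", "mmol/L", (1.0, 12.0), 4.3, 0.6, 4.2, 0.7, 24.0, None),
    ("sodium", "mmol/L", (100.0, 185.0), 137.8, 5.2, 138.5, 4.7, 24.0, (135.0, 145.0)),
    ("white_blood_cells", "1e3 cells/uL", (0.1, 200.0), 12.7, 5.6, 12.8, 8.3, 24.0, (3.5, 9.0)),
    ("age", "years", (18.0, 110.0), 70.6, 15.1, 67.3, 16.4, None, None),
    ("weight", "kg", (25.0, 350.0), 77.1, 18.6, 83.0, 25.7, None, None),
]

#: Study prevalence: 115 severely depressed of 936 extracted stays.
STUDY_PREVALENCE = 115.0 / 936.0


def default_cohort_spec(
    n_patients: int = 936,
    prevalence: float = STUDY_PREVALENCE,
    correlation: Optional[Sequence[Sequence[float]]] = None,
) -> CohortSpec:
    """CohortSpec with the study-matched default parameters."""
    variables = tuple(
        VariableSpec(
            name=name,
            unit=unit,
            physiologic_bounds=bounds,
            class_means=(m_pos, m_neg),
            class_sds=(s_pos, s_neg),
            acquisition_period_h=period,
            normal_range=normal,
        )
        for name, unit, bounds, m_pos, s_pos, m_neg, s_neg, period, normal in _TABLE1
    )
    corr = None if correlation is None else tuple(tuple(map(float, row)) for row in correlation)
    return CohortSpec(
        variables=variables,
        prevalence=prevalence,
        n_patients=n_patients,
        correlation=corr,
    )


# Alias: the defaults transcribe the study's baseline-characteristics table.
default_table1_spec = default_cohort_spec


@lru_cache(maxsize=256)
def _calibrated_loc(target_mean: float, sd: float, low: float, high: float) -> float:
    """Location of the underlying normal whose [low, high]-truncation has
    mean ``target_mean`` (scale fixed at ``sd``)."""
    if not low < target_mean < high:
        raise ValueError("target mean must lie strictly inside the bounds")

    def gap(loc: float) -> float:
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    return float(brentq(gap, target_mean - 12 * sd, target_mean + 12 * sd, xtol=1e-10))


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float, low: float, high: float) -> np.ndarray:
    loc = _calibrated_loc(mean, sd, low, high)
    a, b = (low - loc) / sd, (high - loc) / sd
    x = stats.truncnorm.ppf(u, a, b, loc=loc, scale=sd)
    return np.clip(x, low, high)  # guard ppf round-off at the edges


def generate_cohort(spec: CohortSpec, seed: int) -> CohortTable:
    """Draw one synthetic cohort.

    Labels are Bernoulli(prevalence); each continuous variable is drawn from
    its class-conditional mean-calibrated truncated normal; gender is
    Bernoulli with the class-specific male fraction (1 = male). Variables are
    independent within class unless ``spec.correlation`` supplies a Gaussian
    copula. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_patients
    labels = (rng.random(n) < spec.prevalence).astype(int)

    p = len(spec.variables)
    if spec.correlation is not None:
        r = np.asarray(spec.correlation, dtype=float)
        # Gaussian copula: correlated normal scores -> uniform quantiles
        w, v = np.linalg.eigh(r)
        z = rng.standard_normal((n, p)) @ (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
        u = stats.norm.cdf(z)
    else:
        u = rng.random((n, p))
    u = np.clip(u, 1e-12, 1.0 - 1e-12)

    data = {}
    for j, var in enumerate(spec.variables):
        lo, hi = var.physiologic_bounds
        x = np.empty(n)
        for cls, side in ((1, 0), (0, 1)):
            mask = labels == cls
            if mask.any():
                x[mask] = _truncnorm_ppf(
                    u[mask, j], var.class_means[side], var.class_sds[side], lo, hi
                )
        data[var.name] = x

    male_p = np.where(labels == 1, spec.male_fraction[0], spec.male_fraction[1])
    data["gender"] = (rng.random(n) < male_p).astype(float)

    frame = pd.DataFrame(data, index=pd.RangeIndex(n, name="patient_id"))
    return CohortTable(
        data=frame,
        labels=pd.Series(labels, index=frame.index, name="lvef_class"),
        variables={v.name: v for v in spec.variables},
    )


def generate_timed_measurements(
    cohort: CohortTable,
    spec: CohortSpec,
    horizon_h: float = 30.0,
    seed: int = 0,
    noise_sd_fraction: float = 0.25,
    window_effects: Optional[Sequence[tuple[str, float, float, float]]] = None,
) -> pd.DataFrame:
    """Expand a cohort into timestamped bedside/lab measurement streams.

    Each timed variable is sampled on its acquisition-period grid with a
    uniform jitter of up to a quarter period, and observed with additive
    Gaussian noise of SD = ``noise_sd_fraction`` x the patient's class SD
    around the patient's latent (cohort-table) value. Demographic constants
    (``acquisition_period_h is None``) are not streamed.

    ``window_effects`` optionally plants a time-localised class effect:
    tuples ``(variable, start_h, end_h, delta_pos)`` shift the latent value
    of positive-class patients by ``delta_pos`` for samples whose time falls
    in ``[start_h, end_h)``.

    Returns a tidy frame with columns ``patient_id, variable, t_hours, value``.
    """
    if horizon_h <= 0:
        raise ValueError("horizon_h must be positive")
    rng = np.random.default_rng(seed)
    labels = cohort.labels.to_numpy()
    ids = cohort.data.index.to_numpy()
    effects = list(window_effects or [])

    records: list[pd.DataFrame] = []
    for var in spec.variables:
        period = var.acquisition_period_h
        if period is None or var.name not in cohort.data.columns:
            continue
        latent = cohort.data[var.name].to_numpy()
        sd = np.where(labels == 1, var.class_sds[0], var.class_sds[1])
        n_ticks = int(np.floor(horizon_h / period)) + 1
        grid = np.arange(n_ticks) * period
        # per-patient, per-tick jittered acquisition times
        t = grid[None, :] + rng.uniform(0.0, 0.25 * period, size=(len(ids), n_ticks))
        value = latent[:, None] + rng.standard_normal(t.shape) * (
            noise_sd_fraction * sd[:, None]
        )
        for name, lo_h, hi_h, delta in effects:
            if name == var.name:
                in_window = (t >= lo_h) & (t < hi_h) & (labels[:, None] == 1)
                value = value + delta * in_window
        keep = t < horizon_h
        rows = np.repeat(ids, n_ticks).reshape(len(ids), n_ticks)
        records.append(
            pd.DataFrame(
                {
                    "patient_id": rows[keep],
                    "variable": var.name,
                    "t_hours": t[keep],
                    "value": value[keep],
                }
            )
        )
    if not records:
        return pd.DataFrame(columns=TIMED_CSV_COLUMNS)
    out = pd.concat(records, ignore_index=True)
    return out.sort_values(["patient_id", "variable", "t_hours"], kind="stable").reset_index(
        drop=True
    )
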