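"""First-order Takagi-Sugeno (TS) fuzzy classification models.

A first-order TS model is a set of R rules

    Rule k: if x1 is A_{1,k} and ... and xp is A_{p,k}
            then y_k = a_k . x + b_k

whose continuous output is the activation-weighted mean

    output(x) = sum_k beta_k(x) y_k(x) / sum_k beta_k(x),

with beta_k the product of the rule's per-variable antecedent memberships.
Model identification runs Gustafson-Kessel clustering in the input-output
product space (one cluster per rule), projects the fuzzy partition onto
each input axis to obtain Gaussian antecedent membership functions, and
estimates each rule's affine consequent by membership-weighted least
squares. Dichotomous classification applies a threshold to the continuous
output (>= threshold -> severely depressed class).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gk import FuzzyPartition, gk_cluster
from .preprocessing import CohortTable, MinMaxNormalizer

__all__ = [
    "GaussianMF",
    "TSRule",
    "TSModel",
    "identify_ts_model",
    "project_memberships",
    "ts_evaluate",
    "classify",
    "load_printed_rules",
    "TakagiSugenoClassifier",
    "TakagiSugenoResults",
]

_BETA_FLOOR = 1e-12


@dataclass(frozen=True)
class GaussianMF:
    """Gaussian membership function exp(-((x - mu)/sigma)^2 / 2) in [0, 1].

    ``mu=None`` or ``sigma=None`` denotes the activation-agnostic constant
    function 1 (used when a rule's antecedent is unknown or degenerate).
    """

    mu: Optional[float] = None
    sigma: Optional[float] = None

    def evaluate(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.mu is None or self.sigma is None or not np.isfinite(self.sigma):
            return np.ones_like(x)
        return np.exp(-0.5 * ((x - self.mu) / self.sigma) ** 2)


@dataclass(frozen=True)
class TSRule:
    """One TS rule: per-input antecedents plus an affine consequent."""

    antecedents: tuple[GaussianMF, ...]
    consequent_a: np.ndarray
    consequent_b: float

    def __post_init__(self):
        if len(self.antecedents) != len(self.consequent_a):
            raise ValueError("antecedent count must equal consequent length")

    def activation(self, X: np.ndarray) -> np.ndarray:
        """Product t-norm over the per-variable antecedent memberships."""
        X = np.atleast_2d(X)
        beta = np.ones(X.shape[0])
        for j, mf in enumerate(self.antecedents):
            beta *= mf.evaluate(X[:, j])
        return beta

    def consequent(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return X @ self.consequent_a + self.consequent_b


@dataclass
class TSModel:
    """A complete TS classifier: rules, input bookkeeping and threshold."""

    rules: tuple[TSRule, ...]
    input_names: tuple[str, ...]
    normalization_ranges: Optional[dict[str, tuple[float, float]]] = None
    threshold: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Continuous output for each row of (normalized) X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"expected {self.n_inputs} inputs, got {X.shape[1]}"
            )
        beta = np.stack([r.activation(X) for r in self.rules])
        y_rules = np.stack([r.consequent(X) for r in self.rules])
        total = beta.sum(axis=0)
        out = np.empty(X.shape[0])
        ok = total >= _BETA_FLOOR
        if ok.any():
            out[ok] = (beta[:, ok] * y_rules[:, ok]).sum(axis=0) / total[ok]
        if (~ok).any():
            # all rules inactive: fall back to the unweighted rule mean
            out[~ok] = y_rules[:, ~ok].mean(axis=0)
        return out

    def classify(self, X: np.ndarray) -> np.ndarray:
        if self.threshold is None:
            raise RuntimeError("model threshold is not calibrated; cannot classify")
        return (self.evaluate(X) >= self.threshold).astype(int)

    # ------------------------------------------------------------------ JSON
    def to_json(self) -> str:
        payload = {
            "kind": "takagi_sugeno",
            "input_names": list(self.input_names),
            "normalization_ranges": (
                None
                if self.normalization_ranges is None
                else {k: list(v) for k, v in self.normalization_ranges.items()}
            ),
            "threshold": self.threshold,
            "metadata": self.metadata,
            "rules": [
                {
                    "antecedents": [
                        {"mu": mf.mu, "sigma": mf.sigma} for mf in r.antecedents
                    ],
                    "a": list(r.consequent_a),
                    "b": r.consequent_b,
                }
                for r in self.rules
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TSModel":
        d = json.loads(text)
        if d.get("kind") != "takagi_sugeno":
            raise ValueError("not a Takagi-Sugeno model JSON")
        rules = tuple(
            TSRule(
                antecedents=tuple(
                    GaussianMF(mu=a["mu"], sigma=a["sigma"]) for a in r["antecedents"]
                ),
                consequent_a=np.asarray(r["a"], dtype=float),
                consequent_b=float(r["b"]),
            )
            for r in d["rules"]
        )
        ranges = d.get("normalization_ranges")
        return cls(
            rules=rules,
            input_names=tuple(d["input_names"]),
            normalization_ranges=(
                None if ranges is None else {k: tuple(v) for k, v in ranges.items()}
            ),
            threshold=d.get("threshold"),
            metadata=d.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TSModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def project_memberships(
    partition: FuzzyPartition,
    X: np.ndarray,
    variable_index: int,
    min_sigma: float = 1e-3,
) -> list[GaussianMF]:
    """Fit one Gaussian membership function per cluster to the projection of
    the fuzzy partition onto a single input axis.

    The center is the membership-weighted mean of the axis values and the
    width the membership-weighted SD, so the fitted function peaks (at 1) at
    the projected cluster center. Axes with fewer than 3 distinct values get
    a flat (constant 1) function with a warning.
    """
    x = np.asarray(X, dtype=float)[:, variable_index]
    if len(np.unique(x)) < 3:
        warnings.warn(
            f"variable {variable_index} has fewer than 3 distinct values; "
            "using a flat membership function",
            RuntimeWarning,
            stacklevel=2,
        )
        return [GaussianMF() for _ in range(partition.n_clusters)]
    m = partition.fuzziness_m
    out = []
    for i in range(partition.n_clusters):
        w = partition.memberships[i] ** m
        total = w.sum()
        mu = float((w * x).sum() / total)
        sigma = float(np.sqrt((w * (x - mu) ** 2).sum() / total))
        out.append(GaussianMF(mu=mu, sigma=max(sigma, min_sigma)))
    return out


def _weighted_affine_fit(
    X: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, float]:
    """Membership-weighted least squares for one rule's (a, b); falls back to
    a small ridge when the weighted design is rank deficient."""
    n, p = X.shape
    design = np.column_stack([X, np.ones(n)])
    sw = np.sqrt(np.maximum(w, 0.0))
    A = design * sw[:, None]
    b = y * sw
    coef, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < p + 1:
        warnings.warn(
            "rank-deficient weighted regression; applying ridge regularization",
            RuntimeWarning,
            stacklevel=3,
        )
        G = A.T @ A
        lam = 1e-8 * max(np.trace(G) / (p + 1), 1.0)
        coef = np.linalg.solve(G + lam * np.eye(p + 1), A.T @ b)
    return coef[:p], float(coef[p])


def identify_ts_model(
    X: np.ndarray,
    y: np.ndarray,
    c: int = 2,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
    input_names: Optional[Sequence[str]] = None,
) -> TSModel:
    """Identify a TS model from normalized inputs and a target.

    Clusters the input-output product space with Gustafson-Kessel (the
    target min-max scaled for clustering only), derives one rule per
    cluster, and fits consequents by membership-weighted least squares
    against the raw target. The target may be the binary class label (the
    usual case; the continuous output then acts as a class possibility) or
    any finite regression target.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y lengths differ")
    if X.min() < -1e-9 or X.max() > 1 + 1e-9:
        raise ValueError("inputs must be min-max normalized to [0, 1]")
    if n <= c * (p + 1):
        raise ValueError("need N > c * (p + 1) samples to identify the model")

    span = y.max() - y.min()
    y_scaled = (y - y.min()) / span if span > 0 else np.zeros_like(y)
    Z = np.column_stack([X, y_scaled])
    partition, _ = gk_cluster(Z, c=c, m=m, tol=tol, max_iter=max_iter, seed=seed)

    antecedents = [project_memberships(partition, X, j) for j in range(p)]
    rules = []
    for i in range(c):
        a, b = _weighted_affine_fit(X, y, partition.memberships[i])
        rules.append(
            TSRule(
                antecedents=tuple(antecedents[j][i] for j in range(p)),
                consequent_a=a,
                consequent_b=b,
            )
        )
    names = tuple(input_names) if input_names is not None else tuple(
        f"x{j + 1}" for j in range(p)
    )
    return TSModel(
        rules=tuple(rules),
        input_names=names,
        metadata={"c": c, "m": m, "seed": seed},
    )


def ts_evaluate(model: TSModel, x: np.ndarray) -> float | np.ndarray:
    """Continuous TS output; scalar for a single sample."""
    out = model.evaluate(np.atleast_2d(x))
    return float(out[0]) if np.ndim(x) == 1 else out


def classify(model: TSModel, x: np.ndarray):
    """Thresholded class: 1 iff the continuous output >= model.threshold."""
    out = model.classify(np.atleast_2d(x))
    return int(out[0]) if np.ndim(x) == 1 else out


# Printed fitted rules for the 7-variable model (normalized inputs
# x1..x7 = systolic NBP, respiratory rate, BUN, hemoglobin, sodium,
# white blood cells, admission weight).
_PRINTED_INPUTS = (
    "systolic_nbp",
    "respiratory_rate",
    "bun",
    "hemoglobin",
    "sodium",
    "white_blood_cells",
    "weight",
)
_PRINTED_RULE1 = ([-0.0093, 0.0670, 0.2700, 0.5000, -1.200, 0.4000, 0.0540], 0.5000)
_PRINTED_RULE2 = ([-0.4300, 0.3100, 0.5000, 0.2400, -0.0280, -0.1500, -0.3600], 0.1400)


def load_printed_rules() -> TSModel:
    """The published two-rule, seven-input fitted model.

    Consequent coefficients and offsets are transcribed exactly. The
    antecedent membership-function parameters were published only as
    figures, so antecedents default to the constant function 1
    (activation-agnostic); callers exercising full weighted-sum inference
    must supply activations or antecedents explicitly.
    """
    rules = tuple(
        TSRule(
            antecedents=tuple(GaussianMF() for _ in _PRINTED_INPUTS),
            consequent_a=np.asarray(a, dtype=float),
            consequent_b=b,
        )
        for a, b in (_PRINTED_RULE1, _PRINTED_RULE2)
    )
    return TSModel(
        rules=rules,
        input_names=_PRINTED_INPUTS,
        metadata={"source": "published fitted rules", "c": 2},
    )


# --------------------------------------------------------------------------
# statsmodels-style model / results pair
# --------------------------------------------------------------------------


class TakagiSugenoClassifier:
    """TS fuzzy classifier for a binary outcome, statsmodels-style.

    Parameters
    ----------
    endog : (N,) binary labels (1 = severely depressed LVEF).
    exog : (N, p) raw feature matrix (un-normalized).
    n_rules : number of fuzzy rules (= GK clusters); the study used 2.
    m : GK fuzziness exponent.
    feature_names : optional column names.
    normalize : fit a min-max normalizer on the training data (default);
        pass False if ``exog`` is already scaled to [0, 1].
    """

    def __init__(
        self,
        endog,
        exog,
        n_rules: int = 2,
        m: float = 2.0,
        feature_names: Optional[Sequence[str]] = None,
        normalize: bool = True,
    ):
        exog = pd.DataFrame(np.atleast_2d(np.asarray(exog, dtype=float)))
        if feature_names is not None:
            exog.columns = list(feature_names)
        else:
            exog.columns = [f"x{j + 1}" for j in range(exog.shape[1])]
        self.endog = np.asarray(endog, dtype=int).ravel()
        if set(np.unique(self.endog)) - {0, 1}:
            raise ValueError("endog must be binary 0/1")
        if len(np.unique(self.endog)) < 2:
            raise ValueError("both classes must be present")
        self.exog = exog
        self.n_rules = n_rules
        self.m = m
        self.normalize = normalize

    @classmethod
    def from_cohort(cls, table: CohortTable, **kwargs) -> "TakagiSugenoClassifier":
        return cls(table.y, table.data, feature_names=table.feature_names, **kwargs)

    def fit(
        self, seed: int = 0, tol: float = 1e-6, max_iter: int = 200
    ) -> "TakagiSugenoResults":
        from .evaluation import roc_curve, select_threshold

        if self.normalize:
            scaler = MinMaxNormalizer.fit(self.exog)
            Xn = scaler.transform(self.exog).to_numpy()
            ranges = {
                name: (float(row["min"]), float(row["max"]))
                for name, row in scaler.ranges.iterrows()
            }
        else:
            scaler = None
            Xn = self.exog.to_numpy()
            ranges = None
        model = identify_ts_model(
            Xn,
            self.endog,
            c=self.n_rules,
            m=self.m,
            tol=tol,
            max_iter=max_iter,
            seed=seed,
            input_names=self.exog.columns,
        )
        model = replace(model, normalization_ranges=ranges)
        scores = model.evaluate(Xn)
        roc = roc_curve(scores, self.endog)
        model.threshold = float(select_threshold(roc))
        return TakagiSugenoResults(self, model, scaler)


class TakagiSugenoResults:
    """Fitted TS model: rules, calibrated threshold and training diagnostics."""

    def __init__(self, model: TakagiSugenoClassifier, ts_model: TSModel, scaler):
        self.model = model
        self.ts_model = ts_model
        self.scaler = scaler

    @property
    def threshold(self) -> float:
        return self.ts_model.threshold

    def _normalized(self, exog) -> np.ndarray:
        exog = pd.DataFrame(np.atleast_2d(np.asarray(exog, dtype=float)))
        exog.columns = list(self.model.exog.columns)
        if self.scaler is None:
            return exog.to_numpy()
        return self.scaler.transform(exog).to_numpy()

    def predict_score(self, exog=None) -> np.ndarray:
        """Continuous TS output on raw inputs (normalized internally)."""
        X = self.model.exog if exog is None else exog
        return self.ts_model.evaluate(self._normalized(X))

    def predict(self, exog=None) -> np.ndarray:
        """Thresholded class labels."""
        X = self.model.exog if exog is None else exog
        return self.ts_model.classify(self._normalized(X))

    def training_metrics(self) -> dict[str, float]:
        from .evaluation import auc, metrics_at

        scores = self.predict_score()
        acc, sens, spec = metrics_at(scores, self.model.endog, self.threshold)
        return {
            "auc": auc(scores, self.model.endog),
            "accuracy": acc,
            "sensitivity": sens,
            "specificity": spec,
        }

    def summary(self) -> str:
        rows = []
        for name_idx, name in enumerate(self.ts_model.input_names):
            row = {"input": name}
            for k, rule in enumerate(self.ts_model.rules, start=1):
                row[f"a[rule {k}]"] = rule.consequent_a[name_idx]
                mf = rule.antecedents[name_idx]
                row[f"mu[rule {k}]"] = np.nan if mf.mu is None else mf.mu
            rows.append(row)
        table = pd.DataFrame(rows).set_index("input")
        metrics = self.training_metrics()
        lines = [
            "Takagi-Sugeno fuzzy classifier (severely depressed LVEF)",
            "=" * 60,
            f"rules: {len(self.ts_model.rules)}   fuzziness m: {self.model.m}   "
            f"threshold: {self.threshold:.4f}",
            "",
            table.to_string(float_format=lambda v: f"{v: .4f}"),
            "",
            "rule offsets b: "
            + ", ".join(f"{r.consequent_b:.4f}" for r in self.ts_model.rules),
            "",
            "training: "
            + "  ".join(f"{k}={v:.3f}" for k, v in metrics.items()),
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        self.ts_model.save(path)
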