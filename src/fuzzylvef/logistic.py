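"""Logistic regression baseline, fitted by maximum likelihood (IRLS).

The model is pi(x) = exp(g(x)) / (1 + exp(g(x))) with linear logit
g(x) = beta_0 + beta_1 x_1 + ... + beta_p x_p. Classification applies a
threshold to pi(x), chosen on the ROC exactly as for the fuzzy model so
the two families are compared on equal footing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocessing import CohortTable, MinMaxNormalizer

__all__ = [
    "LogisticModel",
    "fit_logistic",
    "predict_proba",
    "LogisticClassifier",
    "LogisticResults",
]

_SEPARATION_BETA = 1e4


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # sum y*eta - log(1 + e^eta), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass
class LogisticModel:
    """Fitted coefficients (intercept first) with convergence diagnostics."""

    beta: np.ndarray
    input_names: tuple[str, ...] = ()
    converged: bool = True
    iterations: int = 0
    threshold: Optional[float] = None
    normalization_ranges: Optional[dict[str, tuple[float, float]]] = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_inputs(self) -> int:
        return len(self.beta) - 1

    def logit(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} inputs, got {X.shape[1]}")
        return self.beta[0] + X @ self.beta[1:]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.logit(X))

    def classify(self, X: np.ndarray) -> np.ndarray:
        if self.threshold is None:
            raise RuntimeError("model threshold is not calibrated; cannot classify")
        return (self.predict_proba(X) >= self.threshold).astype(int)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "logistic",
                "input_names": list(self.input_names),
                "beta": list(self.beta),
                "converged": self.converged,
                "iterations": self.iterations,
                "threshold": self.threshold,
                "normalization_ranges": (
                    None
                    if self.normalization_ranges is None
                    else {k: list(v) for k, v in self.normalization_ranges.items()}
                ),
                "metadata": self.metadata,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "LogisticModel":
        d = json.loads(text)
        if d.get("kind") != "logistic":
            raise ValueError("not a logistic model JSON")
        ranges = d.get("normalization_ranges")
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            input_names=tuple(d["input_names"]),
            converged=d["converged"],
            iterations=d["iterations"],
            threshold=d.get("threshold"),
            normalization_ranges=(
                None if ranges is None else {k: tuple(v) for k, v in ranges.items()}
            ),
            metadata=d.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "LogisticModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 0.0,
    input_names: Optional[Sequence[str]] = None,
) -> LogisticModel:
    """Maximum-likelihood logistic regression via iteratively reweighted
    least squares (Newton-Raphson with step halving).

    The log-likelihood is non-decreasing across iterations; convergence is
    declared when the score (gradient) max-norm falls below ``tol``.
    Complete or quasi-complete separation drives |beta| to infinity; it is
    detected and reported via ``converged=False`` with a warning rather
    than raising. ``ridge`` adds an optional L2 penalty (off by default).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if n <= p + 1:
        raise ValueError("need N > p + 1 samples")

    design = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    eta = design @ beta
    ll = _log_likelihood(y, eta) - 0.5 * ridge * beta @ beta
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = _sigmoid(eta)
        grad = design.T @ (y - mu) - ridge * beta
        if np.abs(grad).max() < tol:
            converged = True
            break
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        H = (design * w[:, None]).T @ design + ridge * np.eye(p + 1)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving keeps the penalized log-likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta_c = design @ cand
            ll_c = _log_likelihood(y, eta_c) - 0.5 * ridge * cand @ cand
            if ll_c >= ll - 1e-12:
                beta, eta, ll = cand, eta_c, ll_c
                break
            scale *= 0.5
        else:
            break
        if np.abs(beta).max() > _SEPARATION_BETA:
            break

    if not converged:
        mu = _sigmoid(eta)
        grad = design.T @ (y - mu) - ridge * beta
        converged = bool(np.abs(grad).max() < tol)
    if ridge == 0.0 and eta[y == 1].min() > eta[y == 0].max():
        # complete separation: the unpenalized MLE does not exist, however
        # small the final gradient looks numerically
        converged = False
    if not converged:
        warnings.warn(
            "logistic fit did not converge (possible complete separation); "
            "coefficients may be diverging",
            RuntimeWarning,
            stacklevel=2,
        )
    names = tuple(input_names) if input_names is not None else tuple(
        f"x{j + 1}" for j in range(p)
    )
    return LogisticModel(
        beta=beta, input_names=names, converged=converged, iterations=it
    )


def predict_proba(model: LogisticModel, x: np.ndarray):
    """Event probability pi(x); scalar for a single sample."""
    out = model.predict_proba(np.atleast_2d(x))
    return float(out[0]) if np.ndim(x) == 1 else out


# --------------------------------------------------------------------------
# statsmodels-style model / results pair
# --------------------------------------------------------------------------


class LogisticClassifier:
    """Logistic-regression classifier with the same surface as the TS model."""

    def __init__(
        self,
        endog,
        exog,
        feature_names: Optional[Sequence[str]] = None,
        normalize: bool = True,
        ridge: float = 0.0,
    ):
        exog = pd.DataFrame(np.atleast_2d(np.asarray(exog, dtype=float)))
        if feature_names is not None:
            exog.columns = list(feature_names)
        else:
            exog.columns = [f"x{j + 1}" for j in range(exog.shape[1])]
        self.endog = np.asarray(endog, dtype=int).ravel()
        self.exog = exog
        self.normalize = normalize
        self.ridge = ridge

    @classmethod
    def from_cohort(cls, table: CohortTable, **kwargs) -> "LogisticClassifier":
        return cls(table.y, table.data, feature_names=table.feature_names, **kwargs)

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> "LogisticResults":
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
        lm = fit_logistic(
            Xn,
            self.endog,
            tol=tol,
            max_iter=max_iter,
            ridge=self.ridge,
            input_names=self.exog.columns,
        )
        lm.normalization_ranges = ranges
        scores = lm.predict_proba(Xn)
        roc = roc_curve(scores, self.endog)
        lm.threshold = float(select_threshold(roc))
        return LogisticResults(self, lm, scaler)


class LogisticResults:
    """Fitted logistic baseline: coefficients, threshold, diagnostics."""

    def __init__(self, model: LogisticClassifier, lm: LogisticModel, scaler):
        self.model = model
        self.fitted = lm
        self.scaler = scaler

    @property
    def params(self) -> np.ndarray:
        return self.fitted.beta

    @property
    def converged(self) -> bool:
        return self.fitted.converged

    @property
    def threshold(self) -> float:
        return self.fitted.threshold

    def _normalized(self, exog) -> np.ndarray:
        exog = pd.DataFrame(np.atleast_2d(np.asarray(exog, dtype=float)))
        exog.columns = list(self.model.exog.columns)
        if self.scaler is None:
            return exog.to_numpy()
        return self.scaler.transform(exog).to_numpy()

    def predict_score(self, exog=None) -> np.ndarray:
        X = self.model.exog if exog is None else exog
        return self.fitted.predict_proba(self._normalized(X))

    def predict(self, exog=None) -> np.ndarray:
        X = self.model.exog if exog is None else exog
        return (self.predict_score(X) >= self.threshold).astype(int)

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
        names = ["intercept", *self.model.exog.columns]
        coef = pd.Series(self.fitted.beta, index=names, name="beta")
        metrics = self.training_metrics()
        return "\n".join(
            [
                "Logistic regression classifier (severely depressed LVEF)",
                "=" * 60,
                f"converged: {self.converged}   iterations: {self.fitted.iterations}"
                f"   threshold: {self.threshold:.4f}",
                "",
                coef.to_string(float_format=lambda v: f"{v: .4f}"),
                "",
                "training: " + "  ".join(f"{k}={v:.3f}" for k, v in metrics.items()),
            ]
        )

    def save(self, path) -> None:
        self.fitted.save(path)
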