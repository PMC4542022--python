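"""Sequential forward selection (SFS) with a cross-validated AUC criterion,
and the consensus ("most often selected") rule across repeated runs."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import repeated_stratified_cv
from .preprocessing import CohortTable

__all__ = ["SFSTrace", "sfs", "run_repeated_sfs", "selection_frequencies", "consensus_features"]


@dataclass
class SFSTrace:
    """Record of one greedy SFS run.

    ``steps`` holds the accepted (feature, CV mean AUC) per round, in
    acceptance order, so the AUC sequence along steps is non-decreasing up
    to the stop. ``candidate_aucs`` keeps every candidate evaluation per
    round for inspection.
    """

    steps: list[tuple[str, float]] = field(default_factory=list)
    selected_set: list[str] = field(default_factory=list)
    candidates: list[str] = field(default_factory=list)
    candidate_aucs: list[dict[str, float]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "steps": [[f, a] for f, a in self.steps],
                "selected_set": self.selected_set,
                "candidates": self.candidates,
                "candidate_aucs": self.candidate_aucs,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SFSTrace":
        d = json.loads(text)
        return cls(
            steps=[(f, float(a)) for f, a in d["steps"]],
            selected_set=list(d["selected_set"]),
            candidates=list(d["candidates"]),
            candidate_aucs=[dict(c) for c in d.get("candidate_aucs", [])],
        )


def sfs(
    builder: Callable[[CohortTable, int], object],
    table: CohortTable,
    k: int = 5,
    cv_repetitions: int = 1,
    seed: int = 0,
    improvement_tol: float = 1e-4,
    max_features: Optional[int] = None,
) -> SFSTrace:
    """Greedy forward selection maximizing cross-validated mean AUC.

    Each round evaluates every remaining candidate feature added to the
    incumbent set under repeated stratified k-fold CV (same fold
    configuration for all candidates in a round, for a fair comparison)
    and accepts the best candidate iff it improves the incumbent mean AUC
    by more than ``improvement_tol``; otherwise selection stops. Ties
    break toward the lowest candidate index. Candidates whose CV fails are
    skipped with a warning.
    """
    features = table.feature_names
    if not features:
        raise ValueError("table has no candidate features")
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    trace = SFSTrace(candidates=list(features))
    incumbent = -np.inf
    limit = max_features if max_features is not None else len(features)

    while len(selected) < limit:
        round_seed = int(rng.integers(2**31 - 1))
        scores: dict[str, float] = {}
        for f in features:
            if f in selected:
                continue
            try:
                report = repeated_stratified_cv(
                    builder,
                    table.select(selected + [f]),
                    k=k,
                    repetitions=cv_repetitions,
                    seed=round_seed,
                )
                scores[f] = float(report.records["auc"].mean())
            except Exception as exc:  # CV failure on this candidate only
                warnings.warn(
                    f"skipping candidate {f!r}: cross-validation failed ({exc})",
                    RuntimeWarning,
                    stacklevel=2,
                )
        if not scores:
            break
        trace.candidate_aucs.append(scores)
        best = max(scores, key=lambda f: (scores[f], -features.index(f)))
        if scores[best] <= incumbent + improvement_tol:
            break
        selected.append(best)
        incumbent = scores[best]
        trace.steps.append((best, incumbent))

    trace.selected_set = list(selected)
    return trace


def run_repeated_sfs(
    builder: Callable[[CohortTable, int], object],
    table: CohortTable,
    repetitions: int = 50,
    seed: int = 0,
    **sfs_kwargs,
) -> list[SFSTrace]:
    """Re-run SFS under ``repetitions`` random CV configurations.

    The study design repeats selection over many random fold
    configurations and keeps the features most often selected; 50
    repetitions is the desk-scale default (500 in the original design).
    """
    rng = np.random.default_rng(seed)
    return [
        sfs(builder, table, seed=int(rng.integers(2**31 - 1)), **sfs_kwargs)
        for _ in range(repetitions)
    ]


def selection_frequencies(traces: Sequence[SFSTrace]) -> pd.Series:
    """Fraction of traces in which each candidate feature was selected."""
    if not traces:
        raise ValueError("need at least one trace")
    candidates = traces[0].candidates
    counts = {f: 0 for f in candidates}
    for t in traces:
        for f in t.selected_set:
            counts[f] = counts.get(f, 0) + 1
    return pd.Series(counts, dtype=float) / len(traces)


def consensus_features(traces: Sequence[SFSTrace], quota: float = 0.5) -> list[str]:
    """Features selected in more than ``quota`` of the SFS repetitions.

    Returned in the candidate order of the traces; deterministic given the
    traces.
    """
    freq = selection_frequencies(traces)
    return [f for f in traces[0].candidates if freq.get(f, 0.0) > quota]
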