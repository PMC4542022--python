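"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: fuzzy c-means from the
textbook update equations, AUC by brute-force pairwise concordance, and
best-subset search by exhaustive enumeration.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def fcm_oracle(
    X: np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    init_memberships: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Plain fuzzy c-means (Euclidean distance). Returns (U, centers)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if init_memberships is None:
        rng = np.random.default_rng(seed)
        g = rng.gamma(1.0, size=(c, n))
        U = g / g.sum(axis=0)
    else:
        U = np.asarray(init_memberships, dtype=float).copy()
    centers = np.zeros((c, X.shape[1]))
    for _ in range(max_iter):
        Um = U**m
        centers = (Um @ X) / Um.sum(axis=1)[:, None]
        d2 = ((X[None, :, :] - centers[:, None, :]) ** 2).sum(axis=2)
        U_new = np.empty_like(U)
        zero = d2 < 1e-30
        hit = zero.any(axis=0)
        U_new[:, hit] = zero[:, hit] / zero[:, hit].sum(axis=0)
        reg = ~hit
        inv = d2[:, reg] ** (-1.0 / (m - 1.0))
        U_new[:, reg] = inv / inv.sum(axis=0)
        delta = np.abs(U_new - U).max()
        U = U_new
        if delta < tol:
            break
    return U, centers


def auc_bruteforce(scores, labels) -> float:
    """Pairwise concordance probability, ties counted one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def exhaustive_best_subset(score_fn, features: list[str]) -> set[str]:
    """Best subset by enumerating every nonempty subset (small p only)."""
    best, best_score = None, -np.inf
    for r in range(1, len(features) + 1):
        for combo in combinations(features, r):
            s = score_fn(set(combo))
            if s > best_score:
                best, best_score = set(combo), s
    return best
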