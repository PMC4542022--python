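"""Gustafson-Kessel (GK) fuzzy clustering.

GK clustering extends fuzzy c-means with a per-cluster adaptive norm
matrix ``A_i = (rho_i det F_i)^(1/p) F_i^{-1}`` derived from the fuzzy
covariance ``F_i`` under the unit-volume constraint ``det A_i = rho_i``
(here rho_i = 1). The induced Mahalanobis-like distance lets clusters take
ellipsoidal shapes of arbitrary orientation, which plain (Euclidean) fuzzy
c-means cannot represent. This is the cluster engine behind the
Takagi-Sugeno model identification: each cluster becomes one fuzzy rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FuzzyPartition", "GKCluster", "gk_cluster", "gk_objective", "membership_of"]

_ZERO_DIST = 1e-30
_MAX_COND = 1e12


@dataclass
class GKCluster:
    """One GK cluster: center, fuzzy covariance and the induced norm matrix."""

    center: np.ndarray
    covariance: np.ndarray
    norm_matrix: np.ndarray
    volume_rho: float = 1.0

    def distance_sq(self, X: np.ndarray) -> np.ndarray:
        """Squared induced distance of each row of X to the center."""
        d = np.atleast_2d(X) - self.center
        return np.maximum(np.einsum("nj,jk,nk->n", d, self.norm_matrix, d), 0.0)


@dataclass
class FuzzyPartition:
    """c x N membership matrix with its fuzziness exponent and objective trace."""

    memberships: np.ndarray
    fuzziness_m: float
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_clusters(self) -> int:
        return self.memberships.shape[0]

    def harden(self) -> np.ndarray:
        """Crisp cluster index per sample (argmax membership)."""
        return self.memberships.argmax(axis=0)


def _condition_covariance(F: np.ndarray, name: str) -> np.ndarray:
    """Shrink a fuzzy covariance toward a scaled identity until well conditioned.

    Small or collinear clusters make F (near-)singular, which breaks the
    inverse in the norm matrix; shrinkage trades a little anisotropy for
    numerical stability.
    """
    p = F.shape[0]
    F = 0.5 * (F + F.T)
    scale = max(np.trace(F) / p, 1e-12)
    gamma = 1e-6
    while True:
        eigvals = np.linalg.eigvalsh(F)
        if eigvals[0] > 0 and eigvals[-1] / eigvals[0] < _MAX_COND:
            return F
        if gamma > 1.0:
            return scale * np.eye(p)
        warnings.warn(
            f"singular fuzzy covariance in {name}; regularizing toward identity",
            RuntimeWarning,
            stacklevel=3,
        )
        F = (1.0 - gamma) * F + gamma * scale * np.eye(p)
        gamma *= 10.0


def _norm_matrix(F: np.ndarray, rho: float) -> np.ndarray:
    p = F.shape[0]
    sign, logdet = np.linalg.slogdet(F)
    A = (rho ** (1.0 / p)) * np.exp(logdet / p) * np.linalg.inv(F)
    return 0.5 * (A + A.T)


def _update_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Inverse-distance membership update; exact-hit samples split equally
    among their zero-distance clusters."""
    c, n = d2.shape
    U = np.empty((c, n))
    zero = d2 < _ZERO_DIST
    hit = zero.any(axis=0)
    if hit.any():
        U[:, hit] = zero[:, hit] / zero[:, hit].sum(axis=0)
    reg = ~hit
    if reg.any():
        expo = 1.0 / (m - 1.0)
        inv = d2[:, reg] ** (-expo)
        U[:, reg] = inv / inv.sum(axis=0)
    return U


def gk_cluster(
    X: np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
    norm: str = "adaptive",
    init_memberships: np.ndarray | None = None,
) -> tuple[FuzzyPartition, list[GKCluster]]:
    """Cluster the rows of X into c fuzzy clusters by alternating optimization.

    Parameters
    ----------
    X : (N, p) data matrix.
    c : number of clusters, 1 <= c < N.
    m : fuzziness exponent (> 1); 2.0 is the conventional default.
    tol : stop when the largest absolute membership change falls below this.
    max_iter : iteration cap.
    seed : seeds the symmetric-Dirichlet membership initialization.
    norm : "adaptive" for the GK determinant-constrained norm matrices,
        "identity" to force Euclidean distances (then the algorithm reduces
        exactly to fuzzy c-means, which the tests exploit as an oracle).
    init_memberships : optional explicit (c, N) initial membership matrix
        (columns must sum to 1); overrides the seeded initialization.

    Returns
    -------
    (FuzzyPartition, list of GKCluster). Membership columns sum to one and
    the recorded objective trace is non-increasing.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n, p = X.shape
    if not 1 <= c < n:
        raise ValueError("need N > c >= 1")
    if m <= 1:
        raise ValueError("fuzziness exponent m must exceed 1")
    if norm not in ("adaptive", "identity"):
        raise ValueError("norm must be 'adaptive' or 'identity'")

    if init_memberships is not None:
        U = np.asarray(init_memberships, dtype=float).copy()
        if U.shape != (c, n) or not np.allclose(U.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("init_memberships must be (c, N) with unit column sums")
    else:
        rng = np.random.default_rng(seed)
        g = rng.gamma(1.0, size=(c, n))
        U = g / g.sum(axis=0)

    trace: list[float] = []
    clusters: list[GKCluster] = []
    for _ in range(max_iter):
        Um = U**m
        weights = Um.sum(axis=1)
        centers = (Um @ X) / weights[:, None]

        clusters = []
        d2 = np.empty((c, n))
        for i in range(c):
            diff = X - centers[i]
            F = (Um[i][:, None] * diff).T @ diff / weights[i]
            F = _condition_covariance(F, "gk_cluster")
            A = np.eye(p) if norm == "identity" else _norm_matrix(F, 1.0)
            cl = GKCluster(center=centers[i], covariance=F, norm_matrix=A)
            clusters.append(cl)
            d2[i] = cl.distance_sq(X)

        U_new = _update_memberships(d2, m)
        trace.append(float(((U_new**m) * d2).sum()))
        delta = np.abs(U_new - U).max()
        U = U_new
        if delta < tol:
            break

    partition = FuzzyPartition(
        memberships=U, fuzziness_m=m, objective_trace=np.asarray(trace)
    )
    return partition, clusters


def gk_objective(
    X: np.ndarray, partition: FuzzyPartition, clusters: list[GKCluster]
) -> float:
    """Weighted within-cluster scatter: sum_ik u_ik^m d_ik^2 (>= 0)."""
    X = np.asarray(X, dtype=float)
    U = partition.memberships
    if U.shape[0] != len(clusters) or U.shape[1] != X.shape[0]:
        raise ValueError("partition/clusters/X shapes are inconsistent")
    d2 = np.stack([cl.distance_sq(X) for cl in clusters])
    return float(((U**partition.fuzziness_m) * d2).sum())


def membership_of(
    x: np.ndarray, clusters: list[GKCluster], m: float = 2.0
) -> np.ndarray:
    """Membership degrees of a single sample in each cluster (sum to 1).

    A sample exactly at a center gets full membership there; ties at zero
    distance are split equally.
    """
    x = np.asarray(x, dtype=float).reshape(1, -1)
    if x.shape[1] != clusters[0].center.shape[0]:
        raise ValueError("sample dimension does not match clusters")
    d2 = np.stack([cl.distance_sq(x) for cl in clusters])
    return _update_memberships(d2, m)[:, 0]
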