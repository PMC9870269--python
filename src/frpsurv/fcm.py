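"""Fuzzy c-means (FCM) clustering.

FCM assigns every data point a graded membership over ``c`` clusters
(memberships sum to one per point) by alternately minimising the weighted
within-cluster distance objective

    F_m = sum_i sum_k mu_ik^m ||s_i - v_k||^2

over cluster centers ``v_k`` and memberships ``mu_ik``.  The pipeline uses
this routine twice: to compress a long flattened deep-feature vector into a
short sequence of cluster centers, and to grade the similarity between
embedded phase-space states when building a fuzzy recurrence plot.

The implementation is deliberately self-contained: the membership/center
update pair and the stopping rule are the substance of the method, not a
detail to delegate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FCMConfig",
    "FuzzyPartition",
    "fcm_fit",
    "update_centers",
    "update_memberships",
    "fcm_objective",
]

#: distances below this are treated as a point/center coincidence
COINCIDENCE_TOL = 1e-12


@dataclass(frozen=True)
class FCMConfig:
    """Parameters of one FCM run.

    Parameters
    ----------
    c : int
        Number of clusters (>= 1; c = 1 is the degenerate all-in-one case).
    m : float
        Fuzzy weighting exponent, > 1.  m -> 1 approaches hard k-means,
        larger m gives softer memberships.  Default 2.
    delta : float
        Convergence threshold: iteration stops when the maximum absolute
        elementwise change of the membership matrix is <= delta.
    max_iter : int
        Maximum number of update iterations (Q).
    seed : int or None
        Seed for the random membership initialisation.
    """

    c: int
    m: float = 2.0
    delta: float = 1e-5
    max_iter: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if int(self.c) != self.c or self.c < 1:
            raise ValueError(f"c must be an integer >= 1, got {self.c!r}")
        if not self.m > 1:
            raise ValueError(f"fuzzy exponent m must be > 1, got {self.m!r}")
        if not self.delta > 0:
            raise ValueError(f"delta must be > 0, got {self.delta!r}")
        if int(self.max_iter) != self.max_iter or self.max_iter < 1:
            raise ValueError(f"max_iter must be an integer >= 1, got {self.max_iter!r}")


@dataclass
class FuzzyPartition:
    """Result of an FCM fit.

    Attributes
    ----------
    memberships : (n_points, c) ndarray
        Membership grades; each row sums to 1.
    centers : (c, dim) ndarray
        Cluster centers, ordered ascending by value (1-D data) or by the
        first principal coordinate of the centers (multi-D).
    n_iterations : int
        Number of center/membership update pairs performed.
    converged : bool
        Whether the membership change dropped to <= delta before max_iter.
    objective_trace : ndarray
        Objective value after each update pair; non-increasing.
    """

    memberships: np.ndarray
    centers: np.ndarray
    n_iterations: int
    converged: bool
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def save(self, path: str | Path) -> None:
        """Serialize to ``<path>.json`` (metadata) + ``<path>.csv`` pair.

        The CSV holds the membership matrix followed by the centers, both in
        full double precision; the JSON records shapes and fit metadata.
        """
        path = Path(path)
        meta = {
            "n_points": int(self.memberships.shape[0]),
            "c": int(self.memberships.shape[1]),
            "dim": int(self.centers.shape[1]),
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
            "objective_trace": [float(v) for v in self.objective_trace],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        flat = np.concatenate(
            [self.memberships.ravel(), self.centers.ravel()]
        )
        np.savetxt(path.with_suffix(".csv"), flat, fmt="%.17g")

    @classmethod
    def load(cls, path: str | Path) -> "FuzzyPartition":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        flat = np.loadtxt(path.with_suffix(".csv"))
        n, c, dim = meta["n_points"], meta["c"], meta["dim"]
        memberships = flat[: n * c].reshape(n, c)
        centers = flat[n * c:].reshape(c, dim)
        return cls(
            memberships=memberships,
            centers=centers,
            n_iterations=meta["n_iterations"],
            converged=meta["converged"],
            objective_trace=np.asarray(meta["objective_trace"]),
        )


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("points must be non-empty")
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.ndim != 2:
        raise ValueError(f"points must be 1-D or 2-D, got shape {pts.shape}")
    if not np.isfinite(pts).all():
        raise ValueError("points contain non-finite values")
    return pts


def _distances(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix, shape (n_points, c)."""
    diff = points[:, None, :] - centers[None, :, :]
    return np.sqrt((diff * diff).sum(axis=2))


def update_centers(points, memberships, m: float = 2.0) -> np.ndarray:
    """Center update: v_k = sum_i mu_ik^m s_i / sum_i mu_ik^m.

    Each center is a convex combination of the points, so it lies in their
    convex hull.  Raises if a cluster has zero total membership mass.
    """
    pts = _as_points(points)
    U = np.asarray(memberships, dtype=float)
    W = U ** m
    mass = W.sum(axis=0)
    if np.any(mass <= 0):
        raise ValueError("cluster with zero membership mass")
    return (W.T @ pts) / mass[:, None]


def update_memberships(points, centers, m: float = 2.0) -> np.ndarray:
    """Membership update: mu_ik = 1 / sum_j (||s_i-v_k|| / ||s_i-v_j||)^(2/(m-1)).

    A point whose distance to one or more centers falls below
    ``COINCIDENCE_TOL`` gets its membership split equally over the
    coincident centers (the limit of the formula), avoiding division by
    zero.
    """
    pts = _as_points(points)
    V = np.atleast_2d(np.asarray(centers, dtype=float))
    d = _distances(pts, V)
    p = 2.0 / (m - 1.0)

    U = np.zeros_like(d)
    coincident = d < COINCIDENCE_TOL
    hit = coincident.any(axis=1)
    if hit.any():
        U[hit] = coincident[hit] / coincident[hit].sum(axis=1, keepdims=True)
    free = ~hit
    if free.any():
        inv = d[free] ** (-p)
        U[free] = inv / inv.sum(axis=1, keepdims=True)
    return U


def fcm_objective(points, memberships, centers, m: float = 2.0) -> float:
    """Weighted within-cluster sum of squared distances F_m."""
    pts = _as_points(points)
    U = np.asarray(memberships, dtype=float)
    V = np.atleast_2d(np.asarray(centers, dtype=float))
    d2 = _distances(pts, V) ** 2
    return float(((U ** m) * d2).sum())


def _sort_key(centers: np.ndarray) -> np.ndarray:
    """Scalar ordering key per cluster: the center value in 1-D, else the
    projection of each center onto the first principal axis of the centers."""
    if centers.shape[1] == 1:
        return centers[:, 0]
    centered = centers - centers.mean(axis=0)
    # SVD of the (c, dim) center matrix; first right-singular vector
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # fix the sign for determinism
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return centers @ axis


def fcm_fit(points, config: FCMConfig, init: np.ndarray | None = None) -> FuzzyPartition:
    """Run FCM to convergence.

    Alternates the center and membership updates starting from a random
    row-normalised membership matrix (symmetric Dirichlet per point, seeded
    via ``config.seed``) until the maximum absolute elementwise membership
    change is <= ``config.delta`` or ``config.max_iter`` iterations have
    run.  Clusters in the returned partition are deterministically ordered
    (ascending center value in 1-D, first principal coordinate otherwise).

    Parameters
    ----------
    points : array-like, shape (n_points,) or (n_points, dim)
    config : FCMConfig
    init : ndarray, optional
        Explicit initial membership matrix, shape (n_points, c); rows must
        sum to 1.  Overrides the seeded random initialisation (useful for
        oracle comparisons and permutation tests).
    """
    pts = _as_points(points)
    n_pts = pts.shape[0]
    c = config.c

    if c == 1:
        center = pts.mean(axis=0, keepdims=True)
        U = np.ones((n_pts, 1))
        return FuzzyPartition(
            memberships=U,
            centers=center,
            n_iterations=0,
            converged=True,
            objective_trace=np.array([fcm_objective(pts, U, center, config.m)]),
        )

    n_distinct = np.unique(pts, axis=0).shape[0]
    if c > n_distinct:
        raise ValueError(
            f"c={c} exceeds the number of distinct points ({n_distinct})"
        )

    if init is not None:
        U = np.asarray(init, dtype=float)
        if U.shape != (n_pts, c):
            raise ValueError(f"init shape {U.shape} != {(n_pts, c)}")
        if not np.allclose(U.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("init rows must sum to 1")
    else:
        rng = np.random.default_rng(config.seed)
        U = rng.dirichlet(np.ones(c), size=n_pts)

    trace: list[float] = []
    converged = False
    q = 0
    for q in range(1, config.max_iter + 1):
        centers = update_centers(pts, U, config.m)
        U_next = update_memberships(pts, centers, config.m)
        trace.append(fcm_objective(pts, U_next, centers, config.m))
        change = np.abs(U - U_next).max()
        U = U_next
        if change <= config.delta:
            converged = True
            break

    order = np.argsort(_sort_key(centers), kind="stable")
    return FuzzyPartition(
        memberships=U[:, order],
        centers=centers[order],
        n_iterations=q,
        converged=converged,
        objective_trace=np.asarray(trace),
    )
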