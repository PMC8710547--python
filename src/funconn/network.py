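"""Connectome construction: partial-correlation matrices and sparsity
thresholding.

Each subject's regional time series (T timepoints x N regions) is turned
into a full partial-correlation matrix — the correlation of every region
pair conditional on all remaining N-2 regions, read off the (optionally
shrunk) inverse covariance — and then binarized over a sweep of sparsity
thresholds: at sparsity S the round(S * N(N-1)/2) pairs with the largest
absolute weights become edges of an undirected, unweighted graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import LedoitWolf

__all__ = [
    "ConnectivityMatrix",
    "BinaryNetwork",
    "SparsitySweep",
    "partial_correlation_matrix",
    "binarize_at_sparsity",
    "sweep_networks",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N matrix of partial-correlation weights, zero diagonal."""

    weights: np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric (tolerance 1e-10)")
        self.weights = w
        if self.node_labels is None:
            self.node_labels = [f"node{i}" for i in range(w.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected unweighted graph at one sparsity threshold."""

    adjacency: np.ndarray
    sparsity: float = field(default=np.nan)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        a = (a != 0)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not (a == a.T).all():
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(a, False)
        self.adjacency = a
        n = a.shape[0]
        if n > 1:
            achieved = a.sum() / (n * (n - 1))
        else:
            achieved = 0.0
        if np.isnan(self.sparsity):
            self.sparsity = achieved

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> np.ndarray:
        """(E, 2) int64 array of edges with i < j, lexicographic order."""
        i, j = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[i, j]
        return np.column_stack([i[mask], j[mask]]).astype(np.int64)


@dataclass
class SparsitySweep:
    """Ordered grid of sparsity thresholds, default 0.10 to 0.40 step 0.01."""

    s_min: float = 0.10
    s_max: float = 0.40
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.s_min < self.s_max <= 1.0):
            raise ValueError("require 0 < s_min < s_max <= 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def thresholds(self) -> np.ndarray:
        n_steps = int(round((self.s_max - self.s_min) / self.step))
        t = self.s_min + self.step * np.arange(n_steps + 1)
        return np.round(t, 10)


def partial_correlation_matrix(
    ts: np.ndarray,
    estimator: str = "precision",
    shrinkage: float | None = None,
    node_labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Full partial-correlation matrix of regional time series.

    Parameters
    ----------
    ts : (T, N) array
        One subject's time series, T timepoints x N regions.
    estimator : {"precision", "shrinkage", "auto"}
        "precision" inverts the sample covariance directly (requires
        T > N); "shrinkage" regularizes it first — by the Ledoit–Wolf
        estimate, or toward ``mu * I`` with the given `shrinkage`
        intensity in [0, 1).  "auto" uses precision when the sample
        covariance is comfortably well-conditioned and falls back to
        Ledoit–Wolf otherwise (band-pass filtering can leave fewer
        effective temporal degrees of freedom than regions, making the
        sample covariance singular even when T > N).
    shrinkage : float, optional
        Explicit shrinkage intensity; only used with
        ``estimator="shrinkage"``. ``None`` selects Ledoit–Wolf.

    Returns
    -------
    ConnectivityMatrix
        Entry (i, j) is -P_ij / sqrt(P_ii P_jj) for precision matrix P:
        the correlation of regions i and j given all other regions.
    """
    x = np.asarray(ts, dtype=float)
    if x.ndim != 2:
        raise ValueError("time series must be a 2-D (T, N) array")
    t_len, n = x.shape
    if n < 2:
        raise ValueError("need at least 2 regions")
    if t_len <= 2:
        raise ValueError("need more than 2 timepoints")
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd <= 1e-12 * (np.abs(x.mean(axis=0)) + 1.0))
    if dead.size:
        labels = node_labels or [f"node{i}" for i in range(n)]
        raise ValueError(
            "constant (zero-variance) time series at node(s): "
            + ", ".join(labels[i] for i in dead)
        )
    if estimator == "auto":
        if t_len > n:
            cov = np.cov(x, rowvar=False)
            estimator = "precision" if np.linalg.cond(cov) < 1e8 else "shrinkage"
        else:
            estimator = "shrinkage"
    if estimator == "precision":
        if t_len <= n:
            raise ValueError(
                f"T={t_len} <= N={n}: sample covariance is singular; "
                'use estimator="shrinkage"'
            )
        cov = np.cov(x, rowvar=False)
    elif estimator == "shrinkage":
        if shrinkage is None:
            cov = LedoitWolf(assume_centered=False).fit(x).covariance_
        else:
            if not 0.0 <= shrinkage < 1.0:
                raise ValueError("shrinkage intensity must be in [0, 1)")
            s = np.cov(x, rowvar=False)
            mu = np.trace(s) / n
            cov = (1.0 - shrinkage) * s + shrinkage * mu * np.eye(n)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    prec = np.linalg.inv(cov)
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    pc = np.clip((pc + pc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(pc, 0.0)
    return ConnectivityMatrix(weights=pc, node_labels=node_labels)


def _ranked_pairs(w: ConnectivityMatrix | np.ndarray):
    """Upper-triangle pairs ordered by (|weight| desc, i asc, j asc)."""
    weights = w.weights if isinstance(w, ConnectivityMatrix) else np.asarray(w)
    n = weights.shape[0]
    i, j = np.triu_indices(n, k=1)
    mag = np.abs(weights[i, j])
    order = np.lexsort((j, i, -mag))
    return i[order], j[order], n


def binarize_at_sparsity(w: ConnectivityMatrix | np.ndarray, s: float) -> BinaryNetwork:
    """Binarize a weighted matrix at target sparsity (edge density) `s`.

    Keeps the ``m = round(s * N(N-1)/2)`` pairs with the largest absolute
    weight (ties broken by ascending node-index pair, so sweeps are
    deterministic and nested).
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("sparsity must be in [0, 1]")
    i, j, n = _ranked_pairs(w)
    n_pairs = n * (n - 1) // 2
    m = int(np.floor(s * n_pairs + 0.5))  # round half up
    adj = np.zeros((n, n), dtype=bool)
    adj[i[:m], j[:m]] = True
    adj |= adj.T
    achieved = m / n_pairs if n_pairs else 0.0
    return BinaryNetwork(adjacency=adj, sparsity=achieved)


def sweep_networks(
    w: ConnectivityMatrix | np.ndarray, sweep: SparsitySweep | None = None
) -> list[BinaryNetwork]:
    """One BinaryNetwork per threshold of the sweep; edge sets are nested."""
    sweep = sweep or SparsitySweep()
    i, j, n = _ranked_pairs(w)
    n_pairs = n * (n - 1) // 2
    out = []
    adj = np.zeros((n, n), dtype=bool)
    prev = 0
    for s in sweep.thresholds:
        m = int(np.floor(s * n_pairs + 0.5))
        adj[i[prev:m], j[prev:m]] = True
        adj[j[prev:m], i[prev:m]] = True
        prev = max(prev, m)
        out.append(BinaryNetwork(adjacency=adj.copy(), sparsity=m / n_pairs))
    return out
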