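"""Small-world and efficiency metrics of binary brain networks.

Global parameters: clustering coefficient (Cp), characteristic path length
(Lp), their normalizations against degree-preserving random networks
(gamma = Cp/Cp_rand, lambda = Lp/Lp_rand), the small-worldness scalar
sigma = gamma/lambda, global efficiency (Eg) and local efficiency (Eloc).
Nodal parameters: nodal efficiency (Ne), nodal local efficiency (NLe) and
nodal clustering coefficient (NCp).

Conventions for sparse/disconnected graphs: distances between unreachable
pairs are +inf; Lp averages hop counts over *reachable* ordered pairs only
(NaN when there are none); efficiencies use 1/inf = 0; clustering and
local efficiency of a node with degree < 2 are 0.  Under these
conventions the global metrics are exactly the nodal means:
mean(NCp) = Cp, mean(Ne) = Eg, mean(NLe) = Eloc.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._graph_kernels import (
    bfs_all_pairs,
    double_edge_swap,
    local_efficiency_per_node,
    null_cp_lp_batch,
)
from .network import BinaryNetwork

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "NullModelConfig",
    "nodal_clustering",
    "shortest_paths",
    "global_metrics",
    "nodal_metrics",
    "rewire_null",
    "normalized_metrics",
    "auc_over_sweep",
    "GLOBAL_METRIC_NAMES",
    "NODAL_METRIC_NAMES",
]

logger = logging.getLogger(__name__)

GLOBAL_METRIC_NAMES = ("Cp", "Lp", "gamma", "lambda", "sigma", "Eg", "Eloc")
NODAL_METRIC_NAMES = ("Ne", "NLe", "NCp")


@dataclass
class GlobalMetrics:
    cp: float
    lp: float
    eg: float
    eloc: float
    gamma: float = np.nan
    lam: float = np.nan
    sigma: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {
            "Cp": self.cp,
            "Lp": self.lp,
            "gamma": self.gamma,
            "lambda": self.lam,
            "sigma": self.sigma,
            "Eg": self.eg,
            "Eloc": self.eloc,
        }


@dataclass
class NodalMetrics:
    ne: np.ndarray
    nle: np.ndarray
    ncp: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"Ne": self.ne, "NLe": self.nle, "NCp": self.ncp}


@dataclass
class NullModelConfig:
    """Degree-preserving (Maslov–Sneppen) null ensemble for gamma/lambda."""

    n_nulls: int = 100
    rewires_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nulls < 1:
            raise ValueError("n_nulls must be >= 1")
        if self.rewires_per_edge < 1:
            raise ValueError("rewires_per_edge must be >= 1")


def _adj(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.adjacency
    a = np.asarray(net) != 0
    np.fill_diagonal(a, False)
    return a


def _ncp_all(adj: np.ndarray) -> np.ndarray:
    a = adj.astype(np.float64)
    deg = a.sum(axis=1)
    tri = ((a @ a) * a).sum(axis=1) / 2.0  # triangles through each node
    out = np.zeros(adj.shape[0])
    mask = deg >= 2
    out[mask] = 2.0 * tri[mask] / (deg[mask] * (deg[mask] - 1.0))
    return out


def nodal_clustering(net: BinaryNetwork | np.ndarray, node: int | None = None):
    """Nodal clustering coefficient 2 t_i / (k_i (k_i - 1)); 0 for k_i < 2.

    Returns the full vector, or a scalar when `node` is given.
    """
    ncp = _ncp_all(_adj(net))
    if node is None:
        return ncp
    return float(ncp[node])


def shortest_paths(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """All-pairs hop-count distance matrix (BFS); inf where unreachable."""
    return bfs_all_pairs(np.ascontiguousarray(_adj(net)))


def _lp_eg_ne(dist: np.ndarray):
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    lp = dist[finite].mean() if finite.any() else np.nan
    inv = np.zeros_like(dist)
    inv[finite] = 1.0 / dist[finite]
    ne = inv.sum(axis=1) / max(n - 1, 1)
    return lp, ne

def global_metrics(net: BinaryNetwork | np.ndarray) -> GlobalMetrics:
    """Cp, Lp, Eg and Eloc of one binary network (gamma/lambda/sigma NaN;
    see `normalized_metrics`)."""
    adj = np.ascontiguousarray(_adj(net))
    dist = bfs_all_pairs(adj)
    lp, ne = _lp_eg_ne(dist)
    ncp = _ncp_all(adj)
    nle = local_efficiency_per_node(adj)
    return GlobalMetrics(
        cp=float(ncp.mean()), lp=float(lp),
        eg=float(ne.mean()), eloc=float(nle.mean()),
    )


def nodal_metrics(net: BinaryNetwork | np.ndarray) -> NodalMetrics:
    """Per-node Ne, NLe and NCp."""
    adj = np.ascontiguousarray(_adj(net))
    _, ne = _lp_eg_ne(bfs_all_pairs(adj))
    return NodalMetrics(ne=ne, nle=local_efficiency_per_node(adj), ncp=_ncp_all(adj))


def all_metrics(net: BinaryNetwork | np.ndarray) -> tuple[GlobalMetrics, NodalMetrics]:
    """Global and nodal metrics in one pass (shared distance matrix)."""
    adj = np.ascontiguousarray(_adj(net))
    lp, ne = _lp_eg_ne(bfs_all_pairs(adj))
    ncp = _ncp_all(adj)
    nle = local_efficiency_per_node(adj)
    gm = GlobalMetrics(cp=float(ncp.mean()), lp=float(lp),
                       eg=float(ne.mean()), eloc=float(nle.mean()))
    return gm, NodalMetrics(ne=ne, nle=nle, ncp=ncp)


def rewire_null(
    net: BinaryNetwork | np.ndarray,
    cfg: NullModelConfig | None = None,
    seed: int | None = None,
) -> BinaryNetwork:
    """One degree-preserving random rewiring of `net`.

    Performs `rewires_per_edge * E` successful double-edge swaps; the
    degree sequence and edge count are preserved exactly and the result
    is simple. Deterministic given the seed.
    """
    cfg = cfg or NullModelConfig()
    if seed is None:
        seed = cfg.seed
    adj = _adj(net)
    n = adj.shape[0]
    i, j = np.nonzero(np.triu(adj, k=1))
    edges = np.column_stack([i, j]).astype(np.int64)
    if edges.shape[0] < 2:
        warnings.warn("fewer than 2 edges: nothing to rewire, returning input")
        return BinaryNetwork(adjacency=adj.copy())
    edges = double_edge_swap(
        edges, n, cfg.rewires_per_edge * edges.shape[0], int(seed) & 0x7FFFFFFF
    )
    out = np.zeros((n, n), dtype=bool)
    out[edges[:, 0], edges[:, 1]] = True
    out |= out.T
    return BinaryNetwork(adjacency=out)


def null_cp_lp(
    net: BinaryNetwork | np.ndarray, cfg: NullModelConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Cp and Lp over the null ensemble (arrays of length n_nulls)."""
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_nulls)
    adj = _adj(net)
    i, j = np.nonzero(np.triu(adj, k=1))
    edges = np.column_stack([i, j]).astype(np.int64)
    if edges.shape[0] < 2:
        warnings.warn("fewer than 2 edges: null ensemble equals the input graph")
        cp = _ncp_all(adj).mean()
        lp, _ = _lp_eg_ne(bfs_all_pairs(np.ascontiguousarray(adj)))
        return np.full(cfg.n_nulls, cp), np.full(cfg.n_nulls, lp)
    return null_cp_lp_batch(
        edges,
        adj.shape[0],
        cfg.rewires_per_edge * edges.shape[0],
        (seeds & 0x7FFFFFFF).astype(np.int64),
    )


def normalized_metrics(
    net: BinaryNetwork | np.ndarray, cfg: NullModelConfig | None = None
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) of `net` against its degree-matched nulls.

    gamma = Cp / mean Cp(nulls), lambda = Lp / mean Lp(nulls),
    sigma = gamma / lambda.  NaN where a denominator is 0 or Lp is
    undefined (empty/fully disconnected graph).
    """
    cfg = cfg or NullModelConfig()
    adj = np.ascontiguousarray(_adj(net))
    cp = _ncp_all(adj).mean()
    lp, _ = _lp_eg_ne(bfs_all_pairs(adj))
    null_cp, null_lp = null_cp_lp(net, cfg)
    mean_cp = np.nanmean(null_cp)
    mean_lp = np.nanmean(null_lp)
    gamma = cp / mean_cp if mean_cp > 0 else np.nan
    lam = lp / mean_lp if (np.isfinite(lp) and mean_lp > 0) else np.nan
    sigma = gamma / lam if (np.isfinite(gamma) and np.isfinite(lam) and lam > 0) else np.nan
    if not np.isfinite(gamma):
        logger.warning("null mean Cp is 0 or Cp undefined: gamma reported missing")
    return float(gamma), float(lam), float(sigma)


def auc_over_sweep(thresholds: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal area of a metric curve over the sparsity sweep.

    NaN anywhere in the curve propagates to a NaN AUC (logged), matching
    the treatment of thresholds where a metric is undefined.
    """
    t = np.asarray(thresholds, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise ValueError("thresholds and values must have the same length")
    if t.size < 2:
        raise ValueError("need at least 2 thresholds to integrate")
    if np.isnan(v).any():
        logger.warning("metric curve contains missing values: AUC reported missing")
        return float("nan")
    return float(np.trapezoid(v, t))
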