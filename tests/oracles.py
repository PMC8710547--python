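"""Independent brute-force oracles for the graph metrics.

Deliberately naive: Floyd–Warshall distances, exhaustive neighbour-pair
triangle counting, and direct subgraph efficiency, written without any
shared code with the package's implementations.
"""

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
        for j in range(n):
            if i != j and adj[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def ncp_oracle(adj: np.ndarray, i: int) -> float:
    nbrs = [j for j in range(adj.shape[0]) if adj[i, j]]
    k = len(nbrs)
    if k < 2:
        return 0.0
    t = sum(
        1 for a in range(k) for b in range(a + 1, k) if adj[nbrs[a], nbrs[b]]
    )
    return 2.0 * t / (k * (k - 1))


def cp_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    return sum(ncp_oracle(adj, i) for i in range(n)) / n


def lp_oracle(adj: np.ndarray) -> float:
    d = floyd_warshall(adj)
    vals = [
        d[i, j]
        for i in range(adj.shape[0])
        for j in range(adj.shape[0])
        if i != j and np.isfinite(d[i, j])
    ]
    return float(np.mean(vals)) if vals else float("nan")


def ne_oracle(adj: np.ndarray, i: int) -> float:
    d = floyd_warshall(adj)
    n = adj.shape[0]
    return sum(1.0 / d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])) / (
        n - 1
    )


def eg_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    return sum(ne_oracle(adj, i) for i in range(n)) / n


def subgraph_efficiency_oracle(adj: np.ndarray, nodes: list[int]) -> float:
    k = len(nodes)
    if k < 2:
        return 0.0
    sub = adj[np.ix_(nodes, nodes)]
    d = floyd_warshall(sub)
    total = sum(
        1.0 / d[a, b]
        for a in range(k)
        for b in range(k)
        if a != b and np.isfinite(d[a, b])
    )
    return total / (k * (k - 1))


def nle_oracle(adj: np.ndarray, i: int) -> float:
    nbrs = [j for j in range(adj.shape[0]) if adj[i, j]]
    return subgraph_efficiency_oracle(adj, nbrs)


def eloc_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    return sum(nle_oracle(adj, i) for i in range(n)) / n


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Direct evaluation of the step-up formula q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        running = min(running, m * p[order[rank]] / (rank + 1))
        q_sorted[rank] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def random_graph(rng: np.random.Generator, n: int, density: float) -> np.ndarray:
    adj = rng.random((n, n)) < density
    adj = np.triu(adj, 1)
    adj = adj | adj.T
    return adj
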