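"""Numba kernels for the graph-metric hot loops.

All kernels operate on dense boolean adjacency matrices (or integer edge
lists) so the per-graph cost stays flat across the ~2e5 null-model
evaluations of a full pipeline run.
"""

import numpy as np
from numba import njit

__all__ = [
    "bfs_all_pairs",
    "local_efficiency_per_node",
    "double_edge_swap",
    "mean_clustering",
    "mean_path_length",
    "null_cp_lp_batch",
]


@njit(cache=True)
def bfs_all_pairs(adj):
    """All-pairs hop-count distances of an undirected unweighted graph.

    adj : (N, N) bool adjacency. Returns float64 (N, N); unreachable pairs
    are +inf, the diagonal is 0.
    """
    n = adj.shape[0]
    # CSR neighbour lists: BFS then touches O(N + E) per source
    deg = np.zeros(n, np.int64)
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                deg[i] += 1
    offsets = np.zeros(n + 1, np.int64)
    for i in range(n):
        offsets[i + 1] = offsets[i] + deg[i]
    nbrs = np.empty(offsets[n], np.int64)
    pos = offsets[:-1].copy()
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                nbrs[pos[i]] = j
                pos[i] += 1
    dist = np.full((n, n), np.inf)
    queue = np.empty(n, np.int64)
    for s in range(n):
        dist[s, s] = 0.0
        head = 0
        tail = 1
        queue[0] = s
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for p in range(offsets[u], offsets[u + 1]):
                v = nbrs[p]
                if dist[s, v] == np.inf:
                    dist[s, v] = du + 1.0
                    queue[tail] = v
                    tail += 1
    return dist


@njit(cache=True)
def _subgraph_efficiency(adj, nodes):
    """Global efficiency of the subgraph induced by `nodes`."""
    k = nodes.shape[0]
    if k < 2:
        return 0.0
    sub = np.empty((k, k), np.bool_)
    for a in range(k):
        for b in range(k):
            sub[a, b] = adj[nodes[a], nodes[b]]
    dist = bfs_all_pairs(sub)
    total = 0.0
    for a in range(k):
        for b in range(k):
            if a != b and dist[a, b] != np.inf:
                total += 1.0 / dist[a, b]
    return total / (k * (k - 1))


@njit(cache=True)
def local_efficiency_per_node(adj):
    """Nodal local efficiency: global efficiency of each node's
    neighbour-induced subgraph (0 for degree < 2)."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                k += 1
        if k < 2:
            continue
        nbrs = np.empty(k, np.int64)
        c = 0
        for j in range(n):
            if adj[i, j]:
                nbrs[c] = j
                c += 1
        out[i] = _subgraph_efficiency(adj, nbrs)
    return out


@njit(cache=True)
def mean_clustering(adj):
    """Mean nodal clustering coefficient (degree < 2 counts as 0)."""
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                k += 1
        if k < 2:
            continue
        nbrs = np.empty(k, np.int64)
        c = 0
        for j in range(n):
            if adj[i, j]:
                nbrs[c] = j
                c += 1
        t = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbrs[a], nbrs[b]]:
                    t += 1
        total += 2.0 * t / (k * (k - 1.0))
    return total / n


@njit(cache=True)
def mean_path_length(adj):
    """Mean hop distance over reachable ordered pairs; NaN when none."""
    dist = bfs_all_pairs(adj)
    n = adj.shape[0]
    total = 0.0
    count = 0
    for i in range(n):
        for j in range(n):
            if i != j and dist[i, j] != np.inf:
                total += dist[i, j]
                count += 1
    if count == 0:
        return np.nan
    return total / count


@njit(cache=True)
def double_edge_swap(edges, n_nodes, n_swaps, seed):
    """Maslov–Sneppen degree-preserving rewiring.

    edges : (E, 2) int64, each row an undirected edge (i < j); modified in
    place and returned. Performs `n_swaps` successful swaps (or gives up
    after 20x as many proposals); the degree sequence is invariant and the
    graph stays simple.
    """
    np.random.seed(seed)
    n_edges = edges.shape[0]
    adj = np.zeros((n_nodes, n_nodes), np.bool_)
    for e in range(n_edges):
        adj[edges[e, 0], edges[e, 1]] = True
        adj[edges[e, 1], edges[e, 0]] = True
    done = 0
    tries = 0
    max_tries = 20 * n_swaps
    while done < n_swaps and tries < max_tries:
        tries += 1
        e1 = np.random.randint(n_edges)
        e2 = np.random.randint(n_edges)
        if e1 == e2:
            continue
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if np.random.randint(2) == 1:
            tmp = c
            c = d
            d = tmp
        # propose a-b, c-d  ->  a-d, c-b
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        done += 1
    return edges


@njit(cache=True)
def null_cp_lp_batch(edges0, n_nodes, n_swaps, seeds):
    """Cp and Lp of a batch of degree-preserving rewired nulls.

    edges0 : (E, 2) int64 template edge list; one independently seeded
    rewiring per entry of `seeds`. Returns (cps, lps) arrays.
    """
    n_nulls = seeds.shape[0]
    cps = np.empty(n_nulls)
    lps = np.empty(n_nulls)
    for t in range(n_nulls):
        edges = edges0.copy()
        edges = double_edge_swap(edges, n_nodes, n_swaps, seeds[t])
        adj = np.zeros((n_nodes, n_nodes), np.bool_)
        for e in range(edges.shape[0]):
            adj[edges[e, 0], edges[e, 1]] = True
            adj[edges[e, 1], edges[e, 0]] = True
        cps[t] = mean_clustering(adj)
        lps[t] = mean_path_length(adj)
    return cps, lps
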