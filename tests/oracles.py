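"""Independent brute-force implementations of every centrality measure.

These are written for transparency, not speed: betweenness enumerates
all simple paths with itertools, distances come from a hand-rolled BFS,
eigenvector/subgraph centralities from a dense numpy eigendecomposition
of the adjacency matrix, and PageRank from a direct linear solve of its
fixed-point system.  They share no code path with the package and are
only usable on tiny graphs.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _all_shortest_paths(adj: dict, s, t) -> list[tuple]:
    """All shortest s-t paths by exhaustive simple-path enumeration."""
    nodes = list(adj)
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    d = dist[t]
    paths = []
    # enumerate all orderings of intermediate nodes of the right length
    others = [v for v in nodes if v not in (s, t)]
    for k in range(d - 1, d):  # a shortest path has exactly d-1 interiors
        for interior in itertools.permutations(others, k):
            path = (s,) + interior + (t,)
            if all(path[i + 1] in adj[path[i]] for i in range(len(path) - 1)):
                paths.append(path)
    return paths


def brute_degree(adj: dict) -> dict:
    return {v: len(adj[v]) for v in adj}


def brute_betweenness(adj: dict) -> dict:
    nodes = list(adj)
    out = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            out[v] += through / len(paths)
    return out


def brute_clustering(adj: dict) -> dict:
    out = {}
    for v, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(sorted(nbrs), 2) if b in adj[a]
        )
        out[v] = 2 * links / (k * (k - 1))
    return out


def _adjacency_matrix(adj: dict) -> tuple[list, np.ndarray]:
    nodes = sorted(adj)
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for v, nbrs in adj.items():
        for u in nbrs:
            a[idx[v], idx[u]] = 1.0
    return nodes, a


def _components(adj: dict) -> list[set]:
    seen = set()
    comps = []
    for v in adj:
        if v in seen:
            continue
        comp = set(bfs_distances(adj, v))
        seen |= comp
        comps.append(comp)
    return comps


def brute_eigenvector(adj: dict) -> dict:
    out = {}
    for comp in _components(adj):
        sub = {v: [u for u in adj[v] if u in comp] for v in comp}
        nodes, a = _adjacency_matrix(sub)
        if len(nodes) == 1:
            out[nodes[0]] = 1.0
            continue
        w, v = np.linalg.eigh(a)
        lead = v[:, np.argmax(w)]
        lead = np.abs(lead)  # Perron vector of a connected component
        lead /= np.linalg.norm(lead)
        out.update(zip(nodes, lead.tolist()))
    return out


def brute_pagerank(adj: dict, d: float = 0.85) -> dict:
    """Solve the PageRank fixed point as a dense linear system.

    With dangling mass spread uniformly:
    PR = (1-d)/n 1 + d (M + D) PR  where M[v,u] = 1/deg(u) for u->v
    and D[v,u] = 1/n for dangling u.
    """
    nodes, a = _adjacency_matrix(adj)
    n = len(nodes)
    deg = a.sum(axis=0)
    m = np.zeros((n, n))
    for u in range(n):
        if deg[u] > 0:
            m[:, u] = a[:, u] / deg[u]
        else:
            m[:, u] = 1.0 / n
    x = np.linalg.solve(np.eye(n) - d * m, np.full(n, (1 - d) / n))
    x /= x.sum()
    return dict(zip(nodes, x.tolist()))


def brute_harmonic(adj: dict) -> dict:
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        out[v] = sum(1.0 / d for u, d in dist.items() if u != v)
    return out


def brute_local_efficiency(adj: dict) -> dict:
    out = {}
    for v, nbrs in adj.items():
        if len(nbrs) < 2:
            out[v] = 0.0
            continue
        sub = {u: [w for w in adj[u] if w in nbrs and w != u] for u in nbrs}
        total = 0.0
        pairs = list(itertools.combinations(sorted(nbrs), 2))
        for a, b in pairs:
            dist = bfs_distances(sub, a)
            if b in dist and dist[b] > 0:
                total += 1.0 / dist[b]
        out[v] = total / len(pairs)
    return out


def brute_subgraph(adj: dict) -> dict:
    nodes, a = _adjacency_matrix(adj)
    w, v = np.linalg.eigh(a)
    sc = (v**2) @ np.exp(w)
    return dict(zip(nodes, sc.tolist()))


def brute_annd(adj: dict) -> dict:
    deg = brute_degree(adj)
    return {
        v: (sum(deg[u] for u in nbrs) / len(nbrs)) if nbrs else 0.0
        for v, nbrs in adj.items()
    }


def brute_auc(scores, labels) -> float:
    """AUC as the literal concordant-pair fraction with 0.5 tie credit."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def graph_to_adj(graph) -> dict:
    """networkx graph -> plain adjacency-dict used by the oracles."""
    return {v: set(graph.neighbors(v)) for v in graph.nodes}


def all_labelled_graphs(n: int):
    """Every labelled simple graph on nodes 0..n-1 as adjacency dicts."""
    pairs = list(itertools.combinations(range(n), 2))
    for bits in range(2 ** len(pairs)):
        adj = {v: set() for v in range(n)}
        for k, (a, b) in enumerate(pairs):
            if bits >> k & 1:
                adj[a].add(b)
                adj[b].add(a)
        yield adj


def is_connected(adj: dict) -> bool:
    if not adj:
        return False
    return len(bfs_distances(adj, next(iter(adj)))) == len(adj)
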