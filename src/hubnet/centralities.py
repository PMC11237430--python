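"""Nine node-centrality measures and the protein × feature matrix.

The measures characterize each protein's position in the interaction
graph: degree (number of interactors), betweenness (bridging between
clusters), local clustering (do a protein's partners interact among
themselves), eigenvector centrality (importance through all indirect
connections), PageRank (where recursively trickled signal accumulates),
harmonic centrality (closeness to the rest of the network), local
efficiency (connectivity of the neighborhood with the protein removed),
subgraph centrality (closed-walk / motif participation, short walks
weighted up), and average nearest-neighbor degree.

Conventions, fixed for reproducibility:

* betweenness and harmonic centrality are reported **unnormalized**;
* eigenvector centrality is computed per connected component with a unit
  Euclidean norm per component and a nonnegative sign;
* PageRank uses damping 0.85, dangling (degree-0) mass redistributed
  uniformly, convergence tolerance 1e-10, at most 1000 iterations;
* subgraph centrality is the diagonal of exp(A) via dense
  eigendecomposition (exact at this network scale);
* undefined values (eigenvector and average nearest-neighbor degree for
  degree-0 nodes) are set to 0 in the assembled matrix and flagged.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .ppi_network import PPINetwork

logger = logging.getLogger("hubnet")

#: fixed column order of the centrality matrix
FEATURES = (
    "degree",
    "betweenness",
    "local_clustering",
    "eigenvector",
    "pagerank",
    "harmonic",
    "local_efficiency",
    "subgraph",
    "avg_nn_degree",
)

PAGERANK_DAMPING = 0.85
PAGERANK_TOL = 1e-10
PAGERANK_MAX_ITER = 1000


def degree(network: PPINetwork) -> dict[str, int]:
    """Number of incident edges per protein."""
    return {v: int(d) for v, d in network.graph.degree()}


def betweenness(network: PPINetwork) -> dict[str, float]:
    """Unnormalized shortest-path betweenness.

    Sum over unordered node pairs (s, t) with s ≠ t ≠ v of the fraction
    of shortest s–t paths passing through v; pairs in different
    components contribute 0.
    """
    return dict(nx.betweenness_centrality(network.graph, normalized=False))


def local_clustering(network: PPINetwork) -> dict[str, float]:
    """Fraction of a node's neighbor pairs that are themselves linked.

    0 by convention for nodes of degree < 2.
    """
    return {v: float(c) for v, c in nx.clustering(network.graph).items()}


def eigenvector_centrality(network: PPINetwork) -> dict[str, float]:
    """Leading adjacency eigenvector, per connected component.

    Each component's subvector has unit Euclidean norm and nonnegative
    entries (Perron–Frobenius sign).  Computed by dense symmetric
    eigendecomposition, which is exact at this scale — there is no
    iterative convergence failure mode.  Singleton components get 1.0.
    """
    out: dict[str, float] = {}
    for comp in nx.connected_components(network.graph):
        members = sorted(comp)
        if len(members) == 1:
            out[members[0]] = 1.0
            continue
        a = nx.to_numpy_array(network.graph, nodelist=members)
        w, v = np.linalg.eigh(a)
        lead = v[:, -1]
        # fix sign so the Perron vector is nonnegative
        if lead.sum() < 0:
            lead = -lead
        lead = np.abs(lead) if (lead < -1e-12).any() else np.clip(lead, 0, None)
        lead = lead / np.linalg.norm(lead)
        out.update(zip(members, lead.tolist()))
    return out


def pagerank(network: PPINetwork, damping: float = PAGERANK_DAMPING) -> dict[str, float]:
    """Stationary PageRank distribution over proteins (sums to 1).

    Degree-0 (dangling) nodes redistribute their mass uniformly.
    Raises if the power iteration does not converge within
    ``PAGERANK_MAX_ITER`` iterations.
    """
    if not 0 < damping < 1:
        raise ValueError("damping must be in (0, 1)")
    try:
        pr = nx.pagerank(
            network.graph,
            alpha=damping,
            tol=PAGERANK_TOL,
            max_iter=PAGERANK_MAX_ITER,
        )
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(
            f"PageRank failed to converge within {PAGERANK_MAX_ITER} "
            f"iterations at tolerance {PAGERANK_TOL}"
        ) from exc
    return {v: float(x) for v, x in pr.items()}


def harmonic_centrality(network: PPINetwork) -> dict[str, float]:
    """Sum of inverse shortest-path distances to all other proteins.

    Unreachable pairs contribute 0 (1/∞); unnormalized.
    """
    return {
        v: float(h) for v, h in nx.harmonic_centrality(network.graph).items()
    }


def local_efficiency(network: PPINetwork) -> dict[str, float]:
    """Average inverse distance between a node's neighbors, node removed.

    Distances are taken in the subgraph induced on the neighbor set; a
    disconnected neighbor pair contributes 0.  Nodes of degree < 2 get 0.
    """
    g = network.graph
    out: dict[str, float] = {}
    for v in g:
        nbrs = list(g.neighbors(v))
        if len(nbrs) < 2:
            out[v] = 0.0
        else:
            out[v] = float(nx.global_efficiency(g.subgraph(nbrs)))
    return out


def subgraph_centrality(network: PPINetwork) -> dict[str, float]:
    """Diagonal of the adjacency matrix exponential, exp(A)_vv.

    Counts closed walks from each node to itself, a walk of length L
    weighted by 1/L!; isolated nodes score exactly 1 (the empty walk).
    """
    nodes = sorted(network.graph.nodes)
    if not nodes:
        return {}
    a = nx.to_numpy_array(network.graph, nodelist=nodes)
    w, v = np.linalg.eigh(a)
    sc = (v**2) @ np.exp(w)
    return dict(zip(nodes, sc.tolist()))


def avg_nearest_neighbor_degree(network: PPINetwork) -> dict[str, float]:
    """Mean degree over a node's neighbors; 0 (flagged policy) if isolated."""
    g = network.graph
    out: dict[str, float] = {}
    for v in g:
        nbrs = list(g.neighbors(v))
        out[v] = float(np.mean([g.degree[u] for u in nbrs])) if nbrs else 0.0
    return out


def centrality_matrix(network: PPINetwork) -> pd.DataFrame:
    """Assemble the proteins × 9 centrality feature matrix.

    Rows are sorted by protein identifier; columns follow the fixed
    ``FEATURES`` order.  The undefined-value policy zeroes eigenvector and
    average nearest-neighbor degree for degree-0 proteins, so the matrix
    never contains missing values; the affected proteins are recorded in
    ``df.attrs["undefined_zeroed"]``.
    """
    if network.n_nodes == 0:
        raise ValueError("network is empty")
    cols = {
        "degree": degree(network),
        "betweenness": betweenness(network),
        "local_clustering": local_clustering(network),
        "eigenvector": eigenvector_centrality(network),
        "pagerank": pagerank(network),
        "harmonic": harmonic_centrality(network),
        "local_efficiency": local_efficiency(network),
        "subgraph": subgraph_centrality(network),
        "avg_nn_degree": avg_nearest_neighbor_degree(network),
    }
    nodes = sorted(network.graph.nodes)
    df = pd.DataFrame(
        {name: [cols[name][v] for v in nodes] for name in FEATURES},
        index=pd.Index(nodes, name="protein"),
        dtype=float,
    )
    isolated = [v for v in nodes if cols["degree"][v] == 0]
    if isolated:
        df.loc[isolated, "eigenvector"] = 0.0
        df.loc[isolated, "avg_nn_degree"] = 0.0
        logger.info(
            "undefined-value policy: zeroed eigenvector/avg_nn_degree for "
            "%d degree-0 proteins", len(isolated),
        )
    df.attrs["undefined_zeroed"] = isolated
    return df
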