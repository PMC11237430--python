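"""Protein–protein interaction (PPI) network construction and queries.

The network is built from bacterial two-hybrid (B2H) style interaction
records: each record names a protein pair, whether the pair was assayed
(``tested``) and whether the assay reported an interaction (``positive``).
Positive pairs become undirected edges of a simple graph whose nodes are
all annotated proteins, including proteins with no detected interaction
(degree 0).  Untested pairs are treated as non-edges; the fraction of
possible pairs actually assayed is reported as ``coverage`` so that the
incompleteness of the screen stays visible downstream.

Each protein carries exactly one domain-class annotation:

``DGC``
    GGDEF-domain diguanylate cyclase (c-di-GMP synthesis).
``PDE``
    EAL/HD-GYP-domain phosphodiesterase (c-di-GMP degradation).
``DUAL``
    Protein carrying both synthesis- and degradation-associated domains.
``PILZ``
    PilZ-domain c-di-GMP receptor.
``OTHER``
    Anything else (assigned when an identifier has no annotation and the
    caller opts into that behaviour).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger("hubnet")

DOMAIN_CLASSES = ("DGC", "PDE", "DUAL", "PILZ", "OTHER")


@dataclass(frozen=True)
class InteractionRecord:
    """One assayed protein pair from a B2H-style screen."""

    protein_a: str
    protein_b: str
    tested: bool = True
    positive: bool = False

    def __post_init__(self) -> None:
        if self.positive and not self.tested:
            raise ValueError(
                f"record ({self.protein_a}, {self.protein_b}): "
                "positive implies tested"
            )

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered pair key (lexicographically sorted)."""
        a, b = sorted((self.protein_a, self.protein_b))
        return (a, b)


@dataclass
class PPINetwork:
    """Simple undirected protein interaction graph with domain annotations.

    Wraps a :class:`networkx.Graph` whose nodes carry a ``domain_class``
    attribute.  ``coverage`` is the fraction of the C(n, 2) possible pairs
    that were assayed (NaN when n < 2).
    """

    graph: nx.Graph
    coverage: float = float("nan")

    # -- basic queries -------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, protein: str) -> int:
        return int(self.graph.degree[protein])

    def domain_class(self, protein: str) -> str:
        return str(self.graph.nodes[protein]["domain_class"])

    def proteins_of_class(self, domain_class: str) -> list[str]:
        return sorted(
            n
            for n, d in self.graph.nodes(data="domain_class")
            if d == domain_class
        )

    def annotations(self) -> dict[str, str]:
        return {n: d for n, d in self.graph.nodes(data="domain_class")}


def load_interactions(
    records: Sequence[InteractionRecord],
    annotations: Mapping[str, str],
    *,
    assign_other: bool = False,
) -> PPINetwork:
    """Build the annotated PPI network from interaction records.

    All annotated proteins become nodes (degree-0 proteins included); each
    distinct positive non-self pair becomes one edge.  Self-pairs
    (homodimer signals) are dropped with a warning because every
    downstream centrality is defined on a simple graph.

    Parameters
    ----------
    records
        Assayed pairs.  The same pair may appear more than once, but
        conflicting ``positive`` flags for a tested pair raise ``ValueError``.
    annotations
        ``protein -> domain class`` mapping; classes must be one of
        ``DGC, PDE, DUAL, PILZ, OTHER``.
    assign_other
        When True, identifiers present in records but absent from
        ``annotations`` are admitted with class ``OTHER``; otherwise they
        raise ``KeyError``.
    """
    ann = dict(annotations)
    for protein, cls in ann.items():
        if cls not in DOMAIN_CLASSES:
            raise ValueError(f"unknown domain class {cls!r} for {protein!r}")

    seen: dict[tuple[str, str], bool] = {}
    tested_pairs: set[tuple[str, str]] = set()
    edges: set[tuple[str, str]] = set()
    n_self_dropped = 0
    for rec in records:
        for p in (rec.protein_a, rec.protein_b):
            if p not in ann:
                if assign_other:
                    ann[p] = "OTHER"
                    logger.warning("protein %s unannotated; assigned OTHER", p)
                else:
                    raise KeyError(f"protein {p!r} has no domain annotation")
        if rec.protein_a == rec.protein_b:
            if rec.positive:
                n_self_dropped += 1
                logger.warning(
                    "self-pair (%s, %s) dropped: simple graph has no "
                    "self-loops", rec.protein_a, rec.protein_b,
                )
            continue
        pair = rec.pair
        if rec.tested:
            if pair in seen and seen[pair] != rec.positive:
                raise ValueError(
                    f"conflicting records for pair {pair}: both positive "
                    "and negative flags present"
                )
            seen[pair] = rec.positive
            tested_pairs.add(pair)
        if rec.positive:
            edges.add(pair)

    g = nx.Graph()
    g.add_nodes_from(sorted(ann))
    nx.set_node_attributes(g, ann, "domain_class")
    g.add_edges_from(edges)

    n = g.number_of_nodes()
    coverage = len(tested_pairs) / math.comb(n, 2) if n >= 2 else float("nan")
    if n_self_dropped:
        logger.info("dropped %d positive self-pairs", n_self_dropped)
    return PPINetwork(graph=g, coverage=coverage)


def largest_connected_component(network: PPINetwork) -> PPINetwork:
    """Subnetwork induced on a maximum-cardinality connected component.

    Ties between equally large components are broken in favour of the one
    containing the lexicographically smallest protein identifier, so the
    result is deterministic.
    """
    if network.n_nodes == 0:
        raise ValueError("network is empty")
    components = [set(c) for c in nx.connected_components(network.graph)]
    best = min(components, key=lambda c: (-len(c), min(c)))
    sub = network.graph.subgraph(best).copy()
    return PPINetwork(graph=sub, coverage=network.coverage)


def hub_induced_subgraph(network: PPINetwork, k: int) -> PPINetwork:
    """Subgraph on the k highest-degree dual-domain hubs and adjacent DGCs.

    Selects the ``k`` highest-degree DUAL-class proteins (degree ties
    broken by identifier order), then adds every DGC-class protein
    adjacent to at least one of them, and returns the induced subgraph —
    the hub-and-spokes view of the signaling core.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    duals = network.proteins_of_class("DUAL")
    if not duals:
        raise ValueError("network has no DUAL-class proteins")
    if len(duals) < k:
        logger.warning(
            "only %d DUAL proteins available (k=%d); using all", len(duals), k
        )
        k = len(duals)
    ranked = sorted(duals, key=lambda p: (-network.degree(p), p))
    hubs = ranked[:k]
    dgcs = {
        nbr
        for h in hubs
        for nbr in network.graph.neighbors(h)
        if network.domain_class(nbr) == "DGC"
    }
    keep = set(hubs) | dgcs
    sub = network.graph.subgraph(keep).copy()
    return PPINetwork(graph=sub, coverage=network.coverage)
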