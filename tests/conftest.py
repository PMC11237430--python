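"""Shared fixtures: tiny named graphs and generator bundles."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hubnet import PPINetwork, SyntheticConfig
from hubnet.phenotype import BiofilmMatrix


def make_network(edges, nodes=None, classes=None) -> PPINetwork:
    """Build an annotated PPINetwork from an edge list (default class OTHER)."""
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    ann = {v: "OTHER" for v in g.nodes}
    if classes:
        ann.update(classes)
    nx.set_node_attributes(g, ann, "domain_class")
    return PPINetwork(graph=g, coverage=1.0)


@pytest.fixture
def triangle() -> PPINetwork:
    return make_network([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3() -> PPINetwork:
    return make_network([("a", "b"), ("b", "c")])


@pytest.fixture
def paw() -> PPINetwork:
    """Triangle x-y-z with a pendant p attached to x."""
    return make_network([("x", "y"), ("y", "z"), ("x", "z"), ("x", "p")])


@pytest.fixture
def default_bundle():
    """One default-config synthetic bundle, generated once per session."""
    import hubnet

    return hubnet.generate_all(SyntheticConfig(seed=11))


def make_biofilm(values: pd.DataFrame, batches=None, wt_row="WT",
                 detergent=None) -> BiofilmMatrix:
    """Wrap a plain values frame (WT row included) into a BiofilmMatrix."""
    envs = list(values.columns)
    batch = pd.Series(batches or {e: "b1" for e in envs})
    det = pd.Series(detergent or {e: False for e in envs})
    return BiofilmMatrix(
        values=values,
        batch=batch,
        wt=values.loc[wt_row].astype(float),
        detergent=det,
        strain_meta={s: s for s in values.index if s != wt_row},
        wt_strain=wt_row,
    )
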