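"""Gene-expression z-scoring and the interactor-coexpression test.

Expression of the genes coding for the signaling proteins is measured
across growth conditions.  Two questions are asked of it: is there any
appreciable per-gene variation at all (after excluding known outliers
such as *rapA*, whose strong phosphate response would dominate), and do
genes whose protein products physically interact show coordinated
expression?

The second question is answered with a permutation test: the statistic
is the mean absolute Pearson correlation of z-scored profiles over
interacting pairs minus the same over non-interacting pairs, and the
null is generated by shuffling the protein labels on the network (which
reassigns which pairs count as "interacting" while keeping both the
expression data and the graph topology fixed).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ppi_network import PPINetwork

logger = logging.getLogger("hubnet")


@dataclass
class ExpressionMatrix:
    """Genes × conditions expression values, optionally with z-scores."""

    values: pd.DataFrame
    zscores: pd.DataFrame | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


def zscore(matrix: ExpressionMatrix, exclude: list[str] | None = None) -> ExpressionMatrix:
    """Drop excluded genes, then z-score each remaining gene's profile.

    Exclusion happens before any cross-gene summary so an outlier never
    influences the rest.  Constant rows become all-zero and are listed
    in ``result.zscores.attrs["constant_rows"]``.  Unknown gene ids in
    ``exclude`` raise ``KeyError``.
    """
    exclude = list(exclude or [])
    unknown = [g for g in exclude if g not in matrix.values.index]
    if unknown:
        raise KeyError(f"unknown gene id(s) in exclude list: {unknown}")
    vals = matrix.values.drop(index=exclude)
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    constant = sd.index[sd == 0].tolist()
    z = vals.sub(mu, axis=0).div(sd.replace(0.0, 1.0), axis=0)
    z.loc[constant] = 0.0
    if constant:
        logger.info("constant expression rows zeroed: %s", constant)
    z.attrs["constant_rows"] = constant
    return ExpressionMatrix(values=vals, zscores=z)


@dataclass
class CoexpressionTest:
    """Permutation test of coordinated expression among interactors."""

    statistic: float           # mean|r| interacting − mean|r| non-interacting
    p_value: float             # add-one convention, in (0, 1]
    null: np.ndarray = field(repr=False)
    n_perm: int = 0
    n_interacting_pairs: int = 0
    n_noninteracting_pairs: int = 0
    n_dropped_pairs: int = 0   # pairs with an undefined (constant) profile


def interactor_coexpression(
    expr: ExpressionMatrix,
    network: PPINetwork,
    n_perm: int = 999,
    seed: int | None = 0,
) -> CoexpressionTest:
    """Test whether interacting proteins' genes are coexpressed.

    Pearson correlations are computed once between all z-scored gene
    profiles; each permutation relabels the proteins on the graph, so
    the null re-partitions the same correlation matrix into
    "interacting" and "non-interacting" pairs.  Pairs involving a
    constant profile have undefined correlation and are dropped (and
    counted).  Requires ≥ 5 interacting pairs with expression data.
    """
    z = expr.zscores if expr.zscores is not None else zscore(expr).zscores
    genes = [g for g in network.nodes if g in z.index]
    if len(genes) < 3:
        raise ValueError("fewer than 3 network proteins have expression data")
    zv = z.loc[genes].values
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    # correlation matrix with NaN for constant rows
    sd = zv.std(axis=1, ddof=1)
    defined = sd > 0
    corr = np.full((n, n), np.nan)
    if defined.sum() >= 2:
        sub = np.corrcoef(zv[defined])
        ix = np.flatnonzero(defined)
        corr[np.ix_(ix, ix)] = sub
    abs_corr = np.abs(corr)

    edge_idx = np.array(
        [
            (gene_pos[a], gene_pos[b])
            for a, b in network.edges
            if a in gene_pos and b in gene_pos
        ],
        dtype=int,
    ).reshape(-1, 2)
    if edge_idx.shape[0] < 5:
        raise ValueError(
            f"only {edge_idx.shape[0]} interacting pairs have expression "
            "data; need at least 5"
        )
    edge_set = {tuple(sorted(e)) for e in edge_idx.tolist()}
    all_pairs = list(itertools.combinations(range(n), 2))
    is_edge = np.array([p in edge_set for p in all_pairs])
    pair_r = np.array([abs_corr[i, j] for i, j in all_pairs])

    def statistic(edge_mask: np.ndarray) -> tuple[float, int]:
        ok = ~np.isnan(pair_r)
        dropped = int((~ok).sum())
        r_in = pair_r[edge_mask & ok]
        r_out = pair_r[~edge_mask & ok]
        if r_in.size == 0 or r_out.size == 0:
            return 0.0, dropped
        return float(r_in.mean() - r_out.mean()), dropped

    obs, n_dropped = statistic(is_edge)
    if np.isnan(pair_r).all():
        logger.warning(
            "all pairwise correlations undefined (identical profiles); "
            "statistic is 0 by convention"
        )

    rng = np.random.default_rng(seed)
    pair_index = {p: k for k, p in enumerate(all_pairs)}
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        mask = np.zeros(len(all_pairs), dtype=bool)
        for i, j in edge_idx:
            pi, pj = perm[i], perm[j]
            key = (pi, pj) if pi < pj else (pj, pi)
            mask[pair_index[key]] = True
        null[b], _ = statistic(mask)
    p = (1 + int((null >= obs).sum())) / (n_perm + 1)
    return CoexpressionTest(
        statistic=obs,
        p_value=p,
        null=null,
        n_perm=n_perm,
        n_interacting_pairs=int(is_edge.sum()),
        n_noninteracting_pairs=int((~is_edge).sum()),
        n_dropped_pairs=n_dropped,
    )
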