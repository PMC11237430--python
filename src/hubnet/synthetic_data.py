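"""Synthetic data emulating the three study modalities.

The generator produces, from one seed:

1. a ~50-protein interaction network whose degree distribution is
   planted in class-specific bands — dual-domain hubs at degree 17–29
   (the LapD-like top of the distribution), low-degree dual-domain
   satellites at 1–6, DGCs at 8–16, PDEs at 0–4 and PilZ receptors at
   0–1 — realized exactly by Havel–Hakimi construction plus
   degree-preserving edge swaps;
2. a strain × environment biofilm biomass matrix (49 deletion strains
   plus wild type, 188 environments in batches) with additive strain
   and environment effects, a centrality-driven contribution of the
   deleted protein, eight constitutively hyper-biofilm PDE-deletion
   strains, detergent environments with growth suppressed, batch
   multipliers, and a floor at zero (assay physics);
3. a low-variance gene × condition expression matrix with one planted
   high-variance outlier gene and, optionally, a latent condition
   factor shared by the genes of interacting proteins.

Every generator is a pure function of its config and seed, and returns
a ground-truth record sufficient to score recovery in the analysis
modules without re-deriving anything.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import centralities as ce
from .expression import ExpressionMatrix
from .phenotype import BiofilmMatrix
from .ppi_network import InteractionRecord, PPINetwork

logger = logging.getLogger("hubnet")

#: default network-effect coefficients for the biofilm generator, in the
#: raw centrality scales (eigenvector, betweenness, PageRank, dual
#: indicator).  The relative magnitudes follow the fitted phenotype
#: model; the overall scale is set so the network term contributes a
#: per-strain SD of ~0.03 biomass units, i.e. the modest incremental
#: explanatory power (ΔR² ≈ 0.06) the analysis attributes to the PPI
#: features, while leaving the strain/environment variance decomposition
#: at its planted levels.
DEFAULT_PPI_COEFFICIENTS = {
    "eigenvector": -0.101,
    "betweenness": -0.00064,
    "pagerank": 2.31,
    "dual_indicator": 0.054,
}

DEFAULT_DEGREE_BANDS = {
    "DUAL_HUB": (17, 29),
    "DUAL_SAT": (1, 6),
    "DGC": (8, 16),
    "PDE": (0, 4),
    "PILZ": (0, 1),
}


@dataclass
class SyntheticConfig:
    """All knobs of the three-modality generator, with study-scale defaults."""

    # network
    n_dual_hubs: int = 8
    n_dual_satellites: int = 7
    n_dgc: int = 15
    n_pde: int = 12
    n_pilz: int = 8
    degree_bands: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_DEGREE_BANDS)
    )
    tested_fraction: float = 0.9
    # biofilm matrix
    n_strains: int = 49
    n_environments: int = 188
    n_batches: int = 4
    baseline_biomass: float = 1.0
    strain_effect_sd: float = 0.09
    env_effect_sd: float = 0.07
    noise_sd: float = 0.03
    batch_multipliers: tuple[float, ...] = (1.0, 1.15, 0.9, 1.05)
    n_hyper_strains: int = 8
    hyper_effect: float = 0.27  # 3 × strain_effect_sd
    n_detergent_envs: int = 6
    detergent_level: float = 0.02
    ppi_effect_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PPI_COEFFICIENTS)
    )
    # expression matrix
    n_conditions: int = 45
    expr_base_sd: float = 0.1
    outlier_gene_sd: float = 1.0
    coexpression_loading: float = 0.0
    seed: int = 0

    @property
    def n_proteins(self) -> int:
        return (
            self.n_dual_hubs + self.n_dual_satellites + self.n_dgc
            + self.n_pde + self.n_pilz
        )

    def class_counts(self) -> dict[str, int]:
        return {
            "DUAL_HUB": self.n_dual_hubs,
            "DUAL_SAT": self.n_dual_satellites,
            "DGC": self.n_dgc,
            "PDE": self.n_pde,
            "PILZ": self.n_pilz,
        }

    def validate(self) -> None:
        for band, (lo, hi) in self.degree_bands.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"degree band {band} = ({lo}, {hi}) is invalid")
            if hi >= self.n_proteins:
                raise ValueError(
                    f"degree band {band} max {hi} >= n_proteins {self.n_proteins}"
                )
        if self.n_strains > self.n_proteins:
            raise ValueError("n_strains exceeds the number of proteins")
        if len(self.batch_multipliers) < self.n_batches:
            raise ValueError("need one batch multiplier per batch")


#: generator band labels -> domain classes used by the analysis
_BAND_TO_CLASS = {
    "DUAL_HUB": "DUAL",
    "DUAL_SAT": "DUAL",
    "DGC": "DGC",
    "PDE": "PDE",
    "PILZ": "PILZ",
}

_BAND_PREFIX = {
    "DUAL_HUB": "DH",
    "DUAL_SAT": "DS",
    "DGC": "GC",
    "PDE": "PD",
    "PILZ": "PZ",
}


@dataclass
class NetworkTruth:
    """Ground truth of one generated network."""

    band: dict[str, str]              # protein -> generator band label
    domain_class: dict[str, str]      # protein -> DGC/PDE/DUAL/PILZ
    target_degree: dict[str, int]
    realized_degree: dict[str, int]
    degree_deviations: dict[str, int]  # protein -> realized - target (nonzero only)
    edges: list[tuple[str, str]]


def _nearest_graphical(degrees: list[int]) -> tuple[list[int], int]:
    """Repair a degree sequence to the nearest graphical one.

    Makes the sum even and then decrements the largest degree until the
    Erdős–Gallai condition holds; returns the repaired sequence and the
    number of unit decrements applied.
    """
    seq = list(degrees)
    n_dev = 0
    if sum(seq) % 2 == 1:
        i = int(np.argmax(seq))
        seq[i] -= 1
        n_dev += 1
    while not nx.is_graphical(seq):
        # shave the two largest degrees by one each, keeping the sum even
        order = np.argsort(seq)
        i, j = int(order[-1]), int(order[-2])
        if seq[i] == 0 or seq[j] == 0:
            raise ValueError("could not repair degree sequence")
        seq[i] -= 1
        seq[j] -= 1
        n_dev += 2
    return seq, n_dev


def generate_network(config: SyntheticConfig, seed: int | None = None):
    """Generate the planted-degree-band PPI network.

    Target degrees are drawn uniformly per class from its band; the
    graph is realized by Havel–Hakimi construction followed by
    10·|E| random degree-preserving double-edge swaps.  Realized degrees
    equal the targets exactly whenever the drawn sequence is graphical;
    otherwise the nearest graphical sequence is used and the deviations
    are recorded in the truth record.

    Returns ``(PPINetwork, NetworkTruth)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    proteins: list[str] = []
    band_of: dict[str, str] = {}
    targets: dict[str, int] = {}
    for band, count in config.class_counts().items():
        lo, hi = config.degree_bands[band]
        for i in range(count):
            name = f"{_BAND_PREFIX[band]}{i + 1:02d}"
            proteins.append(name)
            band_of[name] = band
            targets[name] = int(rng.integers(lo, hi + 1))

    raw_seq = [targets[p] for p in proteins]
    seq, n_dev = _nearest_graphical(raw_seq)
    if n_dev:
        logger.info("degree sequence repaired with %d unit deviations", n_dev)

    if sum(seq) == 0:
        g = nx.empty_graph(len(proteins))
    else:
        g = nx.havel_hakimi_graph(seq)
        n_edges = g.number_of_edges()
        if n_edges >= 2 and g.number_of_nodes() >= 4:
            before = sorted(d for _, d in g.degree())
            nswap = 10 * n_edges
            nx.double_edge_swap(
                g, nswap=nswap, max_tries=200 * nswap,
                seed=int(rng.integers(2**31 - 1)),
            )
            assert sorted(d for _, d in g.degree()) == before, \
                "edge swaps changed the degree sequence"

    # match generated integer nodes to proteins by degree (both sorted)
    nodes_by_deg = sorted(g.nodes, key=lambda v: (-g.degree[v], v))
    prots_by_deg = sorted(proteins, key=lambda p: (-targets[p], p))
    name_of = dict(zip(nodes_by_deg, prots_by_deg))
    h = nx.relabel_nodes(g, name_of)
    h.add_nodes_from(proteins)  # keep any degree-0 proteins

    annotations = {p: _BAND_TO_CLASS[band_of[p]] for p in proteins}
    nx.set_node_attributes(h, annotations, "domain_class")

    realized = {p: int(h.degree[p]) for p in proteins}
    deviations = {
        p: realized[p] - targets[p]
        for p in proteins
        if realized[p] != targets[p]
    }
    if deviations:
        logger.info("degree deviations after repair: %s", deviations)

    network = PPINetwork(graph=h, coverage=config.tested_fraction)
    truth = NetworkTruth(
        band=band_of,
        domain_class=annotations,
        target_degree=targets,
        realized_degree=realized,
        degree_deviations=deviations,
        edges=[tuple(sorted(e)) for e in h.edges],
    )
    return network, truth


def interaction_records(
    network: PPINetwork, config: SyntheticConfig, seed: int | None = None
) -> list[InteractionRecord]:
    """Emit B2H-style records for the generated network.

    All edges become positive tested records; the untested fraction
    (1 − ``tested_fraction``) is sampled from the negative pairs, so no
    positive pair is ever marked untested.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    nodes = sorted(network.nodes)
    edges = {tuple(sorted(e)) for e in network.edges}
    all_pairs = list(itertools.combinations(nodes, 2))
    negatives = [p for p in all_pairs if p not in edges]
    n_untested = round((1 - config.tested_fraction) * len(all_pairs))
    n_untested = min(n_untested, len(negatives))
    untested = set(
        map(tuple, rng.choice(negatives, size=n_untested, replace=False))
    ) if n_untested else set()
    records = []
    for a, b in all_pairs:
        if (a, b) in edges:
            records.append(InteractionRecord(a, b, tested=True, positive=True))
        elif (a, b) in untested:
            records.append(InteractionRecord(a, b, tested=False, positive=False))
        else:
            records.append(InteractionRecord(a, b, tested=True, positive=False))
    return records


@dataclass
class BiofilmTruth:
    """Ground truth of one generated biomass matrix."""

    strain_effects: dict[str, float]
    env_effects: dict[str, float]
    ppi_terms: dict[str, float]
    hyper_strains: list[str]
    detergent_envs: list[str]
    batch_of_env: dict[str, str]
    batch_multipliers: dict[str, float]
    coefficients: dict[str, float]


def generate_biofilm(
    config: SyntheticConfig,
    network: PPINetwork,
    truth: NetworkTruth,
    seed: int | None = None,
):
    """Generate the strain × environment biomass matrix.

    biomass(s, e) = m(batch(e)) · max(0, μ + strain(s) + env(e) +
    ppi(s) + hyper(s) + noise), with the wild-type row generated with
    zero strain and network terms, detergent environments forced near
    zero, and the centrality-driven ppi term computed from the deleted
    protein's features in the full generated network.

    Returns ``(BiofilmMatrix, BiofilmTruth)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    proteins = sorted(network.nodes)
    strains = sorted(
        map(str, rng.choice(proteins, size=config.n_strains, replace=False))
    )
    envs = [f"env{j + 1:03d}" for j in range(config.n_environments)]
    batches = [f"batch{j * config.n_batches // config.n_environments + 1}"
               for j in range(config.n_environments)]
    batch_of = dict(zip(envs, batches))
    mult_of = {
        f"batch{i + 1}": float(config.batch_multipliers[i])
        for i in range(config.n_batches)
    }
    detergent = sorted(
        map(str, rng.choice(envs, size=config.n_detergent_envs, replace=False))
    ) if config.n_detergent_envs else []
    det_set = set(detergent)

    pde_strains = [s for s in strains if truth.domain_class[s] == "PDE"]
    if len(pde_strains) < config.n_hyper_strains:
        raise ValueError(
            f"only {len(pde_strains)} PDE-deletion strains available for "
            f"{config.n_hyper_strains} hyper-biofilm strains"
        )
    hyper = sorted(map(str, rng.choice(
        pde_strains, size=config.n_hyper_strains, replace=False
    )))
    hyper_set = set(hyper)

    cmat = ce.centrality_matrix(network)
    coef = config.ppi_effect_coefficients
    ppi_term = {
        s: coef.get("eigenvector", 0.0) * cmat.at[s, "eigenvector"]
        + coef.get("betweenness", 0.0) * cmat.at[s, "betweenness"]
        + coef.get("pagerank", 0.0) * cmat.at[s, "pagerank"]
        + coef.get("dual_indicator", 0.0)
        * (1.0 if truth.domain_class[s] == "DUAL" else 0.0)
        for s in strains
    }
    # center the network term so it shifts strains relative to each
    # other, not the overall biomass level
    ppi_mean = float(np.mean(list(ppi_term.values())))
    ppi_term = {s: v - ppi_mean for s, v in ppi_term.items()}

    strain_eff = {
        s: float(rng.normal(0, config.strain_effect_sd)) for s in strains
    }
    env_eff = {e: float(rng.normal(0, config.env_effect_sd)) for e in envs}

    mu = config.baseline_biomass
    rows = ["WT"] + strains
    values = np.empty((len(rows), len(envs)))
    for i, s in enumerate(rows):
        for j, e in enumerate(envs):
            if e in det_set:
                inner = max(0.0, rng.normal(config.detergent_level,
                                            config.noise_sd / 3))
            else:
                inner = mu + env_eff[e] + rng.normal(0, config.noise_sd)
                if s != "WT":
                    inner += strain_eff[s] + ppi_term[s]
                    if s in hyper_set:
                        inner += config.hyper_effect
                inner = max(0.0, inner)
            values[i, j] = mult_of[batch_of[e]] * inner

    df = pd.DataFrame(values, index=rows, columns=envs)
    matrix = BiofilmMatrix(
        values=df,
        batch=pd.Series(batch_of),
        wt=df.loc["WT"].copy(),
        detergent=pd.Series({e: e in det_set for e in envs}),
        strain_meta={s: s for s in strains},
        wt_strain="WT",
    )
    bio_truth = BiofilmTruth(
        strain_effects=strain_eff,
        env_effects=env_eff,
        ppi_terms=ppi_term,
        hyper_strains=hyper,
        detergent_envs=detergent,
        batch_of_env=batch_of,
        batch_multipliers=mult_of,
        coefficients=dict(coef),
    )
    return matrix, bio_truth


@dataclass
class ExpressionTruth:
    """Ground truth of one generated expression matrix."""

    outlier_gene: str
    coexpression_loading: float
    gene_means: dict[str, float]


def generate_expression(
    config: SyntheticConfig,
    network: PPINetwork,
    seed: int | None = None,
):
    """Generate the gene × condition expression matrix.

    One gene per network protein; per-gene profiles are Gaussian with a
    small SD, one designated outlier gene (the first PDE, playing the
    rapA role) gets ``outlier_gene_sd``, and a positive
    ``coexpression_loading`` mixes a shared latent condition factor into
    the profiles of all non-isolated proteins' genes, making interacting
    pairs coexpressed.

    Returns ``(ExpressionMatrix, ExpressionTruth)``.
    """
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    genes = sorted(network.nodes)
    pdes = [g for g in genes if network.domain_class(g) == "PDE"]
    outlier = pdes[0] if pdes else genes[0]
    conditions = [f"cond{j + 1:02d}" for j in range(config.n_conditions)]
    lam = config.coexpression_loading
    latent = rng.standard_normal(config.n_conditions)
    means = {g: float(rng.normal(8.0, 1.0)) for g in genes}

    values = np.empty((len(genes), config.n_conditions))
    for i, g in enumerate(genes):
        sd = config.outlier_gene_sd if g == outlier else config.expr_base_sd
        noise = rng.standard_normal(config.n_conditions)
        if lam > 0 and network.degree(g) > 0:
            profile = np.sqrt(1 - lam**2) * noise + lam * latent
        else:
            profile = noise
        values[i] = means[g] + sd * profile

    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=conditions)
    )
    truth = ExpressionTruth(
        outlier_gene=outlier,
        coexpression_loading=lam,
        gene_means=means,
    )
    return expr, truth


def generate_all(config: SyntheticConfig):
    """Generate the full three-modality bundle from one config."""
    network, net_truth = generate_network(config)
    biofilm, bio_truth = generate_biofilm(config, network, net_truth)
    expr, expr_truth = generate_expression(config, network)
    return {
        "network": network,
        "network_truth": net_truth,
        "biofilm": biofilm,
        "biofilm_truth": bio_truth,
        "expression": expr,
        "expression_truth": expr_truth,
    }
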