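"""Biofilm biomass matrix: normalization, filtering, clustering, variability.

The phenotype data are crystal-violet biofilm biomass readings for a
panel of deletion strains (one c-di-GMP protein removed per strain) plus
the wild type, grown across many carbon-source environments assayed in
batches.  The processing order mirrors the analysis:

1. batch-normalize every reading by the mean wild-type biomass of its
   environment's batch (ratio scale; a subtraction mode is available);
2. remove constitutively hyper-biofilm strains (PDE deletions that are
   "on" everywhere, so they carry no environmental information) and
   detergent-containing environments (growth inhibited, readings near 0);
3. summarize variability along both axes and hierarchically cluster
   strains and environments.

Strains are rows and environments are columns throughout; any display
transposition is a plotting concern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger("hubnet")

#: wt batch means this close to 1 are taken as evidence of prior normalization
_ALREADY_NORMALIZED_RTOL = 0.02


@dataclass
class BiofilmMatrix:
    """Strain × environment biomass readings with assay metadata.

    ``values`` holds one row per strain (the wild-type reference row
    included, labelled ``wt_strain``) and one column per environment.
    ``batch`` maps each environment to its assay batch, ``wt`` gives the
    wild-type biomass per environment, ``detergent`` flags environments
    whose medium contained growth-inhibiting detergents, and
    ``strain_meta`` maps each mutant strain to the protein its deletion
    removes from the network.
    """

    values: pd.DataFrame
    batch: pd.Series
    wt: pd.Series
    detergent: pd.Series
    strain_meta: dict[str, str] = field(default_factory=dict)
    wt_strain: str = "WT"
    normalized: bool = False
    removed_strains: list[str] = field(default_factory=list)
    removed_environments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        envs = self.values.columns
        for name, series in (("batch", self.batch), ("wt", self.wt),
                             ("detergent", self.detergent)):
            missing = envs.difference(series.index)
            if len(missing):
                raise ValueError(
                    f"{name} metadata missing for environments: "
                    f"{sorted(missing)[:5]}..."
                )

    @property
    def strains(self) -> list[str]:
        return list(self.values.index)

    @property
    def environments(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mutant_values(self) -> pd.DataFrame:
        """Rows for mutant strains only (wild-type reference excluded)."""
        return self.values.drop(index=self.wt_strain, errors="ignore")


def batch_normalize(raw: BiofilmMatrix, mode: str = "divide") -> BiofilmMatrix:
    """Normalize each reading by the wild-type biomass of its batch.

    ``divide`` (default): value / mean WT biomass of the environment's
    batch, so wild-type entries average ≈ 1 within every batch.
    ``subtract``: value − batch WT mean, centering the wild type near 0.
    Negative raw readings (blank over-subtraction) are floored at 0
    first, with a count logged.

    Raises if a batch's WT mean is ≤ 0, or if every batch WT mean is
    already ≈ 1 — the signature of input that was normalized once
    already, which a silent second division would corrupt.
    """
    if mode not in ("divide", "subtract"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    values = raw.values.copy()
    n_neg = int((values.values < 0).sum())
    if n_neg:
        logger.info("floored %d negative raw readings at 0", n_neg)
        values = values.clip(lower=0.0)
    wt = raw.wt.clip(lower=0.0)

    batch_of = raw.batch
    batch_means = wt.groupby(batch_of.loc[wt.index]).mean()
    bad = batch_means[batch_means <= 0]
    if len(bad):
        raise ValueError(
            f"batch {bad.index[0]!r} has non-positive wild-type mean "
            f"({bad.iloc[0]:.4g}); cannot normalize"
        )
    if raw.normalized or np.allclose(batch_means, 1.0, rtol=_ALREADY_NORMALIZED_RTOL):
        raise ValueError(
            "input already looks batch-normalized (every batch wild-type "
            "mean ≈ 1); refusing to normalize twice"
        )

    denom = batch_of.loc[values.columns].map(batch_means)
    if mode == "divide":
        norm_values = values.div(denom, axis=1)
        norm_wt = wt / batch_of.loc[wt.index].map(batch_means)
    else:
        norm_values = values.sub(denom, axis=1)
        norm_wt = wt - batch_of.loc[wt.index].map(batch_means)
    return replace(raw, values=norm_values, wt=norm_wt, normalized=True)


def apply_filters(
    matrix: BiofilmMatrix,
    hyper_strains: list[str] | None = None,
    detergent_envs: list[str] | None = None,
) -> BiofilmMatrix:
    """Drop listed strains and environments from the matrix.

    Identifiers already removed by a previous call are tolerated (the
    operation is idempotent for a fixed pair of lists); identifiers
    never present raise ``KeyError``.  Removing every environment is an
    error — the downstream summaries would be empty.
    """
    hyper_strains = list(hyper_strains or [])
    detergent_envs = list(detergent_envs or [])
    known_strains = set(matrix.values.index) | set(matrix.removed_strains)
    known_envs = set(matrix.values.columns) | set(matrix.removed_environments)
    for s in hyper_strains:
        if s not in known_strains:
            raise KeyError(f"unknown strain {s!r}")
    for e in detergent_envs:
        if e not in known_envs:
            raise KeyError(f"unknown environment {e!r}")

    drop_s = [s for s in hyper_strains if s in matrix.values.index]
    drop_e = [e for e in detergent_envs if e in matrix.values.columns]
    values = matrix.values.drop(index=drop_s, columns=drop_e)
    if values.shape[1] == 0:
        raise ValueError("no environments remain after filtering")
    logger.info(
        "filtered %d strains and %d environments (%d×%d -> %d×%d)",
        len(drop_s), len(drop_e), *matrix.values.shape, *values.shape,
    )
    return replace(
        matrix,
        values=values,
        wt=matrix.wt.drop(index=drop_e),
        batch=matrix.batch.drop(index=drop_e),
        detergent=matrix.detergent.drop(index=drop_e),
        removed_strains=sorted(set(matrix.removed_strains) | set(drop_s)),
        removed_environments=sorted(set(matrix.removed_environments) | set(drop_e)),
    )


def detect_hyper_strains(matrix: BiofilmMatrix, quantile: float = 0.75) -> list[str]:
    """Find strains that out-form biofilm almost everywhere.

    A mutant strain is called constitutively hyper-biofilm when its
    normalized biomass exceeds the given cross-strain quantile in at
    least 95% of environments — the operational reading of "robust
    biofilm formation in all growth conditions".  Deterministic given
    the matrix and quantile.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    vals = matrix.mutant_values
    thresholds = vals.quantile(quantile, axis=0)  # per environment
    exceed = vals.gt(thresholds, axis=1)
    frac = exceed.mean(axis=1)
    return sorted(frac.index[frac >= 0.95])


@dataclass
class VariabilitySummary:
    """Median and IQR of biomass SD along both axes of the matrix.

    ``across_strains`` summarizes, per environment, the sample SD over
    strains (how much strains differ from one another in that
    environment); ``across_environments`` summarizes, per strain, the SD
    over environments (how much that strain responds to the
    environment).  Comparable medians mean both the deleted gene and the
    growth environment shape the phenotype.
    """

    median_sd_across_strains: float
    iqr_sd_across_strains: tuple[float, float]
    median_sd_across_environments: float
    iqr_sd_across_environments: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "median_sd_across_strains": self.median_sd_across_strains,
            "iqr_sd_across_strains": list(self.iqr_sd_across_strains),
            "median_sd_across_environments": self.median_sd_across_environments,
            "iqr_sd_across_environments": list(self.iqr_sd_across_environments),
        }


def variability_summary(matrix: BiofilmMatrix) -> VariabilitySummary:
    """Decompose biomass variability into strain and environment axes.

    Uses mutant strains only (the wild-type reference row is the
    normalization anchor, not a phenotype of interest); sample SDs (n−1).
    """
    vals = matrix.mutant_values
    sd_across_strains = vals.std(axis=0, ddof=1)      # one per environment
    sd_across_envs = vals.std(axis=1, ddof=1)         # one per strain
    q_s = np.percentile(sd_across_strains, [25, 50, 75])
    q_e = np.percentile(sd_across_envs, [25, 50, 75])
    return VariabilitySummary(
        median_sd_across_strains=float(q_s[1]),
        iqr_sd_across_strains=(float(q_s[0]), float(q_s[2])),
        median_sd_across_environments=float(q_e[1]),
        iqr_sd_across_environments=(float(q_e[0]), float(q_e[2])),
    )


@dataclass
class ClusterResult:
    """Leaf orderings and linkage trees from two-way hierarchical clustering."""

    strain_order: list[str]
    environment_order: list[str]
    strain_linkage: np.ndarray
    environment_linkage: np.ndarray


def hierarchical_cluster(
    matrix: BiofilmMatrix,
    method: str = "average",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomeratively cluster strains and environments.

    Average linkage on Euclidean distance by default; deterministic
    given the matrix.  Needs at least two strains and two environments.
    """
    vals = matrix.values
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("clustering requires at least 2 rows and 2 columns")
    row_link = linkage(pdist(vals.values, metric=metric), method=method)
    col_link = linkage(pdist(vals.values.T, metric=metric), method=method)
    return ClusterResult(
        strain_order=[vals.index[i] for i in leaves_list(row_link)],
        environment_order=[vals.columns[i] for i in leaves_list(col_link)],
        strain_linkage=row_link,
        environment_linkage=col_link,
    )
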