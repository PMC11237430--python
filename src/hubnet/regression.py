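"""Phenotype regression: the biofilm linear model and its permutation nulls.

Each deletion strain removes exactly one protein from the interaction
network, so the network features of that protein can serve as strain
covariates.  The model predicts the normalized biofilm biomass of
(strain, environment) pairs from

* the wild-type biomass in that environment (the only environmental
  information in the model),
* the deleted protein's eigenvector, betweenness and PageRank
  centralities (raw scale, as the coefficient magnitudes require), and
* a dual-domain indicator.

Two permutation schemes guard against overfitting in the large design:
``all`` shuffles the response across all rows, destroying every
association; ``ppi_only`` shuffles which strain gets which protein's
centrality bundle (the bundle moves as a unit, wild-type and
environment structure untouched), isolating the network features'
contribution.  The statistic is the adjusted R² and p-values use the
add-one convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phenotype import BiofilmMatrix

logger = logging.getLogger("hubnet")

PPI_TERMS = ("eigenvector", "betweenness", "pagerank", "dual_indicator")
FULL_TERMS = ("wt",) + PPI_TERMS
DESIGN_COLUMNS = (
    "strain", "environment", "biofilm", "wt",
    "eigenvector", "betweenness", "pagerank", "dual_indicator",
)


@dataclass
class RegressionFit:
    """OLS fit summary: coefficients, p-values, (adjusted) R²."""

    coefficients: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    adj_r_squared: float
    n_obs: int
    std_errors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.adj_r_squared <= self.r_squared + 1e-12


@dataclass
class PermutationResult:
    """Observed adjusted R² against its permutation null."""

    mode: str
    observed: float
    null: list[float] = field(repr=False)
    p_value: float = float("nan")
    n_perm: int = 0
    seed: int | None = None


def assemble_design(
    biofilm: BiofilmMatrix,
    centralities: pd.DataFrame,
    annotations: dict[str, str],
) -> pd.DataFrame:
    """Build the long (strain, environment) design table.

    One row per mutant strain × environment with the normalized biomass
    response, the environment's wild-type biomass, and the deleted
    protein's centrality bundle.  Strains whose protein has no
    centrality row are dropped with a log entry.
    """
    rows = []
    n_dropped = 0
    strains = [s for s in biofilm.strains if s != biofilm.wt_strain]
    for strain in strains:
        protein = biofilm.strain_meta.get(strain, strain)
        if protein not in centralities.index:
            n_dropped += 1
            logger.info("strain %s: protein %s lacks centrality data; dropped",
                        strain, protein)
            continue
        c = centralities.loc[protein]
        dual = 1.0 if annotations.get(protein) == "DUAL" else 0.0
        for env in biofilm.environments:
            rows.append(
                (strain, env, float(biofilm.values.at[strain, env]),
                 float(biofilm.wt.at[env]), float(c["eigenvector"]),
                 float(c["betweenness"]), float(c["pagerank"]), dual)
            )
    if n_dropped:
        logger.info("dropped %d strains without centrality data", n_dropped)
    if not rows:
        raise ValueError("no overlap between strains and centrality rows")
    return pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))


def _design_matrix(rows: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    x = np.column_stack([np.ones(len(rows))] + [rows[t].values for t in terms])
    return x


def _check_rank(x: np.ndarray, terms: tuple[str, ...]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]}); "
            f"check for collinear terms among {('intercept',) + terms}"
        )


def _fit(rows: pd.DataFrame, terms: tuple[str, ...]) -> RegressionFit:
    y = rows["biofilm"].values
    x = _design_matrix(rows, terms)
    if len(y) <= x.shape[1]:
        raise ValueError(f"too few observations ({len(y)}) for {x.shape[1]} terms")
    _check_rank(x, terms)
    res = sm.OLS(y, x).fit()
    names = ("intercept",) + terms
    return RegressionFit(
        coefficients=dict(zip(names, res.params.tolist())),
        p_values=dict(zip(names, res.pvalues.tolist())),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        n_obs=int(res.nobs),
        std_errors=dict(zip(names, res.bse.tolist())),
    )


def fit_ols(rows: pd.DataFrame) -> RegressionFit:
    """Fit the full biofilm model (wt + 3 centralities + dual indicator)."""
    return _fit(rows, FULL_TERMS)


def fit_baseline(rows: pd.DataFrame) -> RegressionFit:
    """Fit the wild-type-only baseline (intercept + wt)."""
    return _fit(rows, ("wt",))


def _adj_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Adjusted R² by least squares; fast path for permutation loops."""
    n, p = x.shape  # p includes the intercept column
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    ss_res = resid @ resid
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p)


def permutation_test(
    rows: pd.DataFrame,
    mode: str = "ppi_only",
    n_perm: int = 199,
    seed: int | None = 0,
) -> PermutationResult:
    """Permutation null for the full model's adjusted R².

    ``all``: shuffle the biofilm response across all rows.
    ``ppi_only``: shuffle the strain → (eigenvector, betweenness,
    PageRank, dual) assignment across strains, each bundle moving as a
    unit; response, wild-type and environment structure stay fixed, so
    the baseline model is numerically untouched by the shuffle.
    """
    if mode not in ("all", "ppi_only"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = np.random.default_rng(seed)
    y = rows["biofilm"].values.astype(float)
    x = _design_matrix(rows, FULL_TERMS)
    observed = _adj_r2(x, y)

    null = np.empty(n_perm)
    if mode == "all":
        for b in range(n_perm):
            null[b] = _adj_r2(x, rng.permutation(y))
    else:
        strains = rows["strain"].values
        uniq = pd.unique(strains)
        # each strain's constant centrality bundle
        bundles = (
            rows.drop_duplicates("strain")
            .set_index("strain")[list(PPI_TERMS)]
        )
        strain_codes = pd.Categorical(strains, categories=uniq).codes
        bundle_arr = bundles.loc[uniq].values  # aligned with uniq order
        for b in range(n_perm):
            perm = rng.permutation(len(uniq))
            permuted = bundle_arr[perm][strain_codes]
            xp = x.copy()
            xp[:, 2:] = permuted  # columns after intercept and wt
            null[b] = _adj_r2(xp, y)
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return PermutationResult(
        mode=mode,
        observed=float(observed),
        null=null.tolist(),
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )
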