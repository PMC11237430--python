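"""Standardization and PCA of the centrality matrix, with loadings.

Raw centralities live on incommensurate scales (degree in tens,
PageRank near 1/n), so features are z-scored (sample SD, n−1) before
the ordination.  The PCA is a plain SVD of the centered matrix; the
sign of each loading column is fixed so that its largest-magnitude
entry is positive, making plots reproducible run to run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("hubnet")


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (mean 0, sample SD 1).

    Zero-variance columns become all-zero and are listed in
    ``result.attrs["zero_variance"]`` rather than dropped, so downstream
    loading matrices keep one row per feature.
    """
    if len(matrix) < 2:
        raise ValueError("standardize requires at least 2 rows")
    x = matrix.astype(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    flagged = sd.index[sd == 0].tolist()
    safe_sd = sd.replace(0.0, 1.0)
    z = (x - mu) / safe_sd
    z[flagged] = 0.0
    if flagged:
        logger.info("zero-variance columns zeroed: %s", flagged)
    z.attrs["zero_variance"] = flagged
    return z


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a PCA.

    ``scores`` is samples × components, ``loadings`` features ×
    components (orthonormal columns), ``explained_fraction`` sums to 1
    over all components, ordered decreasing.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_fraction: np.ndarray
    column_means: pd.Series = field(repr=False, default=None)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def reconstruct(self) -> pd.DataFrame:
        """Invert the projection: scores · loadingsᵀ + column means."""
        x = self.scores.values @ self.loadings.values.T
        return pd.DataFrame(
            x + self.column_means.values,
            index=self.scores.index,
            columns=self.loadings.index,
        )


def pca(matrix: pd.DataFrame) -> PCAResult:
    """Principal component analysis of a (typically standardized) matrix.

    Centers columns, takes the SVD, and returns all min(n−1, p)
    components.  Reconstruction with every component reproduces the
    input to numerical precision.
    """
    if len(matrix) < 2:
        raise ValueError("pca requires at least 2 rows")
    x = matrix.astype(float)
    mu = x.mean(axis=0)
    xc = (x - mu).values
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # sign convention: largest-|entry| of each loading column positive
    flips = np.array(
        [np.sign(vt[j, np.argmax(np.abs(vt[j]))]) or 1.0 for j in range(vt.shape[0])]
    )
    vt = vt * flips[:, None]
    u = u * flips[None, :]
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.full_like(var, 1.0 / len(var))
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=x.index, columns=comp_names)
    loadings = pd.DataFrame(vt.T, index=x.columns, columns=comp_names)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_fraction=frac,
        column_means=mu,
    )
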