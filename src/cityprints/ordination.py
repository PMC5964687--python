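"""Correlation-based principal component analysis of normalized rank profiles.

Levels (taxa) are the variables, samples the observations.  PCA is run on the
level-level Pearson correlation matrix — equivalently, on levels standardized
to zero mean and unit variance — so proportions of variance are invariant to
affine rescaling of any level.  Sign convention: within each component the
largest-magnitude loading is made positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PreconditionError
from .preprocess import NormalizedTable

logger = logging.getLogger(__name__)

__all__ = ["PcaResult", "run_pca", "variance_explained"]


@dataclass
class PcaResult:
    eigenvalues: np.ndarray          # descending
    proportions: np.ndarray          # eigenvalues / n_levels, sums to 1
    scores: pd.DataFrame             # sample x component (first 3 kept)
    loadings: pd.DataFrame           # level x component (all components)
    dropped_levels: list             # constant levels removed before PCA

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def run_pca(norm: NormalizedTable, n_score_components: int = 3) -> PcaResult:
    """PCA of the correlation structure of a normalized table."""
    data = norm.values.T            # samples x levels
    std = data.std(axis=0, ddof=1)
    constant = list(data.columns[(std == 0) | std.isna()])
    if constant:
        logger.warning("dropping %d constant levels before PCA: %s",
                       len(constant), constant[:5])
        data = data.drop(columns=constant)
        std = std.drop(index=constant)
    if data.shape[1] < 2:
        raise PreconditionError("PCA needs >= 2 levels with nonzero variance")

    z = (data - data.mean(axis=0)) / std
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic signs: largest |loading| positive in each component
    for j in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[pivot, j] < 0:
            eigvec[:, j] = -eigvec[:, j]

    proportions = eigval / eigval.sum()
    comp_names = [f"PC{j + 1}" for j in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=data.columns, columns=comp_names)
    k = min(n_score_components, len(eigval))
    scores = pd.DataFrame(z.to_numpy() @ eigvec[:, :k], index=data.index,
                          columns=comp_names[:k])
    return PcaResult(
        eigenvalues=eigval,
        proportions=proportions,
        scores=scores,
        loadings=loadings,
        dropped_levels=constant,
    )


def variance_explained(result: PcaResult, k: int) -> float:
    """Cumulative proportion of variance carried by the first ``k`` components."""
    if k < 1:
        raise PreconditionError("k must be >= 1")
    if k > result.n_components:
        raise PreconditionError(
            f"k={k} exceeds {result.n_components} components"
        )
    return float(result.proportions[:k].sum())
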