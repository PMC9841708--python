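"""Principal components analysis of the genotype matrix.

Missing calls are mean-imputed on the dosage scale, sites are centred
(covariance PCA by default; correlation PCA available via ``scale=True``)
and the sample covariance is eigendecomposed deterministically via the
samples x samples Gram matrix — no randomised solver, so results are
bit-reproducible on a platform.  Component signs are fixed so the largest
absolute loading of each component is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .matrix import GenotypeMatrix, center_sites, mean_impute

__all__ = ["PCAResult", "run_pca"]


@dataclass
class PCAResult:
    """Scores, per-component explained variance and site loadings.

    ``explained_variance_pct`` is each component's share of the *total*
    variance (100 * lambda_k / sum of all eigenvalues), matching how
    ordination plots are annotated.
    """

    scores: np.ndarray
    explained_variance_pct: np.ndarray
    component_loadings: np.ndarray
    sample_ids: List[str]
    site_ids: List[str]


def run_pca(
    gm: GenotypeMatrix, n_components: int, scale: bool = False
) -> PCAResult:
    """PCA of the (imputed, centred) dosage matrix.

    Parameters
    ----------
    gm
        Genotype matrix; masked cells are mean-imputed first.
    n_components
        Number of components to return; at most ``min(n_samples, n_sites)``.
    scale
        Standardise sites to unit variance (correlation PCA).  Default is
        covariance PCA on centred dosages.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if n_components < 1 or n_components > min(gm.n_samples, gm.n_sites):
        raise ValueError(
            f"n_components must be in [1, {min(gm.n_samples, gm.n_sites)}]"
        )
    complete = gm if gm.is_complete else mean_impute(gm)
    X, site_ids = center_sites(complete, scale=scale)
    n = X.shape[0]

    # Eigendecomposition of the samples x samples Gram matrix: identical
    # spectrum to the sites x sites covariance but far smaller for GBS data.
    G = (X @ X.T) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(G)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    total_variance = eigvals.sum()
    lam = eigvals[:n_components]
    U = eigvecs[:, :n_components]

    # scores_k = sqrt((n-1) * lambda_k) * u_k; loadings v_k = X^T u_k / |.|
    scores = U * np.sqrt(np.maximum(lam, 0.0) * (n - 1))[np.newaxis, :]
    loadings = X.T @ U
    norms = np.linalg.norm(loadings, axis=0)
    nonzero = norms > 0
    loadings[:, nonzero] /= norms[nonzero]

    # Deterministic sign convention.
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * lam / total_variance if total_variance > 0 else np.zeros_like(lam)

    return PCAResult(
        scores=scores,
        explained_variance_pct=pct,
        component_loadings=loadings,
        sample_ids=list(gm.sample_ids),
        site_ids=site_ids,
    )
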