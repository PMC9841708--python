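"""Numeric dosage matrix with an explicit missingness mask.

Genotype calls are converted to alternate-allele dosage on the diploid
scale {0, 1, 2}; missing calls are masked.  Mean imputation and per-site
centring are the shared preprocessing behind both the PCA ordination and
the admixture estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .io import MISSING, VariantDataset

__all__ = [
    "GenotypeMatrix",
    "build_dosage_matrix",
    "mean_impute",
    "center_sites",
    "allele_frequencies",
]

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """n_samples x n_sites dosage matrix.

    ``values`` holds alternate-allele dosage on the diploid scale
    (0..2; fractional values arise after imputation); ``mask`` is True where
    the call is missing, in which case the value cell carries no
    information.
    """

    values: np.ndarray
    mask: np.ndarray
    sample_ids: List[str]
    site_ids: List[str]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    @property
    def is_complete(self) -> bool:
        return not bool(self.mask.any())

    def validate(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape != (len(self.sample_ids), len(self.site_ids)):
            raise ValueError("matrix shape does not match id lists")
        unmasked = self.values[~self.mask]
        if unmasked.size and (unmasked.min() < 0 or unmasked.max() > 2):
            raise ValueError("dosage values must lie in [0, 2]")


def build_dosage_matrix(ds: VariantDataset) -> GenotypeMatrix:
    """Convert a biallelic dataset into a dosage matrix.

    Dosage is the number of alternate alleles in the unordered call; a
    missing call is masked (the value cell is NaN).  Multi-allelic records
    must have been excluded upstream and raise an error naming the record.
    """
    for rec in ds.records:
        if not rec.is_biallelic:
            raise ValueError(
                f"record {rec.site_id} is multi-allelic "
                f"({rec.n_alleles - 1} ALT alleles); matrix construction "
                "requires biallelic records"
            )
    n, m = ds.n_samples, ds.n_sites
    values = np.full((n, m), np.nan)
    mask = np.ones((n, m), dtype=bool)
    for j, rec in enumerate(ds.records):
        for i, gt in enumerate(rec.genotypes):
            if gt is not MISSING:
                values[i, j] = gt[0] + gt[1]
                mask[i, j] = False
    gm = GenotypeMatrix(
        values=values,
        mask=mask,
        sample_ids=list(ds.samples),
        site_ids=[rec.site_id for rec in ds.records],
    )
    gm.validate()
    return gm


def mean_impute(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace masked cells with the site's unmasked mean dosage.

    Imputation preserves per-site means exactly and keeps imputed values on
    the dosage scale.  A site with no unmasked call cannot be imputed and
    raises (the site-completeness filter makes that case unreachable in the
    standard cascade).
    """
    observed = ~gm.mask
    n_obs = observed.sum(axis=0)
    if (n_obs == 0).any():
        bad = [gm.site_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"cannot impute all-missing sites: {bad[:5]}")
    values = np.where(gm.mask, 0.0, gm.values)
    site_means = values.sum(axis=0) / n_obs
    imputed = np.where(gm.mask, site_means[np.newaxis, :], gm.values)
    return GenotypeMatrix(
        values=imputed,
        mask=np.zeros_like(gm.mask),
        sample_ids=list(gm.sample_ids),
        site_ids=list(gm.site_ids),
    )


def center_sites(
    gm: GenotypeMatrix, scale: bool = False
) -> Tuple[np.ndarray, List[str]]:
    """Centre each site column to mean zero; optionally standardise.

    Returns the centred matrix and the site ids retained.  With
    ``scale=True``, zero-variance columns are dropped (with a logged count)
    rather than producing division-by-zero artefacts; without scaling all
    columns are kept.
    """
    if not gm.is_complete:
        raise ValueError("center_sites requires a complete (imputed) matrix")
    X = gm.values - gm.values.mean(axis=0, keepdims=True)
    site_ids = list(gm.site_ids)
    if scale:
        sd = gm.values.std(axis=0)
        keep = sd > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropped %d zero-variance sites before scaling", n_dropped)
        X = X[:, keep] / sd[keep][np.newaxis, :]
        site_ids = [s for s, k in zip(site_ids, keep) if k]
    return X, site_ids


def allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site alternate-allele frequency over unmasked calls."""
    observed = ~gm.mask
    n_obs = observed.sum(axis=0)
    values = np.where(gm.mask, 0.0, gm.values)
    with np.errstate(invalid="ignore"):
        freq = values.sum(axis=0) / (2.0 * n_obs)
    return freq
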