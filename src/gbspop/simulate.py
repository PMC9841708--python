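"""Synthetic GBS datasets with known population structure.

The generator emulates the *post-assembly* product of a reduced-
representation (GBS/RAD) study of labelled populations: thousands of short
contigs each carrying one-to-several linked SNPs, diploid-coded genotype
calls across tens of samples, missing calls scattered at random, and —
optionally — a handful of species-diagnostic fixed differences planted
between two designated groups.  Alongside the dataset it returns the
ground truth (true memberships, true population allele frequencies,
planted-site ids) that parameter-recovery tests need.

Statistical model
-----------------
Population allele frequencies follow the Balding–Nichols model: an
ancestral frequency ``p ~ Uniform(0.05, 0.95)`` is drawn per locus, and
population ``k``'s frequency is ``p_k ~ Beta(p (1-F_k)/F_k,
(1-p)(1-F_k)/F_k)``, where ``F_k`` is the drift/divergence parameter.
SNPs within the same locus share their ``p_k`` up to a small jitter, which
induces realistic within-contig correlation without simulating haplotypes.
Individual memberships are one-hot (unadmixed) or
``q ~ Dirichlet(alpha * 1_K)``, and dosages follow the admixture (PSD)
model ``x ~ Binomial(2, q^T p)``.  Missingness is MCAR, applied per cell
at rate ``1 - (1 - rate_ind) (1 - rate_site)``.

When diagnostic markers are planted, the designated group A is fixed
homozygous reference and group B fixed homozygous alternate at the planted
sites (no missingness there), and any *background* site that is fully
segregated between the designated groups by chance is broken by flipping
one call to a heterozygote — so the planted list is the exact ground truth
for plant-and-recover tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .io import (
    Locus,
    LociCollection,
    PopulationMap,
    VariantDataset,
    VariantRecord,
)
from .segregation import iupac_code

__all__ = ["SimConfig", "SimTruth", "simulate_dataset", "summarize_truth"]

#: Jitter (standard deviation) applied to within-locus shared frequencies.
LOCUS_FREQ_JITTER = 0.05

_DOSAGE_TO_CALL = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults are chosen to resemble a desk-scale GBS study of a structured
    plant species complex: 3 populations x 20 samples, 500 contigs of
    120 bp carrying 1–4 linked SNPs each, moderate drift (F = 0.15),
    unadmixed individuals, and ~10% realised missingness.
    """

    n_populations: int = 3
    samples_per_population: int = 20
    n_loci: int = 500
    snps_per_locus: Union[int, Tuple[int, int]] = (1, 4)
    locus_length: int = 120
    divergence_F: Union[float, Sequence[float]] = 0.15
    admixture_alpha: float = 0.0
    missing_rate_individual: float = 0.05
    missing_rate_site: float = 0.05
    n_planted_fixed_differences: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1 or self.samples_per_population < 1:
            raise ValueError("need at least one population and one sample")
        if not 0.0 <= self.missing_rate_individual < 1.0:
            raise ValueError("missing_rate_individual must be in [0, 1)")
        if not 0.0 <= self.missing_rate_site < 1.0:
            raise ValueError("missing_rate_site must be in [0, 1)")
        if self.n_planted_fixed_differences > self.n_loci:
            raise ValueError("cannot plant more fixed differences than loci")
        if self.n_planted_fixed_differences > 0 and self.n_populations < 2:
            raise ValueError("planting fixed differences needs two designated groups")
        for F in self.pop_F():
            if not 0.0 < F < 1.0:
                raise ValueError("divergence_F values must lie in (0, 1)")
        if self.admixture_alpha < 0:
            raise ValueError("admixture_alpha must be >= 0")

    def pop_F(self) -> List[float]:
        if isinstance(self.divergence_F, (int, float)):
            return [float(self.divergence_F)] * self.n_populations
        F = [float(x) for x in self.divergence_F]
        if len(F) != self.n_populations:
            raise ValueError("divergence_F list length must equal n_populations")
        return F

    def snps_for_locus(self, rng: np.random.Generator) -> int:
        if isinstance(self.snps_per_locus, int):
            return self.snps_per_locus
        lo, hi = self.snps_per_locus
        return int(rng.integers(lo, hi + 1))


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    Q: np.ndarray  # n_samples x K
    pop_freqs: np.ndarray  # n_sites x K
    planted_site_ids: List[str]
    sample_ids: List[str]
    site_ids: List[str]
    pop_labels: List[str] = field(default_factory=list)


def _draw_balding_nichols(
    rng: np.random.Generator, p_anc: float, F: float
) -> float:
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    return float(rng.beta(a, b))


def simulate_dataset(
    cfg: SimConfig,
) -> Tuple[VariantDataset, PopulationMap, LociCollection, SimTruth]:
    """Generate a dataset, population map, locus alignments and truth.

    All randomness flows from ``cfg.seed``; the same config yields a
    byte-identical dataset (and therefore byte-identical VCF output).
    """
    rng = np.random.default_rng(cfg.seed)
    K = cfg.n_populations
    pop_names = [f"pop{k + 1}" for k in range(K)]
    samples: List[str] = []
    pop_labels: List[str] = []
    for k, pop in enumerate(pop_names):
        for i in range(cfg.samples_per_population):
            samples.append(f"{pop}_ind{i:03d}")
            pop_labels.append(pop)
    n = len(samples)

    # Memberships: one-hot blocks (unadmixed) or i.i.d. Dirichlet.
    if cfg.admixture_alpha == 0.0:
        Q = np.zeros((n, K))
        for i, pop in enumerate(pop_labels):
            Q[i, pop_names.index(pop)] = 1.0
    else:
        Q = rng.dirichlet(np.full(K, cfg.admixture_alpha), size=n)

    pop_F = cfg.pop_F()

    # Per-locus layout and per-SNP population frequencies.
    locus_ids: List[str] = []
    locus_snp_cols: List[List[int]] = []
    site_locus: List[int] = []
    site_col: List[int] = []
    pop_freq_rows: List[np.ndarray] = []
    for l in range(cfg.n_loci):
        locus_ids.append(f"loc{l:05d}")
        s = cfg.snps_for_locus(rng)
        cols = sorted(int(c) for c in rng.choice(cfg.locus_length, size=s, replace=False))
        locus_snp_cols.append(cols)
        p_anc = float(rng.uniform(0.05, 0.95))
        p_locus = np.array(
            [_draw_balding_nichols(rng, p_anc, pop_F[k]) for k in range(K)]
        )
        for col in cols:
            jitter = rng.normal(0.0, LOCUS_FREQ_JITTER, size=K)
            pop_freq_rows.append(np.clip(p_locus + jitter, 0.01, 0.99))
            site_locus.append(l)
            site_col.append(col)
    P = np.vstack(pop_freq_rows)  # m x K
    m = P.shape[0]

    # PSD dosages and MCAR missingness.
    F_ind = P @ Q.T  # m x n individual-specific alt-allele frequencies
    dosage = rng.binomial(2, F_ind)  # m x n
    p_miss = 1.0 - (1.0 - cfg.missing_rate_individual) * (1.0 - cfg.missing_rate_site)
    missing = rng.random((m, n)) < p_miss

    # REF/ALT bases per site.
    bases = "ACGT"
    ref_idx = rng.integers(0, 4, size=m)
    alt_shift = rng.integers(1, 4, size=m)
    refs = [bases[i] for i in ref_idx]
    alts = [bases[(i + s) % 4] for i, s in zip(ref_idx, alt_shift)]

    group_a_idx = [i for i, p in enumerate(pop_labels) if p == pop_names[0]]
    group_b_idx = (
        [i for i, p in enumerate(pop_labels) if p == pop_names[1]] if K >= 2 else []
    )

    # Plant diagnostic fixed differences: group A fixed REF, group B fixed
    # ALT, no missingness at planted sites.
    planted_sites: List[int] = []
    if cfg.n_planted_fixed_differences > 0:
        planted_loci = rng.choice(
            cfg.n_loci, size=cfg.n_planted_fixed_differences, replace=False
        )
        locus_sites: Dict[int, List[int]] = {}
        for j, l in enumerate(site_locus):
            locus_sites.setdefault(l, []).append(j)
        center = (cfg.locus_length + 1) / 2.0
        for l in sorted(int(x) for x in planted_loci):
            # plant on the centre-closest SNP so the marker survives
            # one-SNP-per-locus thinning downstream
            j = min(
                locus_sites[l],
                key=lambda s: (abs(site_col[s] + 1 - center), site_col[s]),
            )
            dosage[j, group_a_idx] = 0
            dosage[j, group_b_idx] = 2
            missing[j, :] = False
            planted_sites.append(j)

        # Break accidental background segregation between the designated
        # groups so the planted list is the exact ground truth.
        planted_set = set(planted_sites)
        for j in range(m):
            if j in planted_set:
                continue
            obs_a = dosage[j, group_a_idx][~missing[j, group_a_idx]]
            obs_b = dosage[j, group_b_idx][~missing[j, group_b_idx]]
            if obs_a.size == 0 or obs_b.size == 0:
                continue
            al_a = set()
            for d in obs_a:
                al_a.update(_DOSAGE_TO_CALL[int(d)])
            al_b = set()
            for d in obs_b:
                al_b.update(_DOSAGE_TO_CALL[int(d)])
            if not al_a & al_b:
                i = group_a_idx[0]
                dosage[j, i] = 1
                missing[j, i] = False

    # Assemble VariantRecords.
    records: List[VariantRecord] = []
    site_ids: List[str] = []
    for j in range(m):
        contig = locus_ids[site_locus[j]]
        pos = site_col[j] + 1
        genotypes = [
            None if missing[j, i] else _DOSAGE_TO_CALL[int(dosage[j, i])]
            for i in range(n)
        ]
        records.append(
            VariantRecord(
                contig_id=contig,
                pos=pos,
                ref_allele=refs[j],
                alt_alleles=[alts[j]],
                genotypes=genotypes,
            )
        )
        site_ids.append(f"{contig}:{pos}")
    ds = VariantDataset(samples=samples, records=records)
    ds.validate()

    pm = PopulationMap(dict(zip(samples, pop_labels)))

    # Locus alignments consistent with the SNP calls: a random background
    # sequence with the REF base at each SNP column, and per-sample
    # substitutions (ALT for homozygous-alternate, IUPAC ambiguity for
    # heterozygous, N for missing).
    sites_of_locus: Dict[int, List[int]] = {}
    for j, l in enumerate(site_locus):
        sites_of_locus.setdefault(l, []).append(j)
    loci: Dict[str, Locus] = {}
    for l, locus_id in enumerate(locus_ids):
        background = [bases[b] for b in rng.integers(0, 4, size=cfg.locus_length)]
        for j in sites_of_locus[l]:
            background[site_col[j]] = refs[j]
        seqs: Dict[str, str] = {}
        for i, sample in enumerate(samples):
            chars = list(background)
            for j in sites_of_locus[l]:
                col = site_col[j]
                if missing[j, i]:
                    chars[col] = "N"
                elif dosage[j, i] == 2:
                    chars[col] = alts[j]
                elif dosage[j, i] == 1:
                    chars[col] = iupac_code({refs[j], alts[j]})
            seqs[sample] = "".join(chars)
        loci[locus_id] = Locus(
            locus_id=locus_id, sequences=seqs, snp_columns=locus_snp_cols[l]
        )
    lc = LociCollection(loci)

    truth = SimTruth(
        Q=Q,
        pop_freqs=P,
        planted_site_ids=[site_ids[j] for j in planted_sites],
        sample_ids=samples,
        site_ids=site_ids,
        pop_labels=pop_labels,
    )
    return ds, pm, lc, truth


def summarize_truth(truth: SimTruth) -> str:
    """Human-readable summary of the ground truth."""
    n, K = truth.Q.shape
    lines = [f"samples: {n}", f"populations (K): {K}", f"sites: {len(truth.site_ids)}"]
    if truth.pop_labels:
        counts: Dict[str, int] = {}
        for label in truth.pop_labels:
            counts[label] = counts.get(label, 0) + 1
        for label, c in counts.items():
            lines.append(f"  {label}: {c} samples")
    lines.append(f"planted fixed differences: {len(truth.planted_site_ids)}")
    for sid in truth.planted_site_ids:
        lines.append(f"  planted: {sid}")
    if K >= 2:
        divs = [
            float(np.mean(np.abs(truth.pop_freqs[:, a] - truth.pop_freqs[:, b])))
            for a in range(K)
            for b in range(a + 1, K)
        ]
        lines.append(f"mean pairwise frequency divergence: {np.mean(divs):.4f}")
    return "\n".join(lines) + "\n"
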