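"""Ordered SNP filtering cascade and per-locus centre-SNP thinning.

The cascade runs in a fixed order — individual missingness, site
completeness, minor-allele frequency, centre-SNP thinning — because each
stage changes the denominators the next stage uses.  Dropping a
high-missingness individual, for example, changes every site's presence
fraction, so reversing the order gives a different (and unintended) result.

Boundary semantics follow VCFtools conventions: individual missingness
drops strictly-greater-than the threshold; site presence and MAF keep
at-equal (a site whose rarer allele frequency is exactly the threshold is
retained).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .io import MISSING, LociCollection, VariantDataset

__all__ = [
    "FilterConfig",
    "FilterStage",
    "FilterReport",
    "filter_individual_missingness",
    "filter_site_completeness",
    "filter_maf",
    "thin_to_center_snp",
    "apply_cascade",
]

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds for the ordered cascade.

    Parameters
    ----------
    max_individual_missing
        Maximum fraction of missing calls an individual may have and still
        be kept (individuals strictly above are dropped).
    min_site_presence
        Minimum fraction of individuals a SNP must be called in.
    maf
        Minimum minor-allele frequency, computed over non-missing calls
        (two alleles per diploid-coded call).
    thin_to_center
        Whether to keep only the SNP closest to each contig's centre.
    min_allele_count
        Optional alternative to ``maf``: keep a site iff its minor allele is
        observed at least this many times.  When set, ``maf`` is ignored.
        This implements the "minimum allele frequency below 2 alleles"
        reading of the MAF rule literally.
    """

    max_individual_missing: float = 0.40
    min_site_presence: float = 0.80
    maf: float = 0.01
    thin_to_center: bool = True
    min_allele_count: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_individual_missing <= 1.0:
            raise ValueError("max_individual_missing must be in [0, 1]")
        if not 0.0 <= self.min_site_presence <= 1.0:
            raise ValueError("min_site_presence must be in [0, 1]")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError("maf must be in [0, 0.5]")
        if self.min_allele_count is not None and self.min_allele_count < 0:
            raise ValueError("min_allele_count must be >= 0")


@dataclass
class FilterStage:
    name: str
    n_samples_in: int
    n_samples_out: int
    n_sites_in: int
    n_sites_out: int


@dataclass
class FilterReport:
    """Per-stage accounting of the cascade."""

    stages: List[FilterStage] = field(default_factory=list)
    notes: List[str] = field(default_factory=list)

    @property
    def final_n_samples(self) -> int:
        return self.stages[-1].n_samples_out if self.stages else 0

    @property
    def final_n_sites(self) -> int:
        return self.stages[-1].n_sites_out if self.stages else 0

    def add(self, name: str, before: VariantDataset, after: VariantDataset) -> None:
        stage = FilterStage(
            name,
            before.n_samples,
            after.n_samples,
            before.n_sites,
            after.n_sites,
        )
        self.stages.append(stage)
        logger.info(
            "%s: %d -> %d samples, %d -> %d sites",
            name,
            stage.n_samples_in,
            stage.n_samples_out,
            stage.n_sites_in,
            stage.n_sites_out,
        )

    def to_text(self) -> str:
        lines = ["stage\tsamples_in\tsamples_out\tsites_in\tsites_out"]
        for s in self.stages:
            lines.append(
                f"{s.name}\t{s.n_samples_in}\t{s.n_samples_out}"
                f"\t{s.n_sites_in}\t{s.n_sites_out}"
            )
        for note in self.notes:
            lines.append(f"# {note}")
        return "\n".join(lines) + "\n"


def _missing_fraction_per_sample(ds: VariantDataset) -> List[float]:
    counts = [0] * ds.n_samples
    for rec in ds.records:
        for i, gt in enumerate(rec.genotypes):
            if gt is MISSING:
                counts[i] += 1
    return [c / ds.n_sites for c in counts]


def filter_individual_missingness(
    ds: VariantDataset, max_missing: float
) -> VariantDataset:
    """Drop every sample whose missing-call fraction exceeds ``max_missing``.

    The fraction is computed over the dataset's *current* records, so the
    cascade position of this filter matters.  Records are untouched.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    if ds.n_sites == 0:
        raise ValueError(
            "cannot compute individual missingness on a dataset with 0 records"
        )
    fractions = _missing_fraction_per_sample(ds)
    keep = [s for s, f in zip(ds.samples, fractions) if f <= max_missing]
    return ds.subset_samples(keep)


def filter_site_completeness(ds: VariantDataset, min_presence: float) -> VariantDataset:
    """Keep a record iff its fraction of non-missing calls is >= ``min_presence``."""
    if not 0.0 <= min_presence <= 1.0:
        raise ValueError("min_presence must be in [0, 1]")
    if ds.n_samples == 0:
        return VariantDataset(samples=[], records=[])
    kept = []
    for rec in ds.records:
        present = sum(1 for gt in rec.genotypes if gt is not MISSING)
        if present / ds.n_samples >= min_presence:
            kept.append(rec)
    return VariantDataset(samples=list(ds.samples), records=kept)


def _allele_counts(rec) -> Counter:
    counts: Counter = Counter()
    for gt in rec.genotypes:
        if gt is not MISSING:
            counts[gt[0]] += 1
            counts[gt[1]] += 1
    return counts


def minor_allele_frequency(rec) -> float:
    """Frequency of the rarest observed allele over non-missing calls.

    A site where only one allele is observed (monomorphic after
    missingness) has MAF 0.  A site with no non-missing call has MAF 0.
    """
    counts = _allele_counts(rec)
    if len(counts) < 2:
        return 0.0
    total = sum(counts.values())
    return min(counts.values()) / total


def minor_allele_count(rec) -> int:
    counts = _allele_counts(rec)
    if len(counts) < 2:
        return 0
    return min(counts.values())


def filter_maf(
    ds: VariantDataset, maf: float, min_allele_count_mode: Optional[int] = None
) -> VariantDataset:
    """Drop records whose minor-allele frequency is below ``maf``.

    Frequencies are computed over non-missing calls only (two alleles per
    call); the boundary is inclusive (MAF exactly equal to the threshold is
    kept).  Records with zero non-missing calls cannot be evaluated and are
    dropped with a log message.  If ``min_allele_count_mode`` is given, the
    criterion is a minimum observed count of the minor allele instead.
    """
    if not 0.0 <= maf <= 0.5:
        raise ValueError("maf must be in [0, 0.5]")
    kept = []
    n_uncallable = 0
    for rec in ds.records:
        counts = _allele_counts(rec)
        if not counts:
            n_uncallable += 1
            continue
        if min_allele_count_mode is not None:
            if minor_allele_count(rec) >= min_allele_count_mode:
                kept.append(rec)
        elif minor_allele_frequency(rec) >= maf:
            kept.append(rec)
    if n_uncallable:
        logger.info("MAF filter dropped %d sites with no non-missing calls", n_uncallable)
    return VariantDataset(samples=list(ds.samples), records=kept)


def thin_to_center_snp(
    ds: VariantDataset, loci: Optional[LociCollection] = None
) -> VariantDataset:
    """Keep, per contig, only the SNP closest to the contig's centre.

    The centre is ``(alignment length + 1) / 2`` (1-based) when the contig's
    locus alignment is supplied, else the midpoint of the observed SNP
    positions.  Ties in distance-to-centre are broken towards the lower
    position, which is deterministic and independent of record order.
    """
    by_contig: Dict[str, List] = {}
    for rec in ds.records:
        by_contig.setdefault(rec.contig_id, []).append(rec)
    winners = {}
    for contig, recs in by_contig.items():
        if loci is not None and contig in loci:
            center = (loci[contig].length + 1) / 2.0
        else:
            positions = [r.pos for r in recs]
            center = (min(positions) + max(positions)) / 2.0
        best = min(recs, key=lambda r: (abs(r.pos - center), r.pos))
        winners[contig] = (best.contig_id, best.pos)
    kept = [rec for rec in ds.records if winners[rec.contig_id] == (rec.contig_id, rec.pos)]
    return VariantDataset(samples=list(ds.samples), records=kept)


def apply_cascade(
    ds: VariantDataset,
    cfg: FilterConfig,
    loci: Optional[LociCollection] = None,
) -> Tuple[VariantDataset, FilterReport]:
    """Run the full ordered cascade and account for every stage.

    Order: individual missingness -> site completeness -> MAF ->
    centre-SNP thinning.  The order is part of the method: each stage's
    denominators depend on the previous stage's output.
    """
    report = FilterReport()
    current = ds

    out = filter_individual_missingness(current, cfg.max_individual_missing)
    report.add("individual_missingness", current, out)
    current = out

    out = filter_site_completeness(current, cfg.min_site_presence)
    report.add("site_completeness", current, out)
    current = out

    out = filter_maf(current, cfg.maf, min_allele_count_mode=cfg.min_allele_count)
    report.add("maf", current, out)
    current = out

    if cfg.thin_to_center:
        out = thin_to_center_snp(current, loci)
        report.add("center_snp_thinning", current, out)
        if loci is not None:
            report.notes.append(
                "centre defined from locus alignment length where available, "
                "else observed SNP span"
            )
        else:
            report.notes.append("centre defined from observed SNP span")
        current = out

    return current, report
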