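"""Fixed-difference (fully segregated) SNP detection and flanking consensus.

A SNP is *fully segregated* between two labelled groups when the allele
sets observed among the groups' non-missing calls are disjoint — for a
biallelic site, every call in one group homozygous for one allele and
every call in the other group homozygous for the other.  A single
heterozygote in either group disqualifies the site.  Missing calls are
ignored; they never count as wildcard matches.

For each such diagnostic SNP, the flanking region is recovered from the
locus alignment as a per-column majority consensus, with IUPAC ambiguity
codes at the focal SNP column and at tied columns, ready for homology
search against external sequence databases.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Set, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io import MISSING, LociCollection, PopulationMap, VariantDataset

__all__ = [
    "SegregatedSite",
    "SegregationReport",
    "ConsensusSequence",
    "find_fixed_differences",
    "extract_flanking_consensus",
    "export_fasta",
    "iupac_code",
]

#: IUPAC nucleotide ambiguity codes, keyed by the set of bases they denote.
IUPAC: Dict[FrozenSet[str], str] = {
    frozenset(bases): code
    for code, bases in {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
        "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
        "N": "ACGT",
    }.items()
}


def iupac_code(bases: Set[str]) -> str:
    """IUPAC ambiguity code for a non-empty set of bases."""
    if not bases:
        raise ValueError("empty base set has no IUPAC code")
    return IUPAC[frozenset(b.upper() for b in bases)]


@dataclass
class SegregatedSite:
    """One fully segregated SNP with per-group allele evidence."""

    contig_id: str
    pos: int
    alleles_a: Tuple[str, ...]
    alleles_b: Tuple[str, ...]
    n_calls_a: int
    n_calls_b: int

    @property
    def site_id(self) -> str:
        return f"{self.contig_id}:{self.pos}"


@dataclass
class SegregationReport:
    group_a: str
    group_b: str
    sites: List[SegregatedSite]

    def site_ids(self) -> List[str]:
        return [s.site_id for s in self.sites]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig_id": [s.contig_id for s in self.sites],
                "pos": [s.pos for s in self.sites],
                f"alleles_{self.group_a}": [",".join(s.alleles_a) for s in self.sites],
                f"alleles_{self.group_b}": [",".join(s.alleles_b) for s in self.sites],
                f"n_calls_{self.group_a}": [s.n_calls_a for s in self.sites],
                f"n_calls_{self.group_b}": [s.n_calls_b for s in self.sites],
            }
        )


@dataclass
class ConsensusSequence:
    """Flanking consensus of one locus around a focal (diagnostic) SNP."""

    locus_id: str
    sequence: str
    focal_position: int  # 0-based index within `sequence`

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if self.length < 1:
            raise ValueError("consensus sequence is empty")
        if not 0 <= self.focal_position < self.length:
            raise ValueError("focal position outside consensus sequence")


def find_fixed_differences(
    ds: VariantDataset,
    pm: PopulationMap,
    group_a: str,
    group_b: str,
    min_calls_per_group: int = 1,
    require_complete: bool = False,
) -> SegregationReport:
    """Report every site whose observed alleles are disjoint between groups.

    A site is reported iff each group has at least ``min_calls_per_group``
    non-missing calls and the allele sets observed in the two groups do not
    intersect.  ``require_complete=True`` additionally demands that *every*
    sample of both groups is called at the site.  Samples present in the
    dataset but absent from the population map are an error — silently
    defaulting a species label would fabricate diagnostic markers.
    """
    if min_calls_per_group < 1:
        raise ValueError("min_calls_per_group must be >= 1")
    labels = set(pm.labels())
    for label in (group_a, group_b):
        if label not in labels:
            raise ValueError(f"group label {label!r} not present in population map")
    unassigned = [s for s in ds.samples if s not in pm]
    if unassigned:
        raise ValueError(
            f"samples without population assignment: {unassigned[:5]}"
        )
    idx_a = [i for i, s in enumerate(ds.samples) if pm[s] == group_a]
    idx_b = [i for i, s in enumerate(ds.samples) if pm[s] == group_b]

    sites: List[SegregatedSite] = []
    for rec in ds.records:
        alleles_a: Set[int] = set()
        alleles_b: Set[int] = set()
        n_a = n_b = 0
        for i in idx_a:
            gt = rec.genotypes[i]
            if gt is not MISSING:
                n_a += 1
                alleles_a.update(gt)
        for i in idx_b:
            gt = rec.genotypes[i]
            if gt is not MISSING:
                n_b += 1
                alleles_b.update(gt)
        if n_a < min_calls_per_group or n_b < min_calls_per_group:
            continue
        if require_complete and (n_a < len(idx_a) or n_b < len(idx_b)):
            continue
        if not alleles_a or not alleles_b or (alleles_a & alleles_b):
            continue
        bases = [rec.ref_allele] + list(rec.alt_alleles)
        sites.append(
            SegregatedSite(
                contig_id=rec.contig_id,
                pos=rec.pos,
                alleles_a=tuple(bases[a] for a in sorted(alleles_a)),
                alleles_b=tuple(bases[b] for b in sorted(alleles_b)),
                n_calls_a=n_a,
                n_calls_b=n_b,
            )
        )
    return SegregationReport(group_a=group_a, group_b=group_b, sites=sites)


def _expand_base(c: str) -> Set[str]:
    """Base set denoted by a nucleotide character (handles ambiguity codes)."""
    for base_set, code in IUPAC.items():
        if code == c:
            return set(base_set)
    raise ValueError(f"unknown nucleotide character {c!r}")


def _column_consensus(chars: List[str], focal: bool) -> str:
    """Consensus character of one alignment column.

    Majority character among informative (non-gap, non-N) characters; at
    the focal column the IUPAC code of *all* observed bases, at tied
    columns the IUPAC code of the union of the tied characters' base sets.
    Sample sequences may themselves carry ambiguity codes (heterozygous
    calls rendered as IUPAC bases); those are expanded before coding.
    A column with no informative character is 'N'.
    """
    informative = [c for c in chars if c not in ("-", "N")]
    if not informative:
        return "N"
    if focal:
        observed: Set[str] = set()
        for c in informative:
            observed |= _expand_base(c)
        return iupac_code(observed)
    counts = Counter(informative)
    top = max(counts.values())
    tied = sorted(c for c, n in counts.items() if n == top)
    if len(tied) == 1:
        return tied[0]
    union: Set[str] = set()
    for c in tied:
        union |= _expand_base(c)
    return iupac_code(union)


def extract_flanking_consensus(
    loci: LociCollection, contig_id: str, snp_column: int
) -> ConsensusSequence:
    """Per-column consensus of a locus alignment around a focal SNP column.

    Majority-gap columns (more gaps than non-gap characters, or exactly
    half) are removed, which also trims leading/trailing all-gap columns;
    the focal SNP's position is re-indexed accordingly.
    """
    locus = loci[contig_id]
    seqs = list(locus.sequences.values())
    if not seqs:
        raise ValueError(f"locus {contig_id} has no sequences")
    length = locus.length
    if not 0 <= snp_column < length:
        raise ValueError(
            f"SNP column {snp_column} outside locus {contig_id} "
            f"(length {length})"
        )
    out: List[str] = []
    focal_out = -1
    for col in range(length):
        chars = [s[col].upper() for s in seqs]
        n_gap = sum(1 for c in chars if c == "-")
        if n_gap * 2 >= len(chars):
            if col == snp_column:
                raise ValueError(
                    f"focal SNP column {snp_column} of locus {contig_id} "
                    "is a majority-gap column"
                )
            continue
        if col == snp_column:
            focal_out = len(out)
        out.append(_column_consensus(chars, focal=(col == snp_column)))
    consensus = ConsensusSequence(
        locus_id=contig_id, sequence="".join(out), focal_position=focal_out
    )
    consensus.validate()
    return consensus


def export_fasta(seqs: List[ConsensusSequence], path) -> None:
    """Write consensus sequences as FASTA.

    Each header carries the locus id plus the focal SNP offset (0-based)
    and sequence length, e.g. ``>loc7 snp_offset=31 length=112``.
    """
    if not seqs:
        raise ValueError("no consensus sequences to export")
    records = []
    for cs in seqs:
        cs.validate()
        records.append(
            SeqRecord(
                Seq(cs.sequence),
                id=cs.locus_id,
                description=f"snp_offset={cs.focal_position} length={cs.length}",
            )
        )
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def parse_fasta_header(description: str) -> Tuple[str, int, int]:
    """Parse a header written by :func:`export_fasta`.

    Returns ``(locus_id, snp_offset, length)``; the inverse of the header
    format above, used to hand segregated-marker coordinates downstream.
    """
    parts = description.split()
    locus_id = parts[0]
    fields = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
    return locus_id, int(fields["snp_offset"]), int(fields["length"])
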