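"""Readers and writers for the formats the GBS pipeline touches.

The internal data model is deliberately small: a :class:`VariantDataset`
holds biallelic-or-multiallelic SNP records with diploid-coded genotype
calls, a :class:`PopulationMap` assigns samples to group labels (species or
sampling site), and a :class:`LociCollection` holds per-locus alignments in
the ipyrad ``.loci`` dialect, from which flanking consensus sequences are
later extracted.

Genotype calls are *unordered* pairs of allele indices (0 = REF, k = k-th
ALT); phase separators are accepted on input but phase is discarded, because
the assembler's diploid-coded calls for polyploid samples carry no reliable
phase.  Missing calls are represented as ``None``.

VCF reading is delegated to :mod:`pysam` (htslib).  Writing emits a minimal,
deterministic GT-only VCF 4.2 so that write -> read -> write is byte-stable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Tuple

import pysam

__all__ = [
    "MISSING",
    "Genotype",
    "VariantRecord",
    "VariantDataset",
    "PopulationMap",
    "Locus",
    "LociCollection",
    "VcfParseError",
    "PopmapError",
    "LociParseError",
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "write_popmap",
    "read_loci",
    "write_loci",
]

#: Sentinel for a missing genotype call.
MISSING = None

#: A diploid-coded call: unordered pair of allele indices, or ``None``.
Genotype = Optional[Tuple[int, int]]


class VcfParseError(ValueError):
    """Raised when a VCF file cannot be parsed into the data model."""


class PopmapError(ValueError):
    """Raised for malformed or contradictory population maps."""


class LociParseError(ValueError):
    """Raised when a ``.loci`` file violates the pinned dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VariantRecord:
    """One SNP: a position on an assembled contig plus per-sample calls.

    Parameters
    ----------
    contig_id
        Identifier of the assembled locus (contig) carrying the SNP.
    pos
        1-based position within the contig.
    ref_allele
        Reference nucleotide.
    alt_alleles
        Ordered list of one or more alternate nucleotides.
    genotypes
        Per-sample diploid-coded calls, aligned with the dataset's sample
        list.  Each call is an unordered pair of allele indices stored in
        ascending order, or ``None`` for missing.
    """

    contig_id: str
    pos: int
    ref_allele: str
    alt_alleles: List[str]
    genotypes: List[Genotype]

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt_alleles)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    @property
    def site_id(self) -> str:
        return f"{self.contig_id}:{self.pos}"

    def validate(self, n_samples: int) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.site_id}: position must be >= 1")
        if not self.alt_alleles:
            raise ValueError(f"{self.site_id}: at least one ALT allele required")
        if len(self.genotypes) != n_samples:
            raise ValueError(
                f"{self.site_id}: {len(self.genotypes)} calls for "
                f"{n_samples} samples"
            )
        for gt in self.genotypes:
            if gt is MISSING:
                continue
            if len(gt) != 2:
                raise ValueError(f"{self.site_id}: non-diploid call {gt!r}")
            if any(a < 0 or a >= self.n_alleles for a in gt):
                raise ValueError(f"{self.site_id}: allele index out of range in {gt!r}")


@dataclass
class VariantDataset:
    """An ordered collection of samples x SNP records."""

    samples: List[str]
    records: List[VariantRecord]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")
        for rec in self.records:
            rec.validate(self.n_samples)

    def subset_samples(self, keep: List[str]) -> "VariantDataset":
        """Return a dataset restricted to ``keep`` (in dataset order)."""
        index = {s: i for i, s in enumerate(self.samples)}
        idx = [index[s] for s in self.samples if s in set(keep)]
        kept = [self.samples[i] for i in idx]
        records = [
            replace(rec, genotypes=[rec.genotypes[i] for i in idx])
            for rec in self.records
        ]
        return VariantDataset(samples=kept, records=records)


class PopulationMap:
    """Mapping of sample identifier to group label (species or site).

    Lookup of an unassigned sample raises :class:`KeyError`; there is no
    silent default, because misassigned samples corrupt every downstream
    group statistic.
    """

    def __init__(self, assignments: Dict[str, str]):
        for sample, label in assignments.items():
            if not label:
                raise PopmapError(f"empty group label for sample {sample!r}")
        self.assignments: Dict[str, str] = dict(assignments)

    def __getitem__(self, sample: str) -> str:
        try:
            return self.assignments[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} has no population assignment")

    def __contains__(self, sample: str) -> bool:
        return sample in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)

    def labels(self) -> List[str]:
        """Distinct labels, in first-appearance order."""
        seen: Dict[str, None] = {}
        for label in self.assignments.values():
            seen.setdefault(label, None)
        return list(seen)

    def samples_for(self, label: str) -> List[str]:
        return [s for s, l in self.assignments.items() if l == label]


@dataclass
class Locus:
    """One assembled locus: an alignment of per-sample sequences.

    ``snp_columns`` are 0-based column indices of variable positions, taken
    from the marker annotations on the ``.loci`` terminator line.
    """

    locus_id: str
    sequences: Dict[str, str]
    snp_columns: List[int]

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def validate(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"locus {self.locus_id}: unequal sequence lengths")
        for col in self.snp_columns:
            if not 0 <= col < self.length:
                raise ValueError(
                    f"locus {self.locus_id}: SNP column {col} outside alignment"
                )


class LociCollection:
    """Mapping of locus identifier to :class:`Locus`."""

    def __init__(self, loci: Dict[str, Locus]):
        self.loci: Dict[str, Locus] = dict(loci)

    def __getitem__(self, locus_id: str) -> Locus:
        try:
            return self.loci[locus_id]
        except KeyError:
            raise KeyError(f"locus {locus_id!r} not in collection")

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.loci

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[str]:
        return iter(self.loci)

    def items(self):
        return self.loci.items()


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path) -> VariantDataset:
    """Read a VCF 4.x file with GT fields into a :class:`VariantDataset`.

    ``./.`` and ``.`` calls become missing; ``0|1`` and ``1/0`` parse to the
    same unordered call.  Calls with an arity other than 2 are rejected:
    the pipeline operates on diploid-coded genotypes only (true polyploid
    calls are an open genotyping problem upstream of this package).
    """
    path = Path(path)
    verbosity = pysam.set_verbosity(0)
    try:
        try:
            vf = pysam.VariantFile(str(path))
        except (ValueError, OSError) as exc:
            raise VcfParseError(f"malformed VCF header in {path}: {exc}") from exc
        samples = list(vf.header.samples)
        records: List[VariantRecord] = []
        iterator = iter(vf)
        while True:
            try:
                raw = next(iterator)
            except StopIteration:
                break
            except (OSError, ValueError) as exc:
                raise VcfParseError(
                    f"cannot parse record {len(records) + 1} of {path}: {exc}"
                ) from exc
            if raw.alts is None:
                raise VcfParseError(
                    f"record {len(records) + 1} ({raw.chrom}:{raw.pos}) "
                    "declares no ALT allele"
                )
            genotypes: List[Genotype] = []
            for name in samples:
                call = raw.samples[name]
                gt = call.get("GT")
                if gt is None or all(a is None for a in gt):
                    genotypes.append(MISSING)
                    continue
                if len(gt) != 2:
                    raise VcfParseError(
                        f"{raw.chrom}:{raw.pos} sample {name}: call arity "
                        f"{len(gt)}; only diploid-coded (arity-2) calls are "
                        "supported"
                    )
                if any(a is None for a in gt):
                    genotypes.append(MISSING)
                    continue
                a, b = sorted(gt)
                genotypes.append((a, b))
            records.append(
                VariantRecord(
                    contig_id=raw.chrom,
                    pos=raw.pos,
                    ref_allele=raw.ref,
                    alt_alleles=list(raw.alts),
                    genotypes=genotypes,
                )
            )
    finally:
        pysam.set_verbosity(verbosity)
    ds = VariantDataset(samples=samples, records=records)
    ds.validate()
    return ds


def write_vcf(ds: VariantDataset, path) -> None:
    """Write a minimal, deterministic GT-only VCF 4.2 file.

    Missing calls are written as ``./.``.  Contig header lines are emitted
    in first-appearance order so that equal datasets produce byte-identical
    files.
    """
    ds.validate()
    contigs: Dict[str, None] = {}
    for rec in ds.records:
        contigs.setdefault(rec.contig_id, None)
    lines = ["##fileformat=VCFv4.2", "##source=gbspop"]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.extend(f"##contig=<ID={c}>" for c in contigs)
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(ds.samples)
    lines.append("\t".join(header))
    for rec in ds.records:
        fields = [
            rec.contig_id,
            str(rec.pos),
            ".",
            rec.ref_allele,
            ",".join(rec.alt_alleles),
            ".",
            ".",
            ".",
            "GT",
        ]
        for gt in rec.genotypes:
            fields.append("./." if gt is MISSING else f"{gt[0]}/{gt[1]}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------


def read_popmap(path) -> PopulationMap:
    """Read a whitespace-delimited two-column sample -> group map.

    Lines starting with ``#`` and blank lines are skipped.  A sample listed
    twice with the same label is accepted (idempotent); with conflicting
    labels it is an error.
    """
    path = Path(path)
    assignments: Dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise PopmapError(
                f"{path}:{lineno}: expected two columns, got {len(parts)}"
            )
        sample, label = parts
        if sample in assignments and assignments[sample] != label:
            raise PopmapError(
                f"{path}:{lineno}: sample {sample!r} assigned to both "
                f"{assignments[sample]!r} and {label!r}"
            )
        assignments[sample] = label
    if not assignments:
        raise PopmapError(f"{path}: no assignments found")
    return PopulationMap(assignments)


def write_popmap(pm: PopulationMap, path) -> None:
    lines = [f"{sample}\t{label}" for sample, label in pm.assignments.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ipyrad-style .loci
# ---------------------------------------------------------------------------

_SEQ_LINE = re.compile(r"^(\S+)(\s+)(\S+)\s*$")
_TERMINATOR_ID = re.compile(r"\|([^|]*)\|\s*$")


def read_loci(path) -> LociCollection:
    """Read an ipyrad-style ``.loci`` file.

    The dialect: blocks of ``sampleName<whitespace>sequence`` lines, all
    sequences equal length and starting at the same column, terminated by a
    line beginning ``//`` whose annotation marks variable columns with ``*``
    or ``-`` characters (aligned to sequence columns) and ends with
    ``|locusId|``.
    """
    path = Path(path)
    loci: Dict[str, Locus] = {}
    block: List[Tuple[str, str, int]] = []  # (name, seq, column offset)
    block_no = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        if not raw.strip():
            continue
        if raw.startswith("//"):
            block_no += 1
            if not block:
                raise LociParseError(
                    f"{path}:{lineno}: terminator before any sequence line"
                )
            m = _TERMINATOR_ID.search(raw)
            if m and m.group(1):
                locus_id = m.group(1)
                annotation = raw[: m.start()]
            else:
                locus_id = str(block_no - 1)
                annotation = raw
            first_name = block[0][0]
            seq_len = len(block[0][1])
            if any(len(seq) != seq_len for _, seq, _ in block):
                raise LociParseError(
                    f"{path}: locus {locus_id} (block starting with "
                    f"{first_name!r}): unequal sequence lengths"
                )
            offsets = {off for _, _, off in block}
            if len(offsets) > 1:
                raise LociParseError(
                    f"{path}: locus {locus_id}: sequences start at "
                    "inconsistent columns"
                )
            offset = offsets.pop()
            snp_columns = [
                col
                for col in range(seq_len)
                if offset + col < len(annotation)
                and annotation[offset + col] in "*-"
            ]
            locus = Locus(
                locus_id=locus_id,
                sequences={name: seq for name, seq, _ in block},
                snp_columns=snp_columns,
            )
            locus.validate()
            loci[locus_id] = locus
            block = []
            continue
        m = _SEQ_LINE.match(raw)
        if m is None:
            raise LociParseError(f"{path}:{lineno}: not a sequence line: {raw!r}")
        name, _, seq = m.groups()
        block.append((name, seq.upper(), m.start(3)))
    if block:
        raise LociParseError(f"{path}: trailing sequence block without terminator")
    return LociCollection(loci)


def write_loci(lc: LociCollection, path) -> None:
    """Write a ``.loci`` file in the pinned dialect.

    Sample-name padding is derived from the longest name in the collection,
    so write -> read -> write is byte-stable.
    """
    names = [n for locus in lc.loci.values() for n in locus.sequences]
    width = max((len(n) for n in names), default=4) + 4
    lines: List[str] = []
    for locus_id, locus in lc.items():
        for name, seq in locus.sequences.items():
            lines.append(name.ljust(width) + seq)
        marker = [" "] * locus.length
        for col in locus.snp_columns:
            marker[col] = "*"
        lines.append("//".ljust(width) + "".join(marker) + f"|{locus_id}|")
    Path(path).write_text("\n".join(lines) + "\n")
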