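import numpy as np
import pytest

from gbspop.io import VariantDataset, VariantRecord


def make_dataset(samples, rows):
    """Build a VariantDataset from compact genotype rows.

    Each row is ``(contig, pos, ref, alts, calls)`` where calls is a list of
    either ``None`` or ``(a, b)`` tuples.
    """
    records = [
        VariantRecord(
            contig_id=contig,
            pos=pos,
            ref_allele=ref,
            alt_alleles=list(alts),
            genotypes=[None if c is None else tuple(sorted(c)) for c in calls],
        )
        for contig, pos, ref, alts, calls in rows
    ]
    ds = VariantDataset(samples=list(samples), records=records)
    ds.validate()
    return ds


def random_dataset(rng, n_samples, n_sites, missing_rate=0.15, n_contigs=None):
    """A random biallelic dataset with MCAR missingness (for oracle tests)."""
    if n_contigs is None:
        n_contigs = max(1, n_sites // 3)
    samples = [f"s{i:03d}" for i in range(n_samples)]
    rows = []
    positions = {}
    for j in range(n_sites):
        contig = f"c{rng.integers(n_contigs):04d}"
        pos = positions.get(contig, 0) + int(rng.integers(1, 10))
        positions[contig] = pos
        calls = []
        for _ in range(n_samples):
            if rng.random() < missing_rate:
                calls.append(None)
            else:
                d = int(rng.integers(0, 3))
                calls.append({0: (0, 0), 1: (0, 1), 2: (1, 1)}[d])
        rows.append((contig, pos, "A", ["G"], calls))
    return make_dataset(samples, rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
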