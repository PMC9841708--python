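"""Independent brute-force reimplementations used as oracles.

Deliberately written with plain Python loops and no shared code with the
package, so that agreement is evidence rather than tautology.
"""


def bf_individual_missingness(ds, max_missing):
    keep_idx = []
    for i in range(len(ds.samples)):
        n_miss = 0
        for rec in ds.records:
            if rec.genotypes[i] is None:
                n_miss += 1
        if n_miss / len(ds.records) <= max_missing:
            keep_idx.append(i)
    return keep_idx


def bf_site_completeness(ds, min_presence):
    kept = []
    for j, rec in enumerate(ds.records):
        present = 0
        for gt in rec.genotypes:
            if gt is not None:
                present += 1
        if len(ds.samples) > 0 and present / len(ds.samples) >= min_presence:
            kept.append(j)
    return kept


def bf_maf(ds, maf):
    kept = []
    for j, rec in enumerate(ds.records):
        tally = {}
        for gt in rec.genotypes:
            if gt is not None:
                for a in gt:
                    tally[a] = tally.get(a, 0) + 1
        if not tally:
            continue
        if len(tally) < 2:
            freq = 0.0
        else:
            freq = min(tally.values()) / sum(tally.values())
        if freq >= maf:
            kept.append(j)
    return kept


def bf_thin_center(ds, loci=None):
    groups = {}
    for j, rec in enumerate(ds.records):
        groups.setdefault(rec.contig_id, []).append(j)
    kept = []
    for contig, idxs in groups.items():
        if loci is not None and contig in loci:
            center = (loci[contig].length + 1) / 2.0
        else:
            pos = [ds.records[j].pos for j in idxs]
            center = (min(pos) + max(pos)) / 2.0
        best = None
        for j in idxs:
            d = abs(ds.records[j].pos - center)
            if best is None or d < best[0] or (d == best[0] and ds.records[j].pos < best[1]):
                best = (d, ds.records[j].pos, j)
        kept.append(best[2])
    return sorted(kept)


def bf_cascade(ds, cfg, loci=None):
    """Full cascade by brute force; returns (sample ids, site ids)."""
    keep_s = bf_individual_missingness(ds, cfg.max_individual_missing)
    samples = [ds.samples[i] for i in keep_s]
    from gbspop.io import VariantDataset, VariantRecord

    recs = [
        VariantRecord(
            r.contig_id, r.pos, r.ref_allele, list(r.alt_alleles),
            [r.genotypes[i] for i in keep_s],
        )
        for r in ds.records
    ]
    cur = VariantDataset(samples=samples, records=recs)
    cur = VariantDataset(
        samples=samples,
        records=[cur.records[j] for j in bf_site_completeness(cur, cfg.min_site_presence)],
    )
    cur = VariantDataset(
        samples=samples, records=[cur.records[j] for j in bf_maf(cur, cfg.maf)]
    )
    if cfg.thin_to_center:
        cur = VariantDataset(
            samples=samples, records=[cur.records[j] for j in bf_thin_center(cur, loci)]
        )
    return cur.samples, [(r.contig_id, r.pos) for r in cur.records]


def bf_consensus(sequences, focal_col):
    """Per-column tally consensus oracle (majority / IUPAC tie / focal)."""
    iupac = {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "AG": "R", "CT": "Y", "CG": "S", "AT": "W",
        "GT": "K", "AC": "M", "CGT": "B", "AGT": "D",
        "ACT": "H", "ACG": "V", "ACGT": "N",
    }
    expand = {}
    for bases, code in iupac.items():
        expand[code] = set(bases)
    length = len(sequences[0])
    out = []
    focal_out = None
    for col in range(length):
        chars = [s[col].upper() for s in sequences]
        gaps = sum(1 for c in chars if c == "-")
        if gaps * 2 >= len(chars):
            continue
        info = [c for c in chars if c not in "-N"]
        if col == focal_col:
            focal_out = len(out)
        if not info:
            out.append("N")
            continue
        if col == focal_col:
            obs = set()
            for c in info:
                obs |= expand[c]
            out.append(iupac["".join(sorted(obs))])
            continue
        tally = {}
        for c in info:
            tally[c] = tally.get(c, 0) + 1
        top = max(tally.values())
        tied = sorted(c for c, v in tally.items() if v == top)
        if len(tied) == 1:
            out.append(tied[0])
        else:
            union = set()
            for c in tied:
                union |= expand[c]
            out.append(iupac["".join(sorted(union))])
    return "".join(out), focal_out
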