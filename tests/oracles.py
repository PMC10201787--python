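"""Brute-force reference implementations used to cross-check the library.

Every function here recomputes a result by direct enumeration (per-base
scans, pairwise merging to a fixed point, set arithmetic), independent of
the vectorised code paths under test.
"""

from collections import Counter

import numpy as np


def insertions_oracle(fragments, chrom_sizes, shift_mode="none"):
    """(chrom, position) -> count by looping over fragment ends."""
    counts = Counter()
    for chrom, s, e in fragments[["chrom", "start", "end"]].itertuples(index=False):
        size = chrom_sizes[chrom]
        if shift_mode == "none":
            ends = (s, e - 1)
        else:
            ends = (s + 4, e - 6)
        for pos in ends:
            counts[(chrom, min(max(pos, 0), size - 1))] += 1
    return counts


def density_oracle(counts, bin_size, slide):
    """Window heights by summing a per-base array window by window."""
    heights = []
    for start in range(0, len(counts), slide):
        heights.append(int(sum(counts[start : start + bin_size])))
    return heights


def merge_oracle(intervals, max_gap):
    """Pairwise merging to a fixed point; returns sorted (start, end) tuples."""
    work = sorted((int(s), int(e)) for s, e in intervals)
    changed = True
    while changed:
        changed = False
        for i in range(len(work) - 1):
            (s1, e1), (s2, e2) = work[i], work[i + 1]
            if s2 - e1 < max_gap:
                work[i : i + 2] = [(min(s1, s2), max(e1, e2))]
                changed = True
                break
    return work


def covered_fraction_oracle(query, subjects):
    """Fraction of query bases covered by any subject, per-base set scan."""
    chrom, qs, qe = query
    covered = set()
    for sc, ss, se in subjects[["chrom", "start", "end"]].itertuples(index=False):
        if sc != chrom:
            continue
        covered |= set(range(max(qs, ss), min(qe, se)))
    return len(covered) / (qe - qs)


def partition_counts_oracle(a, b, min_fraction=0.10):
    def n_shared(queries, subjects):
        n = 0
        for chrom, qs, qe in queries[["chrom", "start", "end"]].itertuples(index=False):
            if covered_fraction_oracle((chrom, qs, qe), subjects) >= min_fraction:
                n += 1
        return n

    sa = n_shared(a, b)
    sb = n_shared(b, a)
    return {"shared_a": sa, "only_a": len(a) - sa, "shared_b": sb, "only_b": len(b) - sb}


def category_oracle(annotation, chrom, pos, flank=2000):
    """Category of one base by scanning all gene models with explicit rules."""
    in_exon = in_gene = in_up = in_down = False
    for _, g in annotation.genes.iterrows():
        if g.chrom != chrom:
            continue
        if g.start <= pos < g.end:
            in_gene = True
        if g.strand == "+":
            up = (g.start - flank, g.start)
            down = (g.end, g.end + flank)
        else:
            up = (g.end, g.end + flank)
            down = (g.start - flank, g.start)
        if up[0] <= pos < up[1]:
            in_up = True
        if down[0] <= pos < down[1]:
            in_down = True
    for _, e in annotation.exons.iterrows():
        if e.chrom == chrom and e.start <= pos < e.end:
            in_exon = True
    if in_exon:
        return "exon"
    if in_gene:
        return "intron"
    if in_up:
        return "up2k"
    if in_down:
        return "down2k"
    return "intergenic"


def upstream_profile_oracle(track, annotation, genes, span):
    """Per-offset mean insertion count by per-gene, per-offset lookup."""
    sums = np.zeros(span)
    ns = np.zeros(span)
    meta = annotation.genes.set_index("gene_id")
    for gid in genes:
        g = meta.loc[gid]
        arr = track.counts[g.chrom]
        tss = g.start if g.strand == "+" else g.end - 1
        for u in range(1, span + 1):
            pos = tss - u if g.strand == "+" else tss + u
            if 0 <= pos < arr.size:
                sums[u - 1] += arr[pos]
                ns[u - 1] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(ns > 0, sums / np.maximum(ns, 1), 0.0)
    return out
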