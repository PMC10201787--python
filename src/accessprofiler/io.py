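"""Readers and writers for the standard text formats the pipeline consumes.

All on-disk coordinates follow the native convention of each format:
BED/narrowPeak/bedGraph are 0-based half-open (used as-is), GFF3 is
1-based inclusive and converted on read/write. Writers emit deterministic,
sorted output so identical inputs give byte-identical files.
"""

from __future__ import annotations

import os
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .insertion import DensityTrack, InsertionTrack
from .peaks import as_peakset

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "peak",
]


# -- GFF3 ---------------------------------------------------------------------

def write_gff3(annotation: GenomeAnnotation, path) -> None:
    lines = ["##gff-version 3"]
    for chrom in sorted(annotation.chrom_sizes):
        lines.append(f"##sequence-region {chrom} 1 {annotation.chrom_sizes[chrom]}")
    exons_by_gene = {gid: grp for gid, grp in annotation.exons.groupby("gene_id", sort=False)}
    genes = annotation.genes.sort_values(["chrom", "start", "gene_id"], kind="mergesort")
    for _, g in genes.iterrows():
        base = (g.chrom, "accessprofiler", g.start + 1, g.end, g.strand)
        lines.append(_gff_line(*base, "gene", ".", f"ID={g.gene_id}"))
        lines.append(_gff_line(*base, "mRNA", ".", f"ID={g.gene_id}.1;Parent={g.gene_id}"))
        grp = exons_by_gene.get(g.gene_id)
        if grp is not None:
            for k, (_, e) in enumerate(grp.sort_values("start").iterrows(), start=1):
                lines.append(
                    _gff_line(
                        g.chrom, "accessprofiler", e.start + 1, e.end, g.strand,
                        "exon", ".", f"ID={g.gene_id}.1.exon{k};Parent={g.gene_id}.1",
                    )
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _gff_line(chrom, source, start, end, strand, ftype, phase, attrs) -> str:
    return f"{chrom}\t{source}\t{ftype}\t{start}\t{end}\t.\t{strand}\t{phase}\t{attrs}"


def read_gff3(path) -> GenomeAnnotation:
    """Parse gene models from GFF3 via gffutils (in-memory DB).

    Chromosome sizes come from ``##sequence-region`` directives; for
    chromosomes lacking one, the maximum feature end is used.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    chrom_sizes: Dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            chrom_sizes[parts[1]] = int(parts[3])
    genes, exons = [], []
    for g in db.features_of_type("gene"):
        genes.append((g.id, g.seqid, g.start - 1, g.end, g.strand))
        for e in db.children(g, featuretype="exon", order_by="start"):
            exons.append((g.id, e.seqid, e.start - 1, e.end))
        chrom_sizes.setdefault(g.seqid, 0)
        chrom_sizes[g.seqid] = max(chrom_sizes[g.seqid], g.end)
    return GenomeAnnotation(
        chrom_sizes=chrom_sizes,
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"]),
        exons=pd.DataFrame(exons, columns=["gene_id", "chrom", "start", "end"]),
    )


# -- fragments (BED) ----------------------------------------------------------

def write_fragments_bed(fragments: pd.DataFrame, path) -> None:
    """6-column BED, one line per fragment (read pair)."""
    df = fragments.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    with open(path, "w") as fh:
        for i, row in enumerate(df.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tfrag_{i + 1}\t0\t.\n")


def read_fragments_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
    df.columns = ["chrom", "start", "end"]
    return df.astype({"start": np.int64, "end": np.int64})


# -- peaks (narrowPeak / BED) ---------------------------------------------------

def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    peaks = as_peakset(peaks)
    with open(path, "w") as fh:
        for row in peaks.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t{row.score:g}"
                f"\t.\t0\t-1\t-1\t-1\n"
            )


def read_peaks(path) -> pd.DataFrame:
    """Read narrowPeak or plain BED into a peak DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns=dict(enumerate(["chrom", "start", "end", "name", "score"])))
    keep = [c for c in ["chrom", "start", "end", "name", "score"] if c in df.columns]
    return as_peakset(df[keep])


def write_bed(intervals: pd.DataFrame, path, name_col: str = "name") -> None:
    """Generic 4+ column BED writer (chrom, start, end, name[, score])."""
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            name = getattr(row, name_col, ".")
            score = getattr(row, "score", 0)
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t{score:g}\n")


# -- tracks (bedGraph) ----------------------------------------------------------

def write_bedgraph(track: InsertionTrack, path) -> None:
    """Per-base insertion counts as run-length bedGraph; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.counts):
            arr = track.counts[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def read_bedgraph(path, chrom_sizes: Mapping[str, int]) -> InsertionTrack:
    track = InsertionTrack.zeros(chrom_sizes)
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    for row in df.itertuples(index=False):
        arr = track.counts.get(row.chrom)
        if arr is None:
            raise ValueError(f"bedGraph chromosome {row.chrom!r} not in chrom_sizes")
        arr[int(row.start) : int(row.end)] += int(row.value)
    return track


def write_density_bedgraph(density: DensityTrack, path) -> None:
    """Density bars as bedGraph over each bar's centre slice (IGV-loadable)."""
    with open(path, "w") as fh:
        for chrom in sorted(density.bars):
            for row in density.bars[chrom].itertuples(index=False):
                if row.height != 0:
                    fh.write(f"{chrom}\t{row.center_start}\t{row.center_end}\t{row.height}\n")


# -- expression (TSV) ------------------------------------------------------------

def write_expression_tsv(expression: pd.DataFrame, path) -> None:
    expression.sort_index().to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if (df < 0).any().any():
        raise ValueError("negative FPKM in expression table")
    return df
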