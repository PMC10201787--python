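"""Gene annotation model and peak-to-feature assignment.

The genome is represented as chromosome sizes plus simple gene models
(one transcript per gene: transcript interval, strand, exon intervals).
All coordinates are 0-based half-open; GFF3 is converted on read/write.

Peaks are assigned to one of five mutually exclusive genomic categories
-- exon, intron, up2k (<2 kb upstream of the TSS), down2k (<2 kb
downstream of the TTS) and intergenic -- by the category of their
midpoint base. Where several genes claim a base, transcribed state wins:
exon > intron > up2k > down2k > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Reserved names for organellar contigs; excluded from "nuclear" statistics.
ORGANELLE_CHROMS = frozenset({"chrPt", "chrMt"})

#: Category names in display order.
CATEGORIES = ("exon", "intron", "up2k", "down2k", "intergenic")

# uint8 codes; higher code = higher precedence when painting the index.
_CODE = {"intergenic": 0, "down2k": 1, "up2k": 2, "intron": 3, "exon": 4}
_NAME = {v: k for k, v in _CODE.items()}

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
EXON_COLUMNS = ["gene_id", "chrom", "start", "end"]


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus gene models (source of TSS/TTS coordinates).

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp.
    genes
        DataFrame with columns ``gene_id, chrom, start, end, strand``
        (0-based half-open transcript interval, strand '+'/'-').
    exons
        DataFrame with columns ``gene_id, chrom, start, end``; every gene
        has at least one exon, exons lie within the transcript.
    """

    chrom_sizes: Dict[str, int]
    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS))
    exons: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EXON_COLUMNS))

    def __post_init__(self) -> None:
        self.genes = pd.DataFrame(self.genes, columns=GENE_COLUMNS).reset_index(drop=True)
        self.exons = pd.DataFrame(self.exons, columns=EXON_COLUMNS).reset_index(drop=True)
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {size}")
        if len(self.genes):
            if self.genes["gene_id"].duplicated().any():
                raise ValueError("duplicate gene ids in annotation")
            if not self.genes["strand"].isin(["+", "-"]).all():
                raise ValueError("gene strand must be '+' or '-'")
            for _, g in self.genes.iterrows():
                size = self.chrom_sizes.get(g.chrom)
                if size is None:
                    raise ValueError(f"gene {g.gene_id!r} on unknown chromosome {g.chrom!r}")
                if not (0 <= g.start < g.end <= size):
                    raise ValueError(f"gene {g.gene_id!r} interval [{g.start},{g.end}) out of bounds")
        if len(self.exons):
            bounds = self.genes.set_index("gene_id")
            for _, e in self.exons.iterrows():
                g = bounds.loc[e.gene_id]
                if not (g.start <= e.start < e.end <= g.end):
                    raise ValueError(f"exon [{e.start},{e.end}) outside gene {e.gene_id!r}")

    # -- derived coordinates -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def nuclear_chroms(self) -> list[str]:
        return [c for c in self.chrom_sizes if c not in ORGANELLE_CHROMS]

    def nuclear_length(self) -> int:
        return sum(self.chrom_sizes[c] for c in self.nuclear_chroms())

    def tss(self) -> pd.Series:
        """First transcribed base per gene (strand-aware), indexed by gene_id."""
        g = self.genes
        pos = np.where(g["strand"].to_numpy() == "+", g["start"].to_numpy(), g["end"].to_numpy() - 1)
        return pd.Series(pos, index=g["gene_id"].to_numpy(), name="tss")

    def tts(self) -> pd.Series:
        """Last transcribed base per gene (strand-aware), indexed by gene_id."""
        g = self.genes
        pos = np.where(g["strand"].to_numpy() == "+", g["end"].to_numpy() - 1, g["start"].to_numpy())
        return pd.Series(pos, index=g["gene_id"].to_numpy(), name="tts")


@dataclass
class CategoryIndex:
    """Base-resolution lookup mapping every genomic position to one category.

    ``labels[chrom][pos]`` is a uint8 code; the index partitions the genome,
    so per-category base totals sum to the genome length.
    """

    labels: Dict[str, np.ndarray]
    flank: int

    def category_at(self, chrom: str, pos: int) -> str:
        arr = self.labels.get(chrom)
        if arr is None:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < arr.size):
            raise ValueError(f"position {pos} outside {chrom!r} (length {arr.size})")
        return _NAME[int(arr[pos])]

    def base_totals(self) -> Dict[str, int]:
        totals = {c: 0 for c in CATEGORIES}
        for arr in self.labels.values():
            counts = np.bincount(arr, minlength=5)
            for code, n in enumerate(counts):
                totals[_NAME[code]] += int(n)
        return totals


def build_category_index(annotation: GenomeAnnotation, flank: int = 2000) -> CategoryIndex:
    """Label every base exon/intron/up2k/down2k/intergenic.

    Painted in increasing precedence (down2k, up2k, gene body as intron,
    exons last) so at bases claimed by several genes the transcribed state
    wins and upstream flanks beat downstream flanks.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    labels = {c: np.zeros(size, dtype=np.uint8) for c, size in annotation.chrom_sizes.items()}

    def paint(chrom: str, start: int, end: int, code: int) -> None:
        arr = labels[chrom]
        s, e = max(0, start), min(arr.size, end)
        if s < e:
            arr[s:e] = code

    genes = annotation.genes
    for _, g in genes.iterrows():  # down2k layer
        if g.strand == "+":
            paint(g.chrom, g.end, g.end + flank, _CODE["down2k"])
        else:
            paint(g.chrom, g.start - flank, g.start, _CODE["down2k"])
    for _, g in genes.iterrows():  # up2k layer
        if g.strand == "+":
            paint(g.chrom, g.start - flank, g.start, _CODE["up2k"])
        else:
            paint(g.chrom, g.end, g.end + flank, _CODE["up2k"])
    for _, g in genes.iterrows():  # gene body
        paint(g.chrom, g.start, g.end, _CODE["intron"])
    for _, e in annotation.exons.iterrows():
        paint(e.chrom, e.start, e.end, _CODE["exon"])
    return CategoryIndex(labels=labels, flank=flank)


def classify_peak(peak, index: CategoryIndex) -> str:
    """Category of a peak's midpoint base, floor((start+end)/2)."""
    chrom, start, end = peak[0], int(peak[1]), int(peak[2])
    return index.category_at(chrom, (start + end) // 2)


def category_distribution(peaks: pd.DataFrame, index: CategoryIndex) -> Dict[str, float]:
    """Proportion of peaks per category; proportions over the 5 categories sum to 1."""
    if len(peaks) == 0:
        raise ValueError("empty peak set: category distribution undefined")
    counts = {c: 0 for c in CATEGORIES}
    mids = ((peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2).astype(np.int64)
    for chrom, mid in zip(peaks["chrom"], mids):
        counts[index.category_at(chrom, int(mid))] += 1
    n = len(peaks)
    return {c: counts[c] / n for c in CATEGORIES}


def closest_gene(peak, annotation: GenomeAnnotation) -> tuple[str, int]:
    """Gene minimising interval-to-interval distance to the peak (0 if overlapping).

    Ties are broken by the lexicographically smaller gene id. Only genes on
    the peak's chromosome are comparable; none there is an error.
    """
    chrom, pstart, pend = peak[0], int(peak[1]), int(peak[2])
    g = annotation.genes
    if len(g) == 0:
        raise ValueError("annotation contains no genes")
    sub = g[g["chrom"] == chrom]
    if len(sub) == 0:
        raise ValueError(f"no genes on chromosome {chrom!r}")
    gs = sub["start"].to_numpy()
    ge = sub["end"].to_numpy()
    dist = np.maximum(np.maximum(gs - pend, pstart - ge), 0)
    order = sorted(zip(dist, sub["gene_id"]))
    d, gid = order[0]
    return str(gid), int(d)


@dataclass
class GeneClassAssignment:
    """Closest-gene mapping of two peak classes and the exclusive gene sets.

    ``a_only`` holds genes whose associated peaks are all in the first class,
    ``shared_only`` those with all peaks in the second; genes hit by both
    classes are ``mixed`` and excluded from downstream enrichment tests.
    """

    peak_to_gene: pd.DataFrame  # chrom, start, end, peak_class, gene_id, distance
    a_only: frozenset
    shared_only: frozenset
    mixed: frozenset


def exclusive_gene_classes(
    only_a_peaks: pd.DataFrame,
    shared_peaks: pd.DataFrame,
    annotation: GenomeAnnotation,
) -> GeneClassAssignment:
    """Mutually exclusive gene classes from two peak classes via closest genes."""
    rows = []
    sets: dict[str, set] = {"A": set(), "shared": set()}
    for label, peaks in (("A", only_a_peaks), ("shared", shared_peaks)):
        for _, p in peaks.iterrows():
            gid, d = closest_gene((p.chrom, p.start, p.end), annotation)
            sets[label].add(gid)
            rows.append((p.chrom, int(p.start), int(p.end), label, gid, d))
    mixed = sets["A"] & sets["shared"]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_class", "gene_id", "distance"])
    return GeneClassAssignment(
        peak_to_gene=df,
        a_only=frozenset(sets["A"] - mixed),
        shared_only=frozenset(sets["shared"] - mixed),
        mixed=frozenset(mixed),
    )
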