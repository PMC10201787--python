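"""Accessibility versus gene expression.

Expressed genes (FPKM > 0) are split into ten rank deciles, with a
separate group 0 for silent genes. For each group, the mean per-base
insertion count over the 1 kb upstream of the TSS is normalised by the
genome-wide per-base rate to give fold accessibility over background;
a LOESS curve summarises each profile. Per-gene accessibility is also
totalled in a 150 bp window centred 225 bp upstream of the TSS (upstream
offset u=1 is the base immediately 5' of the TSS, so the default window
covers offsets 151-300) and correlated with FPKM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .annotation import GenomeAnnotation
from .insertion import InsertionTrack


@dataclass
class QuantileStratification:
    """11 ordered gene groups: group 0 = FPKM 0; groups 1-10 = expressed deciles."""

    groups: list  # list of 11 lists of gene ids, group 10 = highest expression
    tissue: str

    def __post_init__(self) -> None:
        assert len(self.groups) == 11

    def group_of(self) -> Dict[str, int]:
        return {gid: q for q, genes in enumerate(self.groups) for gid in genes}

    def sizes(self) -> list[int]:
        return [len(g) for g in self.groups]


def stratify_quantiles(expression: pd.DataFrame, tissue: str) -> QuantileStratification:
    """Rank-based decile split of FPKM>0 genes; FPKM=0 genes form group 0.

    Ties are broken by gene id so the partition is deterministic; decile
    sizes differ by at most one.
    """
    if len(expression) == 0:
        raise ValueError("empty expression table")
    if tissue not in expression.columns:
        raise ValueError(f"tissue {tissue!r} not in expression table")
    fpkm = expression[tissue]
    if (fpkm < 0).any():
        raise ValueError("negative FPKM")
    zero = sorted(fpkm.index[fpkm == 0].tolist())
    expressed = fpkm[fpkm > 0]
    if len(expressed) == 0:
        warnings.warn("no expressed genes: deciles 1-10 are empty")
        return QuantileStratification(groups=[zero] + [[] for _ in range(10)], tissue=tissue)
    order = expressed.rename_axis("gene_id").reset_index().sort_values(
        [tissue, "gene_id"], kind="mergesort"
    )
    ranked = order["gene_id"].tolist()
    deciles = [list(chunk) for chunk in np.array_split(np.asarray(ranked, dtype=object), 10)]
    return QuantileStratification(groups=[zero] + deciles, tissue=tissue)


@dataclass
class AggregateProfile:
    """Mean insertion count per upstream offset over a gene group.

    ``offsets`` run 1..span (u=1 immediately 5' of the TSS); ``mean`` is the
    per-offset mean over genes whose offset base lies on the chromosome;
    ``fold`` and ``smoothed`` are filled by fold_over_background / loess_smooth.
    """

    offsets: np.ndarray
    mean: np.ndarray
    n_genes: int
    label: str = ""
    fold: Optional[np.ndarray] = None
    smoothed: Optional[np.ndarray] = None


def _upstream_positions(strand: str, tss: int, offsets: np.ndarray) -> np.ndarray:
    return tss - offsets if strand == "+" else tss + offsets


def upstream_profile(
    track: InsertionTrack,
    annotation: GenomeAnnotation,
    genes: Iterable[str],
    span: int = 1000,
    label: str = "",
) -> AggregateProfile:
    """Per-offset mean insertion count over the span upstream of each TSS.

    Strand-aware: offset u maps to TSS−u on plus-strand genes and TSS+u on
    minus-strand genes. Bases falling off the chromosome are excluded from
    the mean at that offset.
    """
    gene_ids = list(genes)
    if not gene_ids:
        raise ValueError("empty gene group")
    offsets = np.arange(1, span + 1, dtype=np.int64)
    sums = np.zeros(span, dtype=np.float64)
    denom = np.zeros(span, dtype=np.int64)
    meta = annotation.genes.set_index("gene_id")
    tss = annotation.tss()
    for gid in gene_ids:
        g = meta.loc[gid]
        arr = track.counts[g.chrom]
        pos = _upstream_positions(g.strand, int(tss.loc[gid]), offsets)
        valid = (pos >= 0) & (pos < arr.size)
        sums[valid] += arr[pos[valid]]
        denom += valid
    mean = np.divide(sums, denom, out=np.zeros_like(sums), where=denom > 0)
    return AggregateProfile(offsets=offsets, mean=mean, n_genes=len(gene_ids), label=label)


def fold_over_background(profile: AggregateProfile, track: InsertionTrack) -> AggregateProfile:
    """Divide each per-offset mean by the genome-wide per-base insertion rate.

    The background uses nuclear chromosomes only, so organellar
    contamination does not deflate the fold values.
    """
    if track.total_insertions == 0:
        raise ValueError("empty track: background rate undefined")
    rate = track.background_rate()
    if rate == 0:
        raise ValueError("zero nuclear insertions: background rate undefined")
    profile.fold = profile.mean / rate
    return profile


def loess_smooth(x: Sequence[float], y: Sequence[float], span: float = 0.3) -> np.ndarray:
    """Tricube-weighted local linear regression evaluated at the input x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points for LOESS")
    if int(np.floor(span * x.size)) < 2:
        raise ValueError(f"span {span} too small: local windows hold fewer than 2 points")
    return lowess(y, x, frac=span, it=0, return_sorted=False)


def window_accessibility(
    track: InsertionTrack,
    annotation: GenomeAnnotation,
    gene_id: str,
    center_offset: int = 225,
    width: int = 150,
) -> int:
    """Total insertions in a width-bp window centred center_offset bp upstream of the TSS.

    Covers upstream offsets [center_offset − width/2 + 1, center_offset + width/2]
    (151-300 for the defaults); off-chromosome bases contribute 0.
    """
    g = annotation.genes.set_index("gene_id").loc[gene_id]
    tss = int(annotation.tss().loc[gene_id])
    lo = center_offset - width // 2 + 1
    hi = center_offset + width // 2
    arr = track.counts[g.chrom]
    if g.strand == "+":
        s, e = tss - hi, tss - lo + 1
    else:
        s, e = tss + lo, tss + hi + 1
    s, e = max(0, s), min(arr.size, e)
    return int(arr[s:e].sum()) if s < e else 0


def window_accessibility_table(
    track: InsertionTrack,
    annotation: GenomeAnnotation,
    center_offset: int = 225,
    width: int = 150,
) -> pd.Series:
    """window_accessibility for every annotated gene, indexed by gene id."""
    gids = annotation.genes["gene_id"].tolist()
    vals = [window_accessibility(track, annotation, g, center_offset, width) for g in gids]
    return pd.Series(vals, index=gids, name="window_insertions")


def expression_correlation(
    windows: Mapping[str, float] | pd.Series,
    expression: Mapping[str, float] | pd.Series,
    log_transform: bool = False,
) -> tuple[float, float]:
    """Pearson correlation between per-gene window accessibility and FPKM.

    Raw values by default; ``log_transform`` applies log10(x+1) to both
    sides. Requires >= 3 paired genes and non-constant vectors.
    """
    w = pd.Series(windows, dtype=float)
    f = pd.Series(expression, dtype=float)
    common = w.index.intersection(f.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired genes")
    x = w.loc[common].to_numpy()
    y = f.loc[common].to_numpy()
    if log_transform:
        x = np.log10(x + 1)
        y = np.log10(y + 1)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Pearson correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def heatmap_matrix(
    track: InsertionTrack,
    annotation: GenomeAnnotation,
    expression: pd.Series | Mapping[str, float],
    flank: int = 1000,
    body_bins: int = 20,
    bin_size: int = 150,
    slide: int = 20,
) -> pd.DataFrame:
    """Per-gene accessibility heatmap: upstream flank + scaled body + downstream flank.

    One row per gene ordered by descending expression (ties by gene id);
    columns are sliding bin_size/slide windows over [TSS−flank, TSS], then
    body_bins equal slices of the gene body, then [TTS, TTS+flank], all
    oriented 5'→3'. Values are log10(count + 1).
    """
    fpkm = pd.Series(expression, dtype=float)
    gids = [g for g in annotation.genes["gene_id"] if g in fpkm.index]
    order = sorted(gids, key=lambda g: (-fpkm.loc[g], g))
    meta = annotation.genes.set_index("gene_id")
    n_flank_windows = (flank - bin_size) // slide + 1
    cols = (
        [f"up_{i}" for i in range(n_flank_windows)]
        + [f"body_{i}" for i in range(body_bins)]
        + [f"down_{i}" for i in range(n_flank_windows)]
    )
    rows = []
    for gid in order:
        g = meta.loc[gid]
        arr = track.counts[g.chrom]

        def oriented(s: int, e: int) -> np.ndarray:
            out = np.zeros(e - s, dtype=np.int64)
            cs, ce = max(0, s), min(arr.size, e)
            if cs < ce:
                out[cs - s : ce - s] = arr[cs:ce]
            return out if g.strand == "+" else out[::-1]

        if g.strand == "+":
            up = oriented(g.start - flank, g.start)
            body = oriented(g.start, g.end)
            down = oriented(g.end, g.end + flank)
        else:
            up = oriented(g.end, g.end + flank)
            body = oriented(g.start, g.end)
            down = oriented(g.start - flank, g.start)

        def windows(vec: np.ndarray) -> list[int]:
            cs = np.concatenate(([0], np.cumsum(vec)))
            starts = np.arange(n_flank_windows) * slide
            return list(cs[np.minimum(starts + bin_size, vec.size)] - cs[starts])

        slices = [int(chunk.sum()) for chunk in np.array_split(body, body_bins)]
        rows.append(windows(up) + slices + windows(down))
    mat = np.log10(np.asarray(rows, dtype=float) + 1) if rows else np.zeros((0, len(cols)))
    return pd.DataFrame(mat, index=order, columns=cols)
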