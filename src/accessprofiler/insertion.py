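"""Per-base Tn5 insertion tracks and derived statistics.

Each aligned fragment (read pair) marks two Tn5 insertion sites: its two
ends. This module turns fragment intervals into per-base insertion counts,
renders browser-style sliding-window density tracks, and computes two QC
quantities: the organellar read fraction and the SPOT score (Signal
Portion Of Tags — the fraction of insertion events falling inside peaks).

Fragments are DataFrames with columns ``chrom, start, end`` in 0-based
half-open coordinates. Counts are stored densely per chromosome, which is
the right trade-off for the megabase-scale genomes this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from .annotation import ORGANELLE_CHROMS

FRAGMENT_COLUMNS = ["chrom", "start", "end"]


@dataclass
class InsertionTrack:
    """Per-chromosome per-base counts of Tn5 insertion events."""

    counts: Dict[str, np.ndarray]

    @classmethod
    def zeros(cls, chrom_sizes: Mapping[str, int]) -> "InsertionTrack":
        return cls({c: np.zeros(int(n), dtype=np.int64) for c, n in chrom_sizes.items()})

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {c: int(a.size) for c, a in self.counts.items()}

    @property
    def total_insertions(self) -> int:
        return int(sum(a.sum() for a in self.counts.values()))

    @property
    def genome_length(self) -> int:
        return int(sum(a.size for a in self.counts.values()))

    def nuclear_chroms(self) -> list[str]:
        return [c for c in self.counts if c not in ORGANELLE_CHROMS]

    def nuclear_insertions(self) -> int:
        return int(sum(self.counts[c].sum() for c in self.nuclear_chroms()))

    def nuclear_length(self) -> int:
        return int(sum(self.counts[c].size for c in self.nuclear_chroms()))

    def background_rate(self) -> float:
        """Genome-wide per-base insertion rate over nuclear chromosomes."""
        length = self.nuclear_length()
        if length == 0:
            raise ValueError("track has no nuclear chromosomes")
        return self.nuclear_insertions() / length


@dataclass
class DensityTrack:
    """Sliding-histogram bars for genome-browser display.

    Each bar covers the centre ``slide`` bp of a ``bin_size`` window and its
    height is the total insertion count in the full window.
    """

    bars: Dict[str, pd.DataFrame]  # window_start, window_end, center_start, center_end, height
    bin_size: int
    slide: int


def extract_insertions(
    fragments: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    shift_mode: str = "none",
) -> InsertionTrack:
    """Count the two Tn5 insertion sites of every fragment.

    With ``shift_mode='none'`` a fragment (c, s, e) increments positions
    ``s`` and ``e-1``. With ``'tn5_offset'`` the conventional +4/−5 Tn5
    dyad correction is applied (``s+4`` and ``e-6``), clamped to the
    chromosome; clamp collisions still count at the clamped base.
    """
    if shift_mode not in ("none", "tn5_offset"):
        raise ValueError(f"unknown shift_mode {shift_mode!r}")
    track = InsertionTrack.zeros(chrom_sizes)
    if len(fragments) == 0:
        return track
    unknown = set(fragments["chrom"]) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"fragments on unknown chromosome(s): {sorted(unknown)}")
    for chrom, grp in fragments.groupby("chrom", sort=False):
        arr = track.counts[chrom]
        s = grp["start"].to_numpy(dtype=np.int64)
        e = grp["end"].to_numpy(dtype=np.int64)
        if np.any(s >= e):
            raise ValueError("fragment with start >= end")
        if shift_mode == "none":
            left, right = s, e - 1
        else:
            left, right = s + 4, e - 6
        left = np.clip(left, 0, arr.size - 1)
        right = np.clip(right, 0, arr.size - 1)
        np.add.at(arr, left, 1)
        np.add.at(arr, right, 1)
    return track


def density_track(track: InsertionTrack, bin_size: int = 150, slide: int = 20) -> DensityTrack:
    """Sliding histogram of insertion counts (default 150 bp bin, 20 bp slide).

    Windows are anchored at multiples of ``slide`` from coordinate 0 so
    that tracks from different samples are comparable bin-for-bin; windows
    overhanging the chromosome end are truncated for the sum.
    """
    if bin_size <= 0 or slide <= 0:
        raise ValueError("bin_size and slide must be positive")
    if slide > bin_size:
        raise ValueError("slide must not exceed bin_size")
    margin = (bin_size - slide) // 2
    bars: Dict[str, pd.DataFrame] = {}
    for chrom, arr in track.counts.items():
        n = arr.size
        starts = np.arange(0, n, slide, dtype=np.int64)
        csum = np.concatenate(([0], np.cumsum(arr)))
        hi = np.minimum(starts + bin_size, n)
        heights = csum[hi] - csum[starts]
        bars[chrom] = pd.DataFrame(
            {
                "window_start": starts,
                "window_end": starts + bin_size,
                "center_start": starts + margin,
                "center_end": starts + margin + slide,
                "height": heights,
            }
        )
    return DensityTrack(bars=bars, bin_size=bin_size, slide=slide)


def organelle_fraction(alignment_counts: Mapping[str, int]) -> Dict[str, float]:
    """Proportion of reads per reference class (nuclear / plastid / mitochondrial)."""
    total = sum(alignment_counts.values())
    if total <= 0:
        raise ValueError("all-zero alignment counts: fractions undefined")
    if any(v < 0 for v in alignment_counts.values()):
        raise ValueError("negative alignment count")
    return {k: v / total for k, v in alignment_counts.items()}


def spot_score(track: InsertionTrack, peaks: pd.DataFrame) -> float:
    """SPOT score: fraction of insertion events inside the union of peaks."""
    total = track.total_insertions
    if total == 0:
        raise ValueError("empty track: SPOT score undefined")
    if len(peaks) == 0:
        return 0.0
    inside = 0
    for chrom, grp in peaks.groupby("chrom", sort=False):
        arr = track.counts.get(chrom)
        if arr is None:
            continue
        covered = np.zeros(arr.size, dtype=bool)
        for s, e in zip(grp["start"], grp["end"]):
            covered[max(0, int(s)) : min(arr.size, int(e))] = True
        inside += int(arr[covered].sum())
    return inside / total
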