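"""Peak-set hygiene and comparison.

Peaks are DataFrames with columns ``chrom, start, end, name, score``
(0-based half-open), kept sorted by (chrom, start, end). Operations:
merging peaks whose proximal ends are closer than a gap threshold, the
fraction-of-query overlap criterion used to compare two peak sets, the
resulting four-way partition (shared/unique per set), and uniform
down-sampling of fragments to equalise sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd

PEAK_COLUMNS = ["chrom", "start", "end", "name", "score"]


def as_peakset(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and sort a peak DataFrame; fills name/score if absent."""
    df = df.copy()
    if "name" not in df.columns:
        df["name"] = [f"peak_{i}" for i in range(len(df))]
    if "score" not in df.columns:
        df["score"] = 0.0
    df = df[PEAK_COLUMNS]
    if len(df):
        if (df["start"] >= df["end"]).any():
            raise ValueError("peak with start >= end")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(["chrom", "start", "end"]).any():
            raise ValueError("duplicate peak interval")
    return df


def merge_peaks(peaks: pd.DataFrame, max_gap: int = 10) -> pd.DataFrame:
    """Merge peaks whose gap (next.start − prev.end) is strictly below ``max_gap``.

    Merging is transitive; a merged peak spans min(start)..max(end), keeps
    the first member's name and the maximum member score. Overlapping input
    peaks (gap < 0) always merge. Idempotent: the output has all adjacent
    gaps >= max_gap.
    """
    peaks = as_peakset(peaks)
    if len(peaks) <= 1:
        return peaks
    out = []
    for chrom, grp in peaks.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        names = grp["name"].to_numpy()
        scores = grp["score"].to_numpy()
        run_end = np.maximum.accumulate(ends)
        # new group wherever the gap to everything before is >= max_gap
        brk = np.concatenate(([True], starts[1:] - run_end[:-1] >= max_gap))
        gid = np.cumsum(brk) - 1
        for g in range(gid[-1] + 1):
            m = gid == g
            out.append(
                (chrom, int(starts[m].min()), int(ends[m].max()), str(names[m][0]), float(scores[m].max()))
            )
    return as_peakset(pd.DataFrame(out, columns=PEAK_COLUMNS))


def _union_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    ms, me = [], []
    for s, e in zip(starts, ends):
        if me and s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.asarray(ms, dtype=np.int64), np.asarray(me, dtype=np.int64)


def _coverage_within(qs: int, qe: int, ms: np.ndarray, me: np.ndarray) -> int:
    """Bases of [qs, qe) covered by the disjoint intervals (ms, me)."""
    if ms.size == 0:
        return 0
    lo = np.searchsorted(me, qs, side="right")
    hi = np.searchsorted(ms, qe, side="left")
    if lo >= hi:
        return 0
    s = np.maximum(ms[lo:hi], qs)
    e = np.minimum(me[lo:hi], qe)
    return int(np.maximum(e - s, 0).sum())


def overlaps_by_fraction(query, subject_set: pd.DataFrame, min_fraction: float = 0.10) -> bool:
    """True iff the union of subject peaks covers >= min_fraction of the query.

    Union coverage (not best single subject): a query split across two
    subject peaks is biologically one overlap.
    """
    chrom, qs, qe = query[0], int(query[1]), int(query[2])
    if qs >= qe:
        raise ValueError("query with start >= end")
    sub = subject_set[subject_set["chrom"] == chrom]
    if len(sub) == 0:
        return min_fraction <= 0
    ms, me = _union_intervals(sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
    cov = _coverage_within(qs, qe, ms, me)
    return cov / (qe - qs) >= min_fraction


@dataclass
class OverlapPartition:
    """Two-set peak comparison: shared/unique classes per set, with counts.

    Classification is directional and need not be symmetric in counts: a
    peak of A is 'shared' when >= min_fraction of its own length is covered
    by B, and vice versa.
    """

    shared_a: pd.DataFrame
    only_a: pd.DataFrame
    shared_b: pd.DataFrame
    only_b: pd.DataFrame
    min_fraction: float

    @property
    def counts(self) -> Dict[str, int]:
        return {
            "shared_a": len(self.shared_a),
            "only_a": len(self.only_a),
            "shared_b": len(self.shared_b),
            "only_b": len(self.only_b),
        }


def _classify(queries: pd.DataFrame, subjects: pd.DataFrame, min_fraction: float) -> np.ndarray:
    unions = {
        chrom: _union_intervals(g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64))
        for chrom, g in subjects.groupby("chrom", sort=False)
    }
    flags = np.zeros(len(queries), dtype=bool)
    for i, (chrom, qs, qe) in enumerate(zip(queries["chrom"], queries["start"], queries["end"])):
        ms_me = unions.get(chrom)
        if ms_me is None:
            continue
        cov = _coverage_within(int(qs), int(qe), *ms_me)
        flags[i] = cov / (int(qe) - int(qs)) >= min_fraction
    return flags


def partition_peak_sets(
    a: pd.DataFrame, b: pd.DataFrame, min_fraction: float = 0.10
) -> OverlapPartition:
    """Partition each peak set by the >=10%-of-own-length overlap criterion."""
    a = as_peakset(a)
    b = as_peakset(b)
    fa = _classify(a, b, min_fraction)
    fb = _classify(b, a, min_fraction)
    return OverlapPartition(
        shared_a=a[fa].reset_index(drop=True),
        only_a=a[~fa].reset_index(drop=True),
        shared_b=b[fb].reset_index(drop=True),
        only_b=b[~fb].reset_index(drop=True),
        min_fraction=min_fraction,
    )


def downsample_fragments(fragments: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Uniform random subset of min(n, |fragments|) fragments, without replacement."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= len(fragments):
        return fragments.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(fragments), size=n, replace=False)
    sub = fragments.iloc[np.sort(idx)]
    return sub.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
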