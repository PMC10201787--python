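import numpy as np
import pandas as pd
import pytest

from accessprofiler import GenomeAnnotation, InsertionTrack
from accessprofiler.peaks import as_peakset


@pytest.fixture
def small_annotation():
    """Two chromosomes, three gene models covering both strands."""
    genes = pd.DataFrame(
        [
            ("g1", "chr1", 1000, 2000, "+"),
            ("g2", "chr1", 4000, 5000, "-"),
            ("g3", "chr2", 3000, 3600, "+"),
        ],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    exons = pd.DataFrame(
        [
            ("g1", "chr1", 1000, 1300),
            ("g1", "chr1", 1600, 2000),
            ("g2", "chr1", 4000, 5000),
            ("g3", "chr2", 3000, 3200),
            ("g3", "chr2", 3400, 3600),
        ],
        columns=["gene_id", "chrom", "start", "end"],
    )
    return GenomeAnnotation(chrom_sizes={"chr1": 10000, "chr2": 8000}, genes=genes, exons=exons)


@pytest.fixture
def empty_track():
    return InsertionTrack.zeros({"chr1": 10000, "chr2": 8000})


def make_peaks(intervals, chrom="chr1"):
    """Peak DataFrame from (start, end) pairs or (chrom, start, end) triples."""
    rows = []
    for iv in intervals:
        if len(iv) == 2:
            rows.append((chrom, iv[0], iv[1]))
        else:
            rows.append(tuple(iv))
    return as_peakset(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def make_fragments(triples):
    return pd.DataFrame(triples, columns=["chrom", "start", "end"])


def random_peaks(rng, n, chroms=("c1",), lo=0, hi=500, max_len=60):
    rows = []
    seen = set()
    while len(rows) < n:
        chrom = chroms[rng.integers(0, len(chroms))]
        s = int(rng.integers(lo, hi - 1))
        e = int(s + rng.integers(1, max_len))
        e = min(e, hi)
        if e <= s or (chrom, s, e) in seen:
            continue
        seen.add((chrom, s, e))
        rows.append((chrom, s, e))
    return as_peakset(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
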