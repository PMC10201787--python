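"""Synthetic genomes, expression tables, ATAC fragments and peak pairs.

The generator emulates the statistical structure the downstream analyses
assume: uniform background Tn5 insertions, promoter hotspots (150 bp,
centred 225 bp upstream of each TSS) whose excess rate over background
grows with the gene's expression quantile, a configurable organellar
contamination fraction carried on reserved contigs (chrPt, chrMt), and
two peak sets with a controlled shared fraction under the >=10%-overlap
criterion. Ground truth is returned for parameter-recovery tests.

A single global seed drives documented per-generator substreams
(annotation=0, expression=1, fragments=2, peaks=3), so regenerating one
output does not perturb the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .annotation import ORGANELLE_CHROMS, GenomeAnnotation
from .expression import stratify_quantiles

#: Organellar contig sizes used when organelle_fraction > 0 (approximate
#: plastid / mitochondrial genome sizes).
ORGANELLE_SIZES = {"chrPt": 135_000, "chrMt": 450_000}

_STREAM = {"annotation": 0, "expression": 1, "fragments": 2, "peaks": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[stream]])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Defaults describe a 1 Mb single-chromosome genome with 500 genes,
    ~8% organellar contamination and an 83% shared-peak fraction; the
    hotspot geometry (150 bp centred 225 bp upstream of the TSS) matches
    the accessibility structure the profiling analyses look for.
    """

    chrom_sizes: Dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    n_genes: int = 500
    gene_length_range: Tuple[int, int] = (400, 1200)
    flank_min: int = 600
    background_rate: float = 0.01
    hotspot_center_offset: int = 225
    hotspot_width: int = 150
    hotspot_intensity_per_quantile: Tuple[float, ...] = (
        0.0, 0.5, 1.0, 1.5, 2.5, 3.5, 5.0, 6.5, 8.0, 10.0, 12.0,
    )
    organelle_fraction: float = 0.08
    shared_peak_fraction: float = 0.83
    fragment_length_range: Tuple[int, int] = (50, 300)
    n_peaks: int = 150
    peak_length_range: Tuple[int, int] = (200, 800)
    zero_inflation: float = 0.3
    lognorm_mu: float = 1.0
    lognorm_sigma: float = 1.5
    enriched_fraction: float = 0.15
    enriched_fold: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        for rng_name in ("gene_length_range", "fragment_length_range", "peak_length_range"):
            lo, hi = getattr(self, rng_name)
            if not (0 < lo <= hi):
                raise ValueError(f"{rng_name} must satisfy 0 < min <= max")
        plo, phi = self.peak_length_range
        if phi > 5 * plo:
            raise ValueError("peak_length_range max must be <= 5x min (overlap construction)")
        if self.flank_min < 0:
            raise ValueError("flank_min must be non-negative")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")
        if self.hotspot_center_offset <= 0 or self.hotspot_width <= 0:
            raise ValueError("hotspot geometry must be positive")
        ints = tuple(float(x) for x in self.hotspot_intensity_per_quantile)
        if len(ints) != 11:
            raise ValueError("hotspot_intensity_per_quantile must have exactly 11 entries")
        if any(b < a for a, b in zip(ints, ints[1:])) or any(x < 0 for x in ints):
            raise ValueError("hotspot intensities must be non-negative and non-decreasing")
        self.hotspot_intensity_per_quantile = ints
        if not (0 <= self.organelle_fraction < 1):
            raise ValueError("organelle_fraction must lie in [0, 1)")
        if not (0 <= self.shared_peak_fraction <= 1):
            raise ValueError("shared_peak_fraction must lie in [0, 1]")
        if not (0 <= self.zero_inflation <= 1):
            raise ValueError("zero_inflation must lie in [0, 1]")
        if not (0 <= self.enriched_fraction <= 1):
            raise ValueError("enriched_fraction must lie in [0, 1]")
        if self.enriched_fold <= 0:
            raise ValueError("enriched_fold must be positive")

    def nuclear_chrom_sizes(self) -> Dict[str, int]:
        return {c: s for c, s in self.chrom_sizes.items() if c not in ORGANELLE_CHROMS}

    def all_chrom_sizes(self) -> Dict[str, int]:
        """Nuclear chromosomes plus organellar contigs when contamination is on."""
        sizes = dict(self.nuclear_chrom_sizes())
        if self.organelle_fraction > 0:
            for c, s in ORGANELLE_SIZES.items():
                sizes.setdefault(c, self.chrom_sizes.get(c, s))
        return sizes

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("gene_length_range", "fragment_length_range", "peak_length_range",
                    "hotspot_intensity_per_quantile"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class SimulationTruth:
    """Ground truth of a simulation, for parameter-recovery tests."""

    hotspots: Optional[pd.DataFrame] = None  # gene_id, chrom, start, end, quantile, intensity, truncated
    nuclear_fragments: int = 0
    organelle_fragments: int = 0
    peak_labels_a: Optional[np.ndarray] = None  # True where the A peak has a shared partner
    peak_labels_b: Optional[np.ndarray] = None  # True where the B peak was built shared

    @property
    def organelle_fraction_realized(self) -> float:
        total = self.nuclear_fragments + self.organelle_fragments
        return self.organelle_fragments / total if total else 0.0


def generate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Pack non-overlapping gene models onto the nuclear chromosomes.

    Genes are apportioned to chromosomes by length (largest remainder),
    adjacent genes are separated by at least ``flank_min`` bp (also kept
    clear of chromosome ends), leftover space is spread over the gaps
    multinomially, and strands are sampled uniformly. Every gene carries
    1-3 exons. Deterministic under a fixed seed.
    """
    rng = _rng(config.seed, "annotation")
    sizes = config.all_chrom_sizes()
    nuclear = config.nuclear_chrom_sizes()
    if config.n_genes == 0:
        return GenomeAnnotation(chrom_sizes=sizes)
    if not nuclear:
        raise ValueError("no nuclear chromosomes to place genes on")

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    # largest-remainder apportionment of genes to chromosomes
    total_len = sum(nuclear.values())
    quotas = {c: config.n_genes * s / total_len for c, s in nuclear.items()}
    alloc = {c: int(math.floor(q)) for c, q in quotas.items()}
    leftover = config.n_genes - sum(alloc.values())
    for c in sorted(nuclear, key=lambda c: (-(quotas[c] - alloc[c]), c))[:leftover]:
        alloc[c] += 1

    genes, exons = [], []
    gi = 0
    for chrom in nuclear:
        k = alloc[chrom]
        if k == 0:
            continue
        chrom_len = nuclear[chrom]
        lens = lengths[gi : gi + k]
        need = int(lens.sum()) + (k + 1) * config.flank_min
        if need > chrom_len:
            raise ValueError(
                f"infeasible packing on {chrom!r}: {k} genes need {need} bp "
                f"(gene lengths {int(lens.sum())} + spacing {(k + 1) * config.flank_min}) "
                f"but chromosome is {chrom_len} bp"
            )
        slack = chrom_len - need
        extra = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
        pos = 0
        for j in range(k):
            pos += config.flank_min + int(extra[j])
            gid = f"gene_{gi + j + 1:05d}"
            start, end = pos, pos + int(lens[j])
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            genes.append((gid, chrom, start, end, strand))
            exons.extend(_make_exons(rng, gid, chrom, start, end))
            pos = end
        gi += k

    return GenomeAnnotation(
        chrom_sizes=sizes,
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"]),
        exons=pd.DataFrame(exons, columns=["gene_id", "chrom", "start", "end"]),
    )


def _make_exons(rng: np.random.Generator, gid: str, chrom: str, start: int, end: int) -> list:
    length = end - start
    n_ex = 1 if length < 300 else int(rng.integers(1, 4))
    if n_ex == 1:
        return [(gid, chrom, start, end)]
    segments = 2 * n_ex - 1  # exon/intron alternation, exons at both ends
    min_seg = 30
    extra = rng.multinomial(length - min_seg * segments, np.full(segments, 1.0 / segments))
    seg_lens = min_seg + extra
    out, pos = [], start
    for i, sl in enumerate(seg_lens):
        if i % 2 == 0:
            out.append((gid, chrom, pos, pos + int(sl)))
        pos += int(sl)
    return out


def generate_expression(
    annotation: GenomeAnnotation, config: SimulationConfig, n_tissues: int = 2
) -> tuple[pd.DataFrame, frozenset]:
    """Zero-inflated log-normal FPKM per tissue, plus designed tissue-enriched genes.

    A fraction ``enriched_fraction`` of genes expressed in the first tissue
    is forced to be at least ``enriched_fold``-times higher there than in
    the second tissue. Returns the table (genes x tissues) and the set of
    gene ids made enriched by construction.
    """
    if n_tissues < 1:
        raise ValueError("n_tissues must be at least 1")
    if annotation.n_genes == 0:
        raise ValueError("annotation has no genes")
    rng = _rng(config.seed, "expression")
    gids = annotation.genes["gene_id"].tolist()
    names = (["root", "leaf"] + [f"tissue_{i}" for i in range(3, n_tissues + 1)])[:n_tissues]
    n = len(gids)
    data = {}
    for t in names:
        vals = rng.lognormal(config.lognorm_mu, config.lognorm_sigma, size=n)
        vals[rng.random(n) < config.zero_inflation] = 0.0
        data[t] = vals
    table = pd.DataFrame(data, index=pd.Index(gids, name="gene_id"))

    enriched: frozenset = frozenset()
    if n_tissues >= 2 and config.enriched_fraction > 0:
        target, other = names[0], names[1]
        candidates = table.index[table[target] > 0].to_numpy()
        k = int(round(config.enriched_fraction * candidates.size))
        if k > 0:
            chosen = rng.choice(candidates, size=k, replace=False)
            floor = np.maximum(table.loc[chosen, other].to_numpy(), 0.1)
            table.loc[chosen, target] = config.enriched_fold * floor * rng.uniform(1.0, 3.0, size=k)
            enriched = frozenset(str(g) for g in chosen)
    return table, enriched


def _hotspot_interval(strand: str, tss: int, offset: int, width: int) -> tuple[int, int]:
    half = width // 2
    if strand == "+":
        return tss - offset - half, tss - offset + width - half
    return tss + offset - half + 1, tss + offset + width - half + 1


def simulate_fragments(
    annotation: GenomeAnnotation,
    expression: pd.DataFrame,
    config: SimulationConfig,
    tissue: Optional[str] = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw paired-end fragments from a background + promoter-hotspot rate field.

    Per-base insertion events follow an inhomogeneous Poisson law: rate
    ``background_rate`` everywhere, raised to ``background x (1 + intensity)``
    inside each gene's hotspot window, with the intensity taken from the
    gene's expression quantile. Each fragment contributes exactly two
    insertion ends: one drawn from the rate field, its mate at a uniform
    fragment length away in a random direction (clamped to the chromosome).
    A fraction of fragments lands on the organellar contigs.
    """
    if annotation.n_genes > 0 and len(expression):
        tissue = tissue or str(expression.columns[0])
        qmap = stratify_quantiles(expression, tissue).group_of()
    else:
        qmap = {}
    rng = _rng(config.seed, "fragments")
    intensities = config.hotspot_intensity_per_quantile
    lo_f, hi_f = config.fragment_length_range

    nuclear = {c: s for c, s in annotation.chrom_sizes.items() if c not in ORGANELLE_CHROMS}
    rates = {c: np.full(s, config.background_rate, dtype=np.float64) for c, s in nuclear.items()}
    tss = annotation.tss()
    hot_rows = []
    for _, g in annotation.genes.iterrows():
        q = qmap.get(g.gene_id, 0)
        inten = intensities[q]
        s, e = _hotspot_interval(g.strand, int(tss.loc[g.gene_id]), config.hotspot_center_offset, config.hotspot_width)
        size = nuclear[g.chrom]
        cs = max(0, s)
        ce = max(cs, min(size, e))
        truncated = (cs, ce) != (s, e)
        if cs < ce:
            np.maximum(rates[g.chrom][cs:ce], config.background_rate * (1.0 + inten), out=rates[g.chrom][cs:ce])
        hot_rows.append((g.gene_id, g.chrom, cs, ce, q, inten, truncated))
    hotspots = pd.DataFrame(
        hot_rows, columns=["gene_id", "chrom", "start", "end", "quantile", "intensity", "truncated"]
    )

    frames = []
    n_nuclear = 0
    for chrom, rate in rates.items():
        lam = float(rate.sum())
        n_frag = int(rng.poisson(lam)) // 2 if lam > 0 else 0
        if n_frag == 0:
            continue
        cdf = np.cumsum(rate)
        anchors = np.searchsorted(cdf, rng.random(n_frag) * cdf[-1], side="right")
        frames.append(_pair_ends(rng, chrom, anchors, rate.size, lo_f, hi_f))
        n_nuclear += n_frag

    n_org = 0
    if config.organelle_fraction > 0 and n_nuclear > 0:
        f = config.organelle_fraction
        n_org = int(rng.binomial(int(round(n_nuclear / (1.0 - f))), f))
        if n_org > 0:
            org_sizes = {c: s for c, s in annotation.chrom_sizes.items() if c in ORGANELLE_CHROMS}
            names = list(org_sizes)
            weights = np.array([org_sizes[c] for c in names], dtype=float)
            choice = rng.choice(len(names), size=n_org, p=weights / weights.sum())
            for i, c in enumerate(names):
                m = int((choice == i).sum())
                if m:
                    anchors = rng.integers(0, org_sizes[c], size=m)
                    frames.append(_pair_ends(rng, c, anchors, org_sizes[c], lo_f, hi_f))

    if frames:
        fragments = pd.concat(frames, ignore_index=True)
        fragments = fragments.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    else:
        fragments = pd.DataFrame(columns=["chrom", "start", "end"])
    truth = SimulationTruth(hotspots=hotspots, nuclear_fragments=n_nuclear, organelle_fragments=n_org)
    return fragments, truth


def _pair_ends(
    rng: np.random.Generator, chrom: str, anchors: np.ndarray, size: int, lo: int, hi: int
) -> pd.DataFrame:
    lengths = rng.integers(lo, hi + 1, size=anchors.size)
    signs = rng.integers(0, 2, size=anchors.size) * 2 - 1
    mates = np.clip(anchors + signs * lengths, 0, size - 1)
    starts = np.minimum(anchors, mates)
    ends = np.maximum(anchors, mates) + 1
    return pd.DataFrame({"chrom": chrom, "start": starts.astype(np.int64), "end": ends.astype(np.int64)})


def simulate_peak_pair(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Two peak sets with a controlled shared fraction.

    Each B peak is independently labelled shared with probability
    ``shared_peak_fraction``. Shared B peaks overlap a distinct A peak by at
    least 20% of both peaks' lengths (comfortably above the 10% criterion);
    unique peaks of either set are placed in disjoint slots so their
    cross-set overlap is exactly zero.
    """
    from .peaks import as_peakset

    rng = _rng(config.seed, "peaks")
    n = config.n_peaks
    lo, hi = config.peak_length_range
    slot_w = 3 * hi
    nuclear = {c: s for c, s in annotation.chrom_sizes.items() if c not in ORGANELLE_CHROMS}
    slots = [(c, i * slot_w) for c in nuclear for i in range(nuclear[c] // slot_w)]
    if n == 0:
        empty = as_peakset(pd.DataFrame(columns=["chrom", "start", "end", "name", "score"]))
        return empty, empty.copy(), SimulationTruth(
            peak_labels_a=np.zeros(0, bool), peak_labels_b=np.zeros(0, bool)
        )

    shared = rng.random(n) < config.shared_peak_fraction
    n_unique_b = int((~shared).sum())
    needed = n + n_unique_b
    if needed > len(slots):
        raise ValueError(
            f"insufficient genome for peak layout: need {needed} slots of {slot_w} bp "
            f"but only {len(slots)} fit on the nuclear chromosomes"
        )
    chosen = rng.choice(len(slots), size=needed, replace=False)
    a_slots = [slots[i] for i in chosen[:n]]
    b_slots = [slots[i] for i in chosen[n:]]

    len_a = rng.integers(lo, hi + 1, size=n)
    a_rows = []
    for i, (chrom, s0) in enumerate(a_slots):
        start = s0 + hi + int(rng.integers(0, hi - len_a[i] + 1))
        a_rows.append((chrom, start, start + int(len_a[i]), f"A_{i + 1:05d}", float(rng.uniform(10, 1000))))

    partners = rng.permutation(n)[: int(shared.sum())]
    has_partner = np.zeros(n, dtype=bool)
    b_rows = []
    pi = ui = 0
    for j in range(n):
        lb = int(rng.integers(lo, hi + 1))
        score = float(rng.uniform(10, 1000))
        if shared[j]:
            ai = int(partners[pi])
            pi += 1
            has_partner[ai] = True
            chrom, a_start, a_end = a_rows[ai][0], a_rows[ai][1], a_rows[ai][2]
            la = a_end - a_start
            o_min = max(int(math.ceil(0.2 * max(la, lb))), 1)
            o_max = min(la, lb)
            o = int(rng.integers(o_min, o_max + 1))
            start = a_start + o - lb
        else:
            chrom, s0 = b_slots[ui]
            ui += 1
            start = s0 + hi + int(rng.integers(0, hi - lb + 1))
        b_rows.append((chrom, start, start + lb, f"B_{j + 1:05d}", score))

    cols = ["chrom", "start", "end", "name", "score"]
    df_a = pd.DataFrame(a_rows, columns=cols)
    df_a["_shared"] = has_partner
    df_a = df_a.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    df_b = pd.DataFrame(b_rows, columns=cols)
    df_b["_shared"] = shared
    df_b = df_b.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    truth = SimulationTruth(
        peak_labels_a=df_a.pop("_shared").to_numpy(),
        peak_labels_b=df_b.pop("_shared").to_numpy(),
    )
    return as_peakset(df_a), as_peakset(df_b), truth
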