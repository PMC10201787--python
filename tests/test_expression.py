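"""Quantile stratification, upstream profiles, LOESS, windows, correlation, heatmaps."""

import numpy as np
import pandas as pd
import pytest

from accessprofiler import (
    GenomeAnnotation,
    InsertionTrack,
    expression_correlation,
    fold_over_background,
    heatmap_matrix,
    loess_smooth,
    stratify_quantiles,
    upstream_profile,
    window_accessibility,
    window_accessibility_table,
)
from oracles import upstream_profile_oracle


def expr_table(values, tissue="root"):
    return pd.DataFrame({tissue: values}, index=[f"g{i:03d}" for i in range(len(values))])


def one_gene_annotation(strand="+", start=1000, end=2000, size=10000):
    genes = pd.DataFrame(
        [("g1", "chr1", start, end, strand)], columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    exons = pd.DataFrame([("g1", "chr1", start, end)], columns=["gene_id", "chrom", "start", "end"])
    return GenomeAnnotation(chrom_sizes={"chr1": size}, genes=genes, exons=exons)


class TestStratifyQuantiles:
    def test_twenty_distinct_genes_make_ten_pairs(self):
        strat = stratify_quantiles(expr_table(np.arange(1.0, 21.0)), "root")
        assert strat.sizes() == [0] + [2] * 10
        assert set(strat.groups[10]) == {"g018", "g019"}

    def test_all_zero_goes_to_group_zero(self):
        with pytest.warns(UserWarning):
            strat = stratify_quantiles(expr_table([0.0] * 8), "root")
        assert strat.sizes() == [8] + [0] * 10

    def test_group_sizes_differ_by_at_most_one(self):
        strat = stratify_quantiles(expr_table(np.linspace(0.5, 50, 95)), "root")
        sizes = strat.sizes()[1:]
        assert max(sizes) - min(sizes) <= 1 and sum(sizes) == 95

    def test_groups_partition_the_gene_set(self):
        rng = np.random.default_rng(0)
        vals = np.where(rng.random(57) < 0.3, 0.0, rng.lognormal(1, 1, 57))
        strat = stratify_quantiles(expr_table(vals), "root")
        all_ids = [g for grp in strat.groups for g in grp]
        assert sorted(all_ids) == sorted(f"g{i:03d}" for i in range(57))

    def test_ties_broken_deterministically(self):
        a = stratify_quantiles(expr_table([1.0] * 20), "root")
        b = stratify_quantiles(expr_table([1.0] * 20), "root")
        assert a.groups == b.groups

    def test_unknown_tissue_rejected(self):
        with pytest.raises(ValueError, match="tissue"):
            stratify_quantiles(expr_table([1.0]), "leaf")


class TestUpstreamProfile:
    def test_zero_track_gives_zero_profile(self, empty_track):
        ann = one_gene_annotation()
        prof = upstream_profile(empty_track, ann, ["g1"])
        assert prof.mean.sum() == 0

    def test_plus_strand_offset_placement(self):
        ann = one_gene_annotation("+", 1000, 2000)
        track = InsertionTrack.zeros(ann.chrom_sizes)
        track.counts["chr1"][1000 - 225] = 1  # 225 bp upstream of the TSS
        prof = upstream_profile(track, ann, ["g1"])
        assert prof.mean[224] == 1.0 and prof.mean.sum() == 1.0

    def test_minus_strand_offset_placement(self):
        ann = one_gene_annotation("-", 1000, 2000)
        track = InsertionTrack.zeros(ann.chrom_sizes)
        tss = 1999
        track.counts["chr1"][tss + 300] = 1
        prof = upstream_profile(track, ann, ["g1"])
        assert prof.mean[299] == 1.0 and prof.mean.sum() == 1.0

    def test_off_chromosome_bases_excluded_from_mean(self):
        ann = one_gene_annotation("+", 100, 600, size=2000)
        track = InsertionTrack.zeros(ann.chrom_sizes)
        track.counts["chr1"][:100] = 1
        prof = upstream_profile(track, ann, ["g1"], span=1000)
        # offsets 1..100 exist (mean 1); offsets beyond the chromosome contribute no genes
        assert (prof.mean[:100] == 1.0).all()
        assert (prof.mean[100:] == 0.0).all()

    def test_empty_group_is_an_error(self, empty_track):
        with pytest.raises(ValueError):
            upstream_profile(empty_track, one_gene_annotation(), [])

    def test_matches_per_gene_scan_oracle(self, small_annotation):
        rng = np.random.default_rng(21)
        track = InsertionTrack.zeros(small_annotation.chrom_sizes)
        for chrom, arr in track.counts.items():
            arr[:] = rng.poisson(0.05, size=arr.size)
        prof = upstream_profile(track, small_annotation, ["g1", "g2", "g3"], span=500)
        expected = upstream_profile_oracle(track, small_annotation, ["g1", "g2", "g3"], span=500)
        np.testing.assert_allclose(prof.mean, expected)


class TestFoldOverBackground:
    def test_mean_equal_to_background_gives_fold_one(self):
        ann = one_gene_annotation()
        track = InsertionTrack.zeros(ann.chrom_sizes)
        track.counts["chr1"][:] = 1  # rate exactly 1 per bp
        prof = upstream_profile(track, ann, ["g1"])
        prof = fold_over_background(prof, track)
        np.testing.assert_allclose(prof.fold, 1.0)

    def test_fold_arithmetic(self):
        track = InsertionTrack.zeros({"chr1": 1_000_000})
        track.counts["chr1"][:1000] = 1  # 1000 insertions -> background 0.001
        ann = one_gene_annotation(size=1_000_000)
        prof = upstream_profile(track, ann, ["g1"])
        prof.mean = np.full_like(prof.mean, 0.005)
        fold = fold_over_background(prof, track).fold
        np.testing.assert_allclose(fold, 5.0)

    def test_background_excludes_organellar_insertions(self):
        track = InsertionTrack.zeros({"chr1": 1000, "chrPt": 1000})
        track.counts["chr1"][:] = 2
        track.counts["chrPt"][:] = 50  # contamination must not inflate the background
        assert track.background_rate() == 2.0

    def test_empty_track_is_an_error(self, empty_track):
        ann = one_gene_annotation()
        prof = upstream_profile(empty_track, ann, ["g1"])
        with pytest.raises(ValueError):
            fold_over_background(prof, empty_track)


class TestLoessSmooth:
    def test_constant_series_stays_constant(self):
        x = np.arange(50.0)
        np.testing.assert_allclose(loess_smooth(x, np.full(50, 3.7)), 3.7)

    def test_linear_series_is_reproduced_exactly(self):
        x = np.arange(100.0)
        y = 2.5 * x - 7.0
        assert np.abs(loess_smooth(x, y) - y).max() < 1e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loess_smooth(np.arange(5.0), np.arange(5.0))

    def test_span_too_small_rejected(self):
        with pytest.raises(ValueError, match="span"):
            loess_smooth(np.arange(20.0), np.arange(20.0), span=0.05)

    def test_noisy_unimodal_peak_location_recovered(self):
        rng = np.random.default_rng(4)
        x = np.arange(1, 1001, dtype=float)
        y = np.where((x >= 151) & (x <= 300), 6.0, 1.0) + rng.normal(0, 0.5, 1000)
        sm = loess_smooth(x, y, span=0.3)
        assert abs(x[np.argmax(sm)] - 225) <= 20


class TestWindowAccessibility:
    def test_plus_strand_window_interval(self):
        ann = one_gene_annotation("+", 1000, 2000)
        track = InsertionTrack.zeros(ann.chrom_sizes)
        track.counts["chr1"][[700, 849]] = 1  # window [700, 850)
        track.counts["chr1"][[699, 850]] += 1  # just outside
        assert window_accessibility(track, ann, "g1") == 2

    def test_boundary_offsets(self):
        ann = one_gene_annotation("+", 1000, 2000)
        track = InsertionTrack.zeros(ann.chrom_sizes)
        track.counts["chr1"][1000 - 151] = 1  # offset 151: inside
        track.counts["chr1"][1000 - 301] = 1  # offset 301: outside
        assert window_accessibility(track, ann, "g1") == 1

    def test_minus_strand_window(self):
        ann = one_gene_annotation("-", 1000, 2000)
        track = InsertionTrack.zeros(ann.chrom_sizes)
        tss = 1999
        track.counts["chr1"][tss + 151] = 1
        track.counts["chr1"][tss + 300] = 1
        track.counts["chr1"][tss + 301] = 1
        assert window_accessibility(track, ann, "g1") == 2

    def test_zero_track_gives_zero(self, empty_track):
        ann = one_gene_annotation()
        assert window_accessibility(empty_track, ann, "g1") == 0

    def test_off_chromosome_window_contributes_zero(self):
        ann = one_gene_annotation("+", 100, 600, size=2000)
        track = InsertionTrack.zeros(ann.chrom_sizes)
        track.counts["chr1"][:] = 1
        # window offsets 151..300 fall at positions -200..-51: entirely off-chromosome
        assert window_accessibility(track, ann, "g1") == 0

    def test_full_span_window_equals_profile_total(self):
        ann = one_gene_annotation("+", 5000, 6000)
        rng = np.random.default_rng(8)
        track = InsertionTrack.zeros(ann.chrom_sizes)
        track.counts["chr1"][:] = rng.poisson(0.2, size=10000)
        prof = upstream_profile(track, ann, ["g1"], span=1000)
        total = window_accessibility(track, ann, "g1", center_offset=500, width=1000)
        assert total == int(prof.mean.sum())


class TestExpressionCorrelation:
    def test_proportional_gives_r_one(self):
        w = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        assert expression_correlation(w, 3 * w)[0] == pytest.approx(1.0)

    def test_anti_proportional_gives_r_minus_one(self):
        w = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        assert expression_correlation(w, -w + 10)[0] == pytest.approx(-1.0)

    def test_constant_vector_is_an_error(self):
        w = pd.Series([1.0, 1, 1, 1], index=list("abcd"))
        with pytest.raises(ValueError):
            expression_correlation(w, pd.Series([1.0, 2, 3, 4], index=list("abcd")))

    def test_too_few_pairs_is_an_error(self):
        w = pd.Series([1.0, 2], index=list("ab"))
        with pytest.raises(ValueError):
            expression_correlation(w, w)

    def test_log_option_changes_scale_not_sign(self):
        rng = np.random.default_rng(0)
        idx = [f"g{i}" for i in range(100)]
        f = pd.Series(rng.lognormal(1, 1, 100), index=idx)
        w = pd.Series(f * rng.uniform(0.8, 1.2, 100), index=idx)
        r_raw, _ = expression_correlation(w, f)
        r_log, _ = expression_correlation(w, f, log_transform=True)
        assert r_raw > 0 and r_log > 0


class TestHeatmapMatrix:
    def _setup(self):
        genes = pd.DataFrame(
            [("gHi", "chr1", 3000, 4000, "+"), ("gLo", "chr1", 7000, 8000, "+")],
            columns=["gene_id", "chrom", "start", "end", "strand"],
        )
        exons = pd.DataFrame(
            [("gHi", "chr1", 3000, 4000), ("gLo", "chr1", 7000, 8000)],
            columns=["gene_id", "chrom", "start", "end"],
        )
        ann = GenomeAnnotation(chrom_sizes={"chr1": 10000}, genes=genes, exons=exons)
        expr = pd.Series({"gHi": 50.0, "gLo": 1.0})
        return ann, expr

    def test_zero_track_gives_zero_matrix(self, empty_track):
        ann, expr = self._setup()
        track = InsertionTrack.zeros(ann.chrom_sizes)
        mat = heatmap_matrix(track, ann, expr)
        assert (mat.to_numpy() == 0).all()

    def test_log10_of_window_count(self):
        ann, expr = self._setup()
        track = InsertionTrack.zeros(ann.chrom_sizes)
        # 99 insertions at a base covered only by the first upstream window of gHi
        track.counts["chr1"][3000 - 1000 + 5] = 99
        mat = heatmap_matrix(track, ann, expr)
        assert mat.loc["gHi", "up_0"] == pytest.approx(2.0)

    def test_rows_ordered_by_descending_expression(self):
        ann, expr = self._setup()
        track = InsertionTrack.zeros(ann.chrom_sizes)
        mat = heatmap_matrix(track, ann, expr)
        assert list(mat.index) == ["gHi", "gLo"]

    def test_column_layout(self):
        ann, expr = self._setup()
        mat = heatmap_matrix(InsertionTrack.zeros(ann.chrom_sizes), ann, expr, body_bins=10)
        n_flank = (1000 - 150) // 20 + 1
        assert mat.shape[1] == 2 * n_flank + 10
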