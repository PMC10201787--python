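"""End-to-end orchestration: insertions -> density -> peak comparison ->
genomic annotation -> accessibility/expression profiling -> enrichment.

``run_pipeline`` consumes a configuration mapping (paths plus a parameter
block), writes every stage artifact under the output directory and returns
a machine-readable summary. ``demo`` generates a full synthetic dataset
first and then runs the same pipeline on it, so the whole analysis is
exercisable without external data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import io as apio
from .annotation import (
    CATEGORIES,
    ORGANELLE_CHROMS,
    build_category_index,
    category_distribution,
    exclusive_gene_classes,
)
from .enrichment import class_enrichment_test, classify_enrichment
from .expression import (
    expression_correlation,
    fold_over_background,
    loess_smooth,
    stratify_quantiles,
    upstream_profile,
    window_accessibility_table,
    heatmap_matrix,
)
from .insertion import density_track, extract_insertions, organelle_fraction, spot_score
from .peaks import merge_peaks, partition_peak_sets
from .synthetic import (
    SimulationConfig,
    generate_annotation,
    generate_expression,
    simulate_fragments,
    simulate_peak_pair,
)

log = logging.getLogger("accessprofiler")

DEFAULT_PARAMS = {
    "shift_mode": "none",
    "bin_size": 150,
    "slide": 20,
    "max_gap": 10,
    "min_fraction": 0.10,
    "flank": 2000,
    "profile_span": 1000,
    "window_center": 225,
    "window_width": 150,
    "loess_span": 0.3,
    "fold_threshold": 10.0,
    "heatmap_flank": 1000,
    "heatmap_body_bins": 20,
    "tissue": None,
    "other_tissue": None,
}


def config_hash(config: Dict) -> str:
    """Provenance hash over the configuration.

    Input paths contribute their basenames and output directories are
    ignored, so identical analyses hash identically wherever they run.
    """

    def norm(obj):
        if isinstance(obj, dict):
            return {k: (os.path.basename(str(v)) if k.endswith("_path") else norm(v))
                    for k, v in sorted(obj.items()) if not k.endswith("_dir")}
        if isinstance(obj, (list, tuple)):
            return [norm(v) for v in obj]
        return obj

    blob = json.dumps(norm(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _require(config: Dict, key: str) -> str:
    path = config.get(key)
    if not path:
        raise FileNotFoundError(f"missing required input: {key}")
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing required input: {key} ({path})")
    return path


def run_pipeline(config: Dict) -> Dict:
    """Execute all stages; any stage failure aborts naming the stage."""
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    out_dir = config.get("out_dir", ".")
    os.makedirs(out_dir, exist_ok=True)
    summary: Dict = {"config_hash": config_hash(config), "params": params, "stages": {}}

    def stage(name):
        log.info("stage %s: params=%s", name, {k: params[k] for k in sorted(params)})

        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    # ---- load inputs
    annotation = stage("load")(lambda: apio.read_gff3(_require(config, "annotation_path")))
    expression = stage("load")(lambda: apio.read_expression_tsv(_require(config, "expression_path")))
    fragments = stage("load")(lambda: apio.read_fragments_bed(_require(config, "fragments_path")))
    peaks_a = stage("load")(lambda: apio.read_peaks(_require(config, "peaks_a_path")))
    peaks_b = None
    if config.get("peaks_b_path"):
        peaks_b = stage("load")(lambda: apio.read_peaks(_require(config, "peaks_b_path")))

    tissue = params["tissue"] or str(expression.columns[0])
    other = params["other_tissue"] or (
        str(expression.columns[1]) if expression.shape[1] > 1 else None
    )

    # ---- insertions & density
    def _insertions():
        track = extract_insertions(fragments, annotation.chrom_sizes, params["shift_mode"])
        apio.write_bedgraph(track, os.path.join(out_dir, "insertions.bedgraph"))
        dens = density_track(track, params["bin_size"], params["slide"])
        apio.write_density_bedgraph(dens, os.path.join(out_dir, "density.bedgraph"))
        return track

    track = stage("insertions")(_insertions)
    summary["stages"]["insertions"] = {
        "n_fragments": int(len(fragments)),
        "total_insertions": track.total_insertions,
    }

    # ---- organelle fractions
    def _organelle():
        counts = {"nuclear": 0, "plastid": 0, "mitochondrial": 0}
        for chrom, grp in fragments.groupby("chrom"):
            key = {"chrPt": "plastid", "chrMt": "mitochondrial"}.get(chrom, "nuclear")
            counts[key] += len(grp)
        return organelle_fraction(counts) if sum(counts.values()) else {}

    fractions = stage("organelle")(_organelle)
    summary["stages"]["organelle_fractions"] = fractions

    # ---- peak merge / partition / SPOT
    def _peaks():
        a = merge_peaks(peaks_a, params["max_gap"])
        apio.write_narrowpeak(a, os.path.join(out_dir, "peaks_a.merged.narrowPeak"))
        result = {"n_peaks_a": len(a)}
        part = None
        if peaks_b is not None:
            b = merge_peaks(peaks_b, params["max_gap"])
            apio.write_narrowpeak(b, os.path.join(out_dir, "peaks_b.merged.narrowPeak"))
            part = partition_peak_sets(a, b, params["min_fraction"])
            for cls in ("shared_a", "only_a", "shared_b", "only_b"):
                apio.write_narrowpeak(getattr(part, cls), os.path.join(out_dir, f"peaks.{cls}.narrowPeak"))
            counts = part.counts
            pd.Series(counts).to_csv(os.path.join(out_dir, "partition_counts.tsv"), sep="\t", header=False)
            result.update(counts)
            result["n_peaks_b"] = len(b)
            result["shared_b_proportion"] = counts["shared_b"] / max(len(b), 1)
        return a, part, result

    merged_a, partition, peak_summary = stage("peaks")(_peaks)
    summary["stages"]["peaks"] = peak_summary
    summary["stages"]["spot"] = {"spot_score": stage("spot")(lambda: spot_score(track, merged_a))}

    # ---- genomic categories
    def _annotate():
        index = build_category_index(annotation, params["flank"])
        dist = category_distribution(merged_a, index)
        pd.Series(dist).loc[list(CATEGORIES)].to_csv(
            os.path.join(out_dir, "category_distribution.tsv"), sep="\t", header=False
        )
        return dist

    summary["stages"]["categories"] = stage("annotate")(_annotate)

    # ---- accessibility vs expression
    def _profiles():
        strat = stratify_quantiles(expression, tissue)
        rows = []
        group_profiles = {}
        for q, genes in enumerate(strat.groups):
            if not genes:
                continue
            prof = upstream_profile(track, annotation, genes, params["profile_span"], label=f"q{q}")
            prof = fold_over_background(prof, track)
            prof.smoothed = loess_smooth(prof.offsets, prof.fold, params["loess_span"])
            group_profiles[q] = prof
            for u, m, f, s in zip(prof.offsets, prof.mean, prof.fold, prof.smoothed):
                rows.append((q, int(u), m, f, s))
        pd.DataFrame(rows, columns=["quantile", "offset", "mean", "fold", "loess"]).to_csv(
            os.path.join(out_dir, "upstream_profiles.tsv"), sep="\t", index=False
        )

        expressed = [g for q in range(1, 11) for g in strat.groups[q]]
        pooled = fold_over_background(
            upstream_profile(track, annotation, expressed, params["profile_span"], label="expressed"),
            track,
        )
        pooled.smoothed = loess_smooth(pooled.offsets, pooled.fold, params["loess_span"])
        argmax_offset = int(pooled.offsets[int(np.argmax(pooled.smoothed))])

        windows = window_accessibility_table(
            track, annotation, params["window_center"], params["window_width"]
        )
        windows.to_csv(os.path.join(out_dir, "window_accessibility.tsv"), sep="\t", header=True)
        group_means = [float(windows.loc[strat.groups[q]].mean()) for q in range(1, 11) if strat.groups[q]]
        rho = float(stats.spearmanr(np.arange(1, len(group_means) + 1), group_means).statistic)
        r, p = expression_correlation(windows, expression[tissue])
        return strat, argmax_offset, rho, r, p, windows

    strat, argmax_offset, rho, r, p, windows = stage("profile")(_profiles)
    summary["stages"]["profile"] = {
        "tissue": tissue,
        "profile_argmax_offset": argmax_offset,
        "quantile_window_spearman_rho": rho,
        "pearson_r": r,
        "pearson_p": p,
    }

    def _heatmap():
        mat = heatmap_matrix(
            track, annotation, expression[tissue],
            flank=params["heatmap_flank"], body_bins=params["heatmap_body_bins"],
            bin_size=params["bin_size"], slide=params["slide"],
        )
        mat.to_csv(os.path.join(out_dir, "heatmap_matrix.tsv"), sep="\t")
        try:
            from .plotting import plot_heatmap

            plot_heatmap(mat, os.path.join(out_dir, "heatmap.png"))
        except Exception as exc:  # rendering is best-effort; the matrix is the artifact
            log.warning("heatmap rendering skipped: %s", exc)

    stage("heatmap")(_heatmap)

    # ---- tissue-specific enrichment of exclusive peak-gene classes
    enrich_summary: Dict = {}
    if partition is not None and other is not None and annotation.n_genes > 0:
        def _enrich():
            classes = exclusive_gene_classes(partition.only_b, partition.shared_b, annotation)
            labels = classify_enrichment(expression, other, tissue, params["fold_threshold"])
            try:
                res = class_enrichment_test(sorted(classes.a_only), sorted(classes.shared_only), labels)
            except ValueError as exc:
                return {"error": str(exc), "n_class_only": len(classes.a_only),
                        "n_class_shared": len(classes.shared_only)}
            pd.DataFrame(
                res.table, index=["only_b_genes", "shared_genes"], columns=["enriched", "not_enriched"]
            ).to_csv(os.path.join(out_dir, "enrichment_table.tsv"), sep="\t")
            return {
                "chi2": res.chi2,
                "p_value": res.p_value,
                "proportion_only": res.proportion_a,
                "proportion_shared": res.proportion_b,
            }

        enrich_summary = stage("enrich")(_enrich)
    summary["stages"]["enrichment"] = enrich_summary

    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary


def demo(out_dir: str, seed: int = 0, sim_overrides: Optional[Dict] = None) -> Dict:
    """Generate a synthetic dataset and run the full pipeline on it.

    The returned summary carries an extra ``truth`` block with the
    generator's ground-truth parameters for comparison.
    """
    overrides = dict(sim_overrides or {})
    overrides["seed"] = seed
    sim = SimulationConfig(**overrides)
    inputs = os.path.join(out_dir, "inputs")
    os.makedirs(inputs, exist_ok=True)

    annotation = generate_annotation(sim)
    expression, enriched = generate_expression(annotation, sim, n_tissues=2)
    fragments, frag_truth = simulate_fragments(annotation, expression, sim)
    peaks_a, peaks_b, peak_truth = simulate_peak_pair(annotation, sim)

    apio.write_gff3(annotation, os.path.join(inputs, "annotation.gff3"))
    apio.write_expression_tsv(expression, os.path.join(inputs, "expression.tsv"))
    apio.write_fragments_bed(fragments, os.path.join(inputs, "fragments.bed"))
    apio.write_narrowpeak(peaks_a, os.path.join(inputs, "peaks_a.narrowPeak"))
    apio.write_narrowpeak(peaks_b, os.path.join(inputs, "peaks_b.narrowPeak"))
    if frag_truth.hotspots is not None:
        frag_truth.hotspots.to_csv(os.path.join(inputs, "truth_hotspots.tsv"), sep="\t", index=False)

    config = {
        "annotation_path": os.path.join(inputs, "annotation.gff3"),
        "expression_path": os.path.join(inputs, "expression.tsv"),
        "fragments_path": os.path.join(inputs, "fragments.bed"),
        "peaks_a_path": os.path.join(inputs, "peaks_a.narrowPeak"),
        "peaks_b_path": os.path.join(inputs, "peaks_b.narrowPeak"),
        "out_dir": out_dir,
        "params": {},
    }
    summary = run_pipeline(config)
    summary["truth"] = {
        "seed": seed,
        "hotspot_center_offset": sim.hotspot_center_offset,
        "organelle_fraction": sim.organelle_fraction,
        "organelle_fraction_realized": frag_truth.organelle_fraction_realized,
        "shared_peak_fraction": sim.shared_peak_fraction,
        "shared_b_truth_count": int(peak_truth.peak_labels_b.sum()),
        "n_peaks": sim.n_peaks,
        "n_enriched_genes": len(enriched),
    }
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
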