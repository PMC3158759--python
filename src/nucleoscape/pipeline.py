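"""End-to-end orchestration: simulate -> profile -> classify -> differential -> genes -> metaprofile.

``run_pipeline`` drives the whole analysis on a synthetic landscape with a
single seed, writes every stage's output files plus a manifest into the
output directory, and scores the calls against the planted truth.  Each
stage is also importable on its own (and exposed as a CLI subcommand), so
the pipeline can be re-entered from any stage's files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome_io import (ChromSizes, write_chrom_sizes, write_genes, write_tags,
                        write_bedgraph)
from .window_profile import SignalMatrix, make_grid, count_tags, normalize, window_gc, \
    correlate_profiles
from .group_clustering import (cluster_windows, assign_genes, compare_groups,
                               OccupancySegmentation)
from .differential_occupancy import (call_differential, merge_regions, genes_in_regions,
                                     write_calls_tsv, write_regions_bed, DEFAULT_ALPHA)
from .gene_features import (quantify_expression, classify_promoters, find_gene_clusters,
                            expression_breadth, breadth_group_summary)
from .metaprofile import build_profile, compare_profiles
from . import synthetic_data as sim

logger = logging.getLogger("nucleoscape")

__all__ = ["RunConfig", "run_pipeline", "evaluate_against_truth"]


@dataclass
class RunConfig:
    """Reproducible configuration for one end-to-end run."""

    seed: int = 0
    outdir: str = "nucleoscape_run"
    sim: sim.SimConfig = None          # filled from seed if absent
    alpha: float = DEFAULT_ALPHA
    k: int = 2
    min_cluster_run: int = 5
    breadth_threshold: float = 1.0
    phase_offset: int = 50
    metaprofile_span: int = 1000
    metaprofile_bin: int = 5

    def __post_init__(self):
        if self.sim is None:
            self.sim = sim.SimConfig(seed=self.seed)
        elif isinstance(self.sim, dict):
            self.sim = sim.SimConfig(**self.sim)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _boundary_positions(labels: np.ndarray, grid) -> list[int]:
    """Window indices where the label changes (within a chromosome)."""
    cuts = []
    for chrom in grid.chrom_sizes:
        sl = grid.chrom_slice(chrom)
        lab = labels[sl]
        for i in range(1, len(lab)):
            if lab[i] != lab[i - 1]:
                cuts.append(sl.start + i)
    return cuts


def evaluate_against_truth(
    truth: sim.SimTruth,
    segmentation: OccupancySegmentation,
    diff_calls,
    promoter_classes: dict,
    clusters,
    breadth: pd.Series,
    min_cluster_run: int = 5,
) -> dict:
    """Score every stage's calls against the planted truth.

    Window labels are matched to truth up to a label permutation (k-means
    cluster identity is arbitrary); everything else is compared directly.
    """
    out: dict = {}
    # window labels, optimal matching over the label permutation
    true_lab = truth.window_label
    pred_lab = segmentation.labels
    if true_lab.shape != pred_lab.shape:
        raise ValueError("truth/prediction window dimension mismatch")
    acc = float(np.mean(pred_lab == true_lab))
    out["window_label_accuracy"] = max(acc, 1.0 - acc)

    # block boundaries: distance from each true change-point to nearest called one
    true_cuts = _boundary_positions(true_lab, truth.grid)
    pred_cuts = _boundary_positions(pred_lab, truth.grid)
    if true_cuts and pred_cuts:
        pc = np.array(pred_cuts)
        dists = [int(np.min(np.abs(pc - c))) for c in true_cuts]
        out["block_boundary_error_median"] = float(np.median(dists))
        out["block_boundary_error_max"] = float(np.max(dists))
    else:
        out["block_boundary_error_median"] = float("nan")
        out["block_boundary_error_max"] = float("nan")

    # differential windows
    sig = np.array([c.significant for c in diff_calls])
    direction = np.array([c.direction for c in diff_calls], dtype=object)
    flagged = truth.diff_flag
    correct_dir = np.where(truth.diff_direction == "A", "A-enriched",
                           np.where(truth.diff_direction == "B", "B-enriched", "none"))
    hit = sig & flagged & (direction == correct_dir)
    out["differential_recall"] = float(hit[flagged].mean()) if flagged.any() else float("nan")
    out["differential_fpr"] = float(sig[~flagged].mean()) if (~flagged).any() else float("nan")

    # promoter classes
    if promoter_classes:
        pred = {g: promoter_classes[g].cls for g in promoter_classes}
        ids = [g for g in truth.gene_class if g in pred]
        out["promoter_class_accuracy"] = float(
            np.mean([pred[g] == truth.gene_class[g] for g in ids]))
    # clusters: planted runs >= min_run recovered with exact membership.
    # Scored twice: from the promoter classes as called (end-to-end) and from
    # the true classes (isolates the run-caller itself).
    planted = [tuple(ids) for _, ids in truth.gene_class_runs
               if len(ids) >= min_cluster_run]
    called = [c.gene_ids for c in clusters]
    if planted:
        out["cluster_recovery"] = float(np.mean([ids in called for ids in planted]))
        out["cluster_spurious"] = int(sum(ids not in planted for ids in called))
        from .gene_features import find_gene_clusters
        called_true = [c.gene_ids for c in
                       find_gene_clusters(truth.genes, truth.gene_class,
                                          min_run=min_cluster_run)]
        out["cluster_recovery_true_classes"] = float(
            np.mean([ids in called_true for ids in planted]))
        out["cluster_spurious_true_classes"] = int(
            sum(ids not in planted for ids in called_true))
    # breadth classes
    if truth.gene_breadth_class and breadth is not None:
        nt = truth.config.n_tissues_breadth
        hk_pred = breadth >= nt - 1
        hk_true = pd.Series({g: c == "HK" for g, c in truth.gene_breadth_class.items()})
        hk_true = hk_true.loc[breadth.index]
        out["breadth_hk_recall"] = float(hk_pred[hk_true].mean())
        out["breadth_ts_specificity"] = float((~hk_pred[~hk_true]).mean())
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a simulated landscape; write outputs + manifest; return results."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    logger.addHandler(handler)
    timings: dict[str, float] = {}

    def tick(stage):
        timings[stage] = round(time.time() - t0 - sum(timings.values()), 3)
        logger.info("stage %s done (%.2fs)", stage, timings[stage])

    try:
        cfg = config.sim
        rng_base = config.seed

        # --- simulate ---------------------------------------------------
        truth = sim.simulate_landscape(cfg)
        genes = sim.simulate_genes_and_promoters(truth,
                                                 promoter_fasta=outdir / "promoters.fa")
        sim.simulate_genome_fasta(truth, outdir / "genome.fa")
        tags_no = {t: sim.simulate_tags(truth, "NO", t, seed=rng_base * 10 + i)
                   for i, t in enumerate(("A", "B"))}
        # technical replicate of tissue A: same truth, independent sampling
        tags_no_rep = sim.simulate_tags(truth, "NO", "A", seed=rng_base * 10 + 5)
        tags_rna = {t: sim.simulate_tags(truth, "RNA", t, seed=rng_base * 10 + 2 + i)
                    for i, t in enumerate(("A", "B"))}
        write_chrom_sizes(truth.chrom_sizes, outdir / "chrom.sizes")
        write_genes(genes, outdir / "genes.refflat")
        for t, tg in {**{f"NO_{k}": v for k, v in tags_no.items()},
                      **{f"RNA_{k}": v for k, v in tags_rna.items()}}.items():
            write_tags(tg, outdir / f"tags_{t}.bed")
        truth.write(outdir)
        breadth_panel = sim.simulate_breadth_panel(truth)
        breadth_panel.to_csv(outdir / "breadth_panel.tsv", sep="\t")
        tick("simulate")

        # --- profile ----------------------------------------------------
        grid = truth.grid
        samples, channels, libs, cols = [], [], [], []
        raw_counts = {}
        for name, tg, channel in [("NO_A", tags_no["A"], "NO"), ("NO_B", tags_no["B"], "NO"),
                                  ("RNA_A", tags_rna["A"], "RNA"), ("RNA_B", tags_rna["B"], "RNA")]:
            counts, lib = count_tags(grid, tg)
            raw_counts[name] = counts
            cols.append(normalize(counts, lib))
            samples.append(name); channels.append(channel); libs.append(lib)
        matrix = SignalMatrix(grid, np.column_stack(cols), samples, channels, libs)
        matrix.write_tsv(outdir / "signal_matrix.tsv")
        for name in samples:
            write_bedgraph(grid, matrix.column(name), outdir / f"track_{name}.bedgraph")
        import pyfaidx
        fasta = pyfaidx.Fasta(str(outdir / "genome.fa"))
        gc = window_gc(grid, fasta)
        rep_counts, rep_lib = count_tags(grid, tags_no_rep)
        r_rep, p_rep = correlate_profiles(matrix.column("NO_A"),
                                          normalize(rep_counts, rep_lib))
        r_cross, p_cross = correlate_profiles(matrix.column("NO_A"), matrix.column("NO_B"))
        r_gc, p_gc = correlate_profiles(gc, matrix.column("NO_A"))
        tick("profile")

        # --- classify ---------------------------------------------------
        segmentation = cluster_windows(matrix, k=config.k, seed=config.seed)
        segmentation.write_labels(outdir / "window_labels.tsv")
        segmentation.write_blocks_bed(outdir / "blocks.bed")
        assignment = assign_genes(genes, segmentation)
        pd.Series(assignment, name="group").rename_axis("gene_id").to_csv(
            outdir / "gene_groups.tsv", sep="\t")
        tick("classify")

        # --- differential -----------------------------------------------
        calls = call_differential(grid, raw_counts["NO_A"], raw_counts["NO_B"],
                                  libs[0], libs[1], alpha=config.alpha)
        regions = merge_regions(grid, calls)
        write_calls_tsv(calls, outdir / "differential_windows.tsv")
        write_regions_bed(regions, outdir / "differential_regions.bed")
        tick("differential")

        # --- genes ------------------------------------------------------
        expr = {t: quantify_expression(genes, tags_rna[t]) for t in ("A", "B")}
        region_genes = genes_in_regions(regions, genes, expr["A"], expr["B"])
        region_genes.to_csv(outdir / "region_genes.tsv", sep="\t", index=False)
        promoter_classes = classify_promoters(genes, fasta)
        pred_classes = {g: pc.cls for g, pc in promoter_classes.items()}
        clusters = find_gene_clusters(genes, pred_classes, min_run=config.min_cluster_run)
        breadth = expression_breadth(breadth_panel, threshold=config.breadth_threshold)
        breadth_summary = breadth_group_summary(breadth, assignment, cfg.n_tissues_breadth)
        no_density = {}
        for g in genes:
            wid = grid.window_id(g.chrom, g.tss)
            no_density[g.gene_id] = matrix.column("NO_A")[wid]
        group_stats = compare_groups(assignment,
                                     {"expression": expr["A"], "occupancy": no_density})
        gene_table = pd.DataFrame({
            "gene_id": [g.gene_id for g in genes],
            "group": [assignment[g.gene_id] for g in genes],
            "promoter_class": [pred_classes[g.gene_id] for g in genes],
            "cpg_oe": [promoter_classes[g.gene_id].cpg_oe for g in genes],
            "expr_A": [expr["A"][g.gene_id] for g in genes],
            "expr_B": [expr["B"][g.gene_id] for g in genes],
            "breadth": [int(breadth[g.gene_id]) for g in genes],
        })
        gene_table.to_csv(outdir / "gene_table.tsv", sep="\t", index=False)
        tick("genes")

        # --- metaprofile ------------------------------------------------
        hog_genes = [g for g in genes if assignment[g.gene_id] == "HOG"]
        log_genes = [g for g in genes if assignment[g.gene_id] == "LOG"]
        phased = sim.simulate_phased_tags(hog_genes or genes, truth.chrom_sizes,
                                          phase_offset=config.phase_offset,
                                          seed=rng_base * 10 + 7)
        fuzzy = sim.simulate_phased_tags(log_genes or genes, truth.chrom_sizes,
                                         reads_per_gene=0.0, background_rate=25.0,
                                         seed=rng_base * 10 + 8)
        profiles = {}
        for anchor in ("TSS", "TTS"):
            profiles[("HOG", anchor)] = build_profile(
                hog_genes or genes, phased, anchor,
                span=config.metaprofile_span, bin_width=config.metaprofile_bin)
            profiles[("LOG", anchor)] = build_profile(
                log_genes or genes, fuzzy, anchor,
                span=config.metaprofile_span, bin_width=config.metaprofile_bin)
            profiles[("HOG", anchor)].write_tsv(outdir / f"metaprofile_HOG_{anchor}.tsv")
            profiles[("LOG", anchor)].write_tsv(outdir / f"metaprofile_LOG_{anchor}.tsv")
        contrast = compare_profiles(profiles[("HOG", "TSS")], profiles[("LOG", "TSS")])
        tss_prof = profiles[("HOG", "TSS")]
        peak_offset = float(tss_prof.bin_centers()[int(np.argmax(tss_prof.bins))])
        tick("metaprofile")

        # --- evaluate ---------------------------------------------------
        metrics = evaluate_against_truth(truth, segmentation, calls, promoter_classes,
                                         clusters, breadth, config.min_cluster_run)
        metrics.update({
            "replicate_no_r": r_rep, "replicate_no_p": p_rep,
            "cross_tissue_no_r": r_cross, "cross_tissue_no_p": p_cross,
            "gc_no_r": r_gc, "gc_no_p": p_gc,
            "group_expression_ranksum_p": float(
                group_stats.loc[group_stats.measure == "expression", "ranksum_p"].iloc[0]),
            "hog_median_expression": float(group_stats.query(
                "measure == 'expression' and group == 'HOG'")["median"].iloc[0]),
            "log_median_expression": float(group_stats.query(
                "measure == 'expression' and group == 'LOG'")["median"].iloc[0]),
            "frac_windows_differential": float(np.mean([c.significant for c in calls])),
            "n_differential_regions": len(regions),
            "frac_region_genes_expr_concordant": (
                float(region_genes["expr_concordant"].mean())
                if len(region_genes) else float("nan")),
            "metaprofile_peak_offset": peak_offset,
            "metaprofile_peak_to_flank_hog": contrast["peak_to_flank_a"],
            "metaprofile_peak_to_flank_log": contrast["peak_to_flank_b"],
        })
        with open(outdir / "evaluation.json", "w") as fh:
            json.dump(metrics, fh, indent=2)
        breadth_summary.to_csv(outdir / "breadth_summary.tsv", sep="\t", index=False)
        group_stats.to_csv(outdir / "group_stats.tsv", sep="\t", index=False)
        tick("evaluate")

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "timings_s": timings,
            "checksums": {p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return {"truth": truth, "matrix": matrix, "segmentation": segmentation,
                "calls": calls, "regions": regions, "promoter_classes": promoter_classes,
                "clusters": clusters, "breadth": breadth, "metrics": metrics,
                "profiles": profiles, "manifest": manifest}
    finally:
        logger.removeHandler(handler)
        handler.close()
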