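"""End-to-end orchestration on synthetic or user-provided inputs.

`run_all` executes every enabled stage with fixed seeds, writing
machine-readable results (JSON + TSV, each stamped with the configuration
hash) into an append-only run directory. `make_demo` materializes a small
synthetic fixture set with its ground-truth file.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qio
from .atac import annotate_peaks, enhancer_fc_summary, mark_fraction_by_class, pc_loading_select
from .config import RunConfig
from .decomposition import classify_global_change, cluster_summaries, kmeans_stratify, ma_summary
from .expression import MarkExpressionModel, build_delta_matrix, phi_association
from .genome import FeatureWindowSpec
from .relacs import RelacsBarcodeScheme, epz_retention, global_scale, local_log2fc
from .simulate import (
    TruthConfig,
    emit_barcoded_reads,
    generate_genome,
    simulate_atac_counts,
    simulate_chip_counts,
    simulate_expression,
    simulate_segmentation,
    simulate_state_expression,
)
from .states import Segmentation, VaryingInterceptModel, select_tss, state_signature

log = logging.getLogger("quantchip")


def _truth_from_config(config: RunConfig) -> TruthConfig:
    return TruthConfig(
        seed=config.seed,
        n_genes=config.n_genes,
        n_enhancers=config.n_enhancers,
        depth=config.depth,
        dispersion=config.dispersion,
    )


def _window_fc_per_gene(exp, windows, mark, cond_a, cond_b, config: RunConfig) -> pd.Series:
    """Per-gene traditional-mode log2FC of a mark on its feature window."""
    from .genome import overlap_any

    win = windows.windows(exp.genome.genes, mark)
    cell_a, treat_a = cond_a.split("_")
    cell_b, treat_b = cond_b.split("_")
    fc_bins = local_log2fc(
        exp.get(mark=mark, cell_type=cell_a, treatment=treat_a),
        exp.get(mark=mark, cell_type=cell_a, treatment=treat_a, role="input"),
        exp.get(mark=mark, cell_type=cell_b, treatment=treat_b),
        exp.get(mark=mark, cell_type=cell_b, treatment=treat_b, role="input"),
        mode="traditional",
        pseudocount=config.pseudocount,
        count_pseudocount=config.count_pseudocount,
    )
    vals = []
    bins = exp.bins
    for _, w in win.iterrows():
        mask = (bins["chrom"] == w["chrom"]) & (bins["start"] < w["end"]) & (bins["end"] > w["start"])
        ids = bins.loc[mask, "region_id"]
        vals.append(fc_bins.loc[ids].mean() if len(ids) else np.nan)
    return pd.Series(vals, index=win["gene_id"].values, name=mark)


def run_all(config: RunConfig, outdir) -> dict:
    """Run every enabled stage; returns the result dict it also writes.

    Results are idempotent under identical config + seed. On stage failure
    the partial results written so far remain in place and the exception
    propagates after logging the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = qio.config_hash(config.model_dump())
    results: dict = {"config_hash": chash}
    qio.write_json(config.model_dump(), outdir / "resolved_config.json")

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    truth = _truth_from_config(config)
    windows = FeatureWindowSpec.preset(config.window_preset)
    stage = "simulate"
    try:
        log.info("stage simulate: genome + counts (seed=%d)", config.seed)
        genome = generate_genome(truth)
        exp = simulate_chip_counts(genome, truth, windows)

        if "scale" in config.stages:
            stage = "scale"
            log.info("stage scale: global scaling factors")
            scales = {}
            for mark in truth.marks:
                est = global_scale(
                    exp.get(mark=mark, cell_type="mESC", treatment="DMSO"),
                    exp.get(mark=mark, cell_type="mESC", treatment="DMSO", role="input"),
                    exp.get(mark=mark, cell_type="NPC48h", treatment="DMSO"),
                    exp.get(mark=mark, cell_type="NPC48h", treatment="DMSO", role="input"),
                )
                scales[mark] = est.to_dict()
            retention = {}
            for cell in truth.cell_types:
                ret = epz_retention(
                    exp.get(mark="H3K79me2", cell_type=cell, treatment="DMSO"),
                    exp.get(mark="H3K79me2", cell_type=cell, treatment="DMSO", role="input"),
                    exp.get(mark="H3K79me2", cell_type=cell, treatment="EPZ"),
                    exp.get(mark="H3K79me2", cell_type=cell, treatment="EPZ", role="input"),
                )
                retention[cell] = {"retention_pct": ret.retention_pct, "sd_pct": ret.sd_pct}
            results["global_scales"] = scales
            results["epz_retention"] = retention
            qio.write_json({"config_hash": chash, "scales": scales, "retention": retention},
                           outdir / "global_scales.json")

        if "decompose" in config.stages:
            stage = "decompose"
            log.info("stage decompose: global-change classification")
            classes = {}
            for mark in truth.marks:
                chip_a = exp.get(mark=mark, cell_type="mESC", treatment="DMSO")
                in_a = exp.get(mark=mark, cell_type="mESC", treatment="DMSO", role="input")
                chip_b = exp.get(mark=mark, cell_type="NPC48h", treatment="DMSO")
                in_b = exp.get(mark=mark, cell_type="NPC48h", treatment="DMSO", role="input")
                fc = local_log2fc(chip_a, in_a, chip_b, in_b, mode="quantitative",
                                  pseudocount=config.pseudocount,
                                  count_pseudocount=config.count_pseudocount)
                from .relacs import _mean_enrichment

                cov = 0.5 * (
                    _mean_enrichment(chip_a, in_a, config.count_pseudocount)
                    + _mean_enrichment(chip_b, in_b, config.count_pseudocount)
                )
                ma = ma_summary(fc, cov)
                cls = classify_global_change(
                    ma, exp.peak_bins[mark], config.tau_log2, config.delta_log2
                )
                classes[mark] = {
                    "label": cls.label,
                    "peak_median": cls.peak_median,
                    "background_median": cls.background_median,
                }
            results["global_change_classes"] = classes
            qio.write_json({"config_hash": chash, "classes": classes},
                           outdir / "global_change_classes.json")

        # per-gene H3K79me2 enrichment scores per cell type (traditional)
        delta = {}
        if {"cluster", "model"} & set(config.stages):
            stage = "delta"
            log.info("stage delta: per-gene mark fold changes")
            for mark in truth.marks:
                delta[mark] = _window_fc_per_gene(
                    exp, windows, mark, "mESC_DMSO", "NPC48h_DMSO", config
                )
            de_table = simulate_expression(
                genome, truth, pd.DataFrame(delta).rename_axis("gene_id")
            )
            qio.write_tsv(de_table, outdir / "expression_de.tsv")

        if "cluster" in config.stages:
            stage = "cluster"
            log.info("stage cluster: k-means stratification")
            scores = pd.DataFrame(
                {
                    "mESC": _enrichment_score(exp, windows, "H3K79me2", "mESC", "DMSO", config),
                    "NPC48h": _enrichment_score(exp, windows, "H3K79me2", "NPC48h", "DMSO", config),
                }
            ).dropna()
            assignment = kmeans_stratify(scores, k=config.k_clusters, seed=config.seed)
            summaries = cluster_summaries(
                assignment,
                delta["H3K79me2"],
                de_table.set_index("gene_id")["log2fc"],
            )
            qio.write_tsv(summaries.reset_index(), outdir / "cluster_summaries.tsv")
            results["clusters"] = summaries.to_dict(orient="index")

        if "model" in config.stages:
            stage = "model"
            log.info("stage model: regularized expression model")
            matrix = build_delta_matrix(delta, de_table)
            fit = MarkExpressionModel(matrix).fit(seed=config.seed)
            results["expression_model"] = {
                "r2": fit.r2,
                "r2_cv": fit.r2_cv,
                "ranking": fit.ranking,
                "coef": fit.coef.to_dict(),
                "alpha": fit.alpha,
            }
            deg = (matrix["padj"] < config.padj_de).to_numpy()
            gain = (matrix["H3K79me2"] > 0).to_numpy()
            phi, table = phi_association(deg, gain)
            results["phi_deg_vs_h3k79me2_gain"] = {"phi": phi, "table": table.tolist()}
            qio.write_json({"config_hash": chash, **results["expression_model"]},
                           outdir / "expression_model.json")

        if "states" in config.stages:
            stage = "states"
            log.info("stage states: signatures + varying-intercept posterior")
            seg_df, k4_peaks, gene_state = simulate_segmentation(genome, truth)
            seg = Segmentation(seg_df, n_states=truth.n_states)
            chosen = select_tss(genome.transcripts, k4_peaks)
            sigs = state_signature(seg, genome.genes, chosen)
            state_fc = simulate_state_expression(gene_state, truth)
            model = VaryingInterceptModel(
                state_fc.set_index("gene_id")["log2fc"].reindex(sigs.dominant.index),
                sigs.dominant,
            )
            posterior = model.fit(
                chains=config.chains, draws=config.draws, warmup=config.warmup,
                seed=config.seed,
            )
            results["varying_intercept"] = posterior.to_dict()
            qio.write_json({"config_hash": chash, **posterior.to_dict()},
                           outdir / "varying_intercept.json")

        if "atac" in config.stages:
            stage = "atac"
            log.info("stage atac: accessibility dynamics")
            peaks, counts, atac_truth = simulate_atac_counts(genome, truth)
            cond_of = {c: ("EPZ" if "_EPZ_" in c else "DMSO") for c in counts.columns}
            selection = pc_loading_select(
                counts, cond_of, component=config.atac_component,
                n=min(config.atac_top_n, len(counts)),
            )
            annotated = annotate_peaks(peaks, genome, genome.enhancers)
            enh_summary = enhancer_fc_summary(selection, annotated)
            marked = pd.Series(True, index=pd.Index(exp.marked_genes["H3K79me2"]))
            marked = marked.reindex(genome.genes["gene_id"], fill_value=False)
            fractions = mark_fraction_by_class(selection, annotated, marked)
            results["atac"] = {
                "enhancer_fc": enh_summary["classes"],
                "mark_fractions": fractions["fraction_marked"].to_dict(),
            }
            qio.write_json({"config_hash": chash, **results["atac"]}, outdir / "atac.json")
    except Exception:
        log.exception("stage %s failed", stage)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    qio.write_json(results, outdir / "results.json")
    return results


def _enrichment_score(exp, windows, mark, cell, treat, config: RunConfig) -> pd.Series:
    """Per-gene log2(chip/input) under traditional depth normalization."""
    from .relacs import _mean_enrichment

    chips = exp.get(mark=mark, cell_type=cell, treatment=treat)
    inputs = exp.get(mark=mark, cell_type=cell, treatment=treat, role="input")
    enr = _mean_enrichment(chips, inputs, config.count_pseudocount)
    win = windows.windows(exp.genome.genes, mark)
    bins = exp.bins
    vals = []
    for _, w in win.iterrows():
        mask = (bins["chrom"] == w["chrom"]) & (bins["start"] < w["end"]) & (bins["end"] > w["start"])
        ids = bins.loc[mask, "region_id"]
        vals.append(float(np.log2(enr.loc[ids]).mean()) if len(ids) else np.nan)
    return pd.Series(vals, index=win["gene_id"].values)


def make_demo(outdir, seed: int = 0) -> Path:
    """Write a small synthetic fixture set (FASTQ, BEDs, TSVs, truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = TruthConfig(seed=seed, n_genes=300, depth=50_000)
    genome = generate_genome(truth)
    genome.to_dir(outdir / "genome")
    from .genome import write_genes_bed12

    write_genes_bed12(genome, outdir / "genes.bed12")
    exp = simulate_chip_counts(genome, truth)
    qio.write_tsv(exp.bins, outdir / "bins.tsv")
    wide = pd.DataFrame({s.sample_id: s.counts for s in exp.samples})
    wide.index.name = "region_id"
    qio.write_tsv(wide.reset_index(), outdir / "chip_counts.tsv")
    # barcoded reads for one small pool (reference condition)
    pool = [s for s in exp.samples if s.condition == "mESC_DMSO" and s.replicate == 1]
    scheme = RelacsBarcodeScheme.default([s.sample_id for s in pool])
    emit_barcoded_reads(
        pool, exp.bins, scheme, outdir / "reads.fastq", outdir / "alignments.tsv",
        dup_rate=0.2, seed=seed,
    )
    seg_df, k4_peaks, gene_state = simulate_segmentation(genome, truth)
    seg_out = seg_df.copy()
    seg_out["name"] = "E" + seg_out["state"].astype(str)
    qio.write_bed(seg_out, outdir / "segmentation.bed", cols=["chrom", "start", "end", "name"])
    qio.write_bed(k4_peaks, outdir / "h3k4me3_peaks.bed")
    peaks, counts, atac_truth = simulate_atac_counts(genome, truth)
    qio.write_tsv(peaks, outdir / "atac_peaks.tsv")
    qio.write_tsv(counts.reset_index(), outdir / "atac_counts.tsv")
    qio.write_tsv(atac_truth, outdir / "atac_truth.tsv")
    qio.write_json(
        {
            "truth": truth.to_dict(),
            "barcodes": scheme.barcode_to_sample,
            "gene_promoter_state": gene_state.to_dict(),
            "marked_genes": exp.marked_genes,
        },
        outdir / "truth.json",
    )
    return outdir
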