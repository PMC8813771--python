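"""End-to-end pipeline: simulate inputs, map introgressions, compute
phenotype indices, call DEGs per genotype and summarise the salt-response
overlap, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import expression, introgression, io, phenotype, synth
from .config import PipelineConfig

logger = logging.getLogger("saltil")

STAGES = ("simulate", "map-introgressions", "phenotype", "dge", "overlap")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages into ``cfg.outdir``; returns the run manifest.

    Reruns with the same configuration produce byte-identical outputs (the
    manifest records a SHA-256 digest per artifact).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": [], "artifacts": {}}

    def finish_stage(name: str, *paths: Path) -> None:
        manifest["stages"].append(name)
        for p in paths:
            manifest["artifacts"][p.name] = _digest(p)
        logger.info("stage %s complete (%d artifacts)", name, len(paths))

    # -- simulate ----------------------------------------------------------
    try:
        sim = cfg.simulate
        genome = synth.GenomeSpec.rice_like(sim.n_genes)
        mosaic = synth.TruthMosaicConfig(
            dispersed_donor_genes=sim.dispersed_donor_genes)
        model = synth.DivergenceModel(
            mu_donor=sim.mu_donor, mu_recurrent=sim.mu_recurrent,
            dispersion=sim.dispersion, detection_prob=sim.detection_prob)
        annotation, truth = synth.gen_truth_line(genome, mosaic, cfg.seed)
        profiles = synth.gen_variant_profiles(
            annotation, truth.labels, model, cfg.seed)
        design = synth.ExpressionDesign(
            n_genes=sim.expression_genes, replicates=sim.replicates,
            effect_size_log2FC=sim.effect_size_log2FC,
            nb_dispersion=sim.nb_dispersion)
        counts, metadata, lengths, expr_truth = synth.gen_expression(
            design, cfg.seed)
        tolerances = {"FL478": 0.9, "OLESA": 0.1, "IL22": 0.7, "IL13": 0.6}
        pheno, ions = synth.gen_phenotypes(
            tolerances, rng_seed=cfg.seed,
            n_replicates=cfg.phenotype.n_replicates)

        gff = outdir / "annotation.gff3"
        io.write_gff3(annotation, gff)
        prof_path = outdir / "variant_profiles.tsv"
        io.write_tsv(profiles, prof_path)
        counts_path = outdir / "counts.tsv"
        counts.to_csv(counts_path, sep="\t")
        meta_path = outdir / "samples.tsv"
        io.write_tsv(metadata, meta_path)
        len_path = outdir / "gene_lengths.tsv"
        lengths.to_frame().to_csv(len_path, sep="\t")
        pheno_path = outdir / "phenotypes.tsv"
        io.write_tsv(pheno, pheno_path)
        ions_path = outdir / "ions.tsv"
        io.write_tsv(ions, ions_path)
        truth_path = outdir / "truth.json"
        io.write_truth(truth, truth_path, expr_truth)
        finish_stage("simulate", gff, prof_path, counts_path, meta_path,
                     len_path, pheno_path, ions_path, truth_path)
    except Exception as exc:
        raise StageError(f"stage simulate failed: {exc}") from exc

    # -- map-introgressions ------------------------------------------------
    try:
        mp = cfg.map
        mcfg = introgression.MapperConfig(
            threshold=mp.threshold, min_block_run=mp.min_block_run,
            max_gap_genes=mp.max_gap_genes)
        calls, report = introgression.map_introgressions(profiles, mcfg)
        bed_path = outdir / "blocks.bed"
        io.write_bed(report, bed_path)
        summary_path = outdir / "block_summary.tsv"
        io.write_tsv(introgression.summarize(report), summary_path)
        scatter_path = outdir / "variant_excess_scatter.tsv"
        io.write_tsv(introgression.scatter_table(calls), scatter_path)
        metrics = introgression.benchmark_recovery(
            truth.labels, truth.block_transcripts, report, annotation)
        report_json = outdir / "introgression_report.json"
        report_json.write_text(json.dumps({
            "n_blocks": len(report.blocks),
            "blocks": [dict(chrom=b.chrom, start_bp=b.start_bp,
                            end_bp=b.end_bp, n_genes=b.n_genes)
                       for b in report.blocks],
            "n_dispersed": len(report.dispersed),
            "sensitivity": metrics.sensitivity,
            "fdr": metrics.fdr,
            "median_abs_boundary_offset": metrics.median_abs_offset,
        }, indent=1))
        finish_stage("map-introgressions", bed_path, summary_path,
                     scatter_path, report_json)
    except Exception as exc:
        raise StageError(f"stage map-introgressions failed: {exc}") from exc

    # -- phenotype ---------------------------------------------------------
    try:
        check = cfg.phenotype.check_line
        tol_path = outdir / "tolerance_index.tsv"
        io.write_tsv(phenotype.tolerance_index_table(pheno, check), tol_path)
        el_path = outdir / "el_summary.tsv"
        io.write_tsv(phenotype.el_summary(pheno), el_path)
        ses_path = outdir / "ses_distribution.tsv"
        io.write_tsv(phenotype.ses_table(pheno), ses_path)
        nak_path = outdir / "na_k_ratios.tsv"
        io.write_tsv(phenotype.na_k_summary(ions), nak_path)
        finish_stage("phenotype", tol_path, el_path, ses_path, nak_path)
    except Exception as exc:
        raise StageError(f"stage phenotype failed: {exc}") from exc

    # -- dge ---------------------------------------------------------------
    try:
        dcfg = expression.DGEConfig(
            lfc_threshold=cfg.dge.lfc_threshold,
            p_threshold=cfg.dge.p_threshold, fpkm_min=cfg.dge.fpkm_min)
        tables = {}
        for genotype in metadata["genotype"].unique():
            table = expression.dge_contrast(
                counts, metadata, lengths, genotype, dcfg)
            tables[genotype] = table
            path = outdir / f"deg_{genotype}.tsv"
            table.to_csv(path, sep="\t")
        finish_stage("dge", *[outdir / f"deg_{g}.tsv" for g in tables])
    except Exception as exc:
        raise StageError(f"stage dge failed: {exc}") from exc

    # -- overlap -----------------------------------------------------------
    try:
        genos = list(tables)
        up_a, down_a = expression.deg_sets(tables[genos[0]])
        up_b, down_b = expression.deg_sets(tables[genos[1]])
        summary = expression.overlap_summary(up_a, down_a, up_b, down_b)
        overlap_path = outdir / "overlap.json"
        overlap_path.write_text(json.dumps({
            "genotypes": genos,
            "n_a": summary.n_a, "n_b": summary.n_b,
            "common_up": summary.common_up,
            "common_down": summary.common_down,
            "union_size": summary.union_size,
            "pct_common": round(summary.pct_common, 1),
            "truth_pct_common": round(expr_truth.common_percentage(), 1),
        }, indent=1))
        finish_stage("overlap", overlap_path)
    except Exception as exc:
        raise StageError(f"stage overlap failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
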