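"""End-to-end orchestration: simulate/load -> filter -> GWAS -> GWIS ->
annotate -> P&T score -> interaction tests -> LRT -> explained overlap ->
effective count -> report bundle.

Every intermediate artifact is written to the output directory in the
documented tab-separated formats, together with a JSON run manifest that
records every threshold and seed actually used.  Plots (a Manhattan plot of
the GWIS and a per-pathway -log10 p bar chart) are diagnostic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .annotation import build_pathway_variant_sets, map_variants_to_genes
from .config import ClumpSpec, PipelineConfig, ScanSpec, SimConfig
from .interactions import (effective_count, lrt_full_vs_restricted, results_table,
                           test_all)
from .overlap import annotate_explained, prune_loci, unexplained_fraction
from .pgs import GENOME_WIDE, build_all_scores, remove_ambiguous
from .scan import run_gwas, run_gwis
from .synthetic import simulate_cohort

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "compare_collections", "load_pipeline_config"]


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("sim", None)
    clump = raw.pop("clump", None)
    cfg = PipelineConfig(**raw)
    if sim is not None:
        cfg.sim = SimConfig.from_dict(sim)
    if clump is not None:
        cfg.clump = ClumpSpec(**clump)
    return cfg


def _load_inputs(config: PipelineConfig, outdir: Path) -> dict:
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        cohort = simulate_cohort(sim)
        pio.write_variant_table(cohort.variants, outdir / "variants.tsv")
        pio.write_gene_table(cohort.genes, outdir / "genes.tsv")
        pio.write_genotype_matrix(cohort.genotypes, outdir / "genotypes.tsv")
        pio.write_gmt(cohort.pathways, outdir / "pathways.gmt")
        pio.write_vector(cohort.phenotype, "phenotype", outdir / "phenotype.tsv")
        pio.write_vector(cohort.exposure, "exposure", outdir / "exposure.tsv")
        pio.write_covariates(cohort.covariates, outdir / "covariates.tsv")
        with open(outdir / "truth.yaml", "w") as fh:
            yaml.safe_dump(cohort.truth.to_dict(cohort.genotypes.variant_ids), fh)
        return {"genotypes": cohort.genotypes, "variants": cohort.variants,
                "genes": cohort.genes, "pathways": cohort.pathways,
                "phenotype": cohort.phenotype, "exposure": cohort.exposure,
                "covariates": cohort.covariates}
    return {"genotypes": pio.read_genotype_matrix(config.genotypes),
            "variants": pio.read_variant_table(config.variants),
            "genes": pio.read_gene_table(config.genes),
            "pathways": pio.read_gmt(config.gmt),
            "phenotype": pio.read_vector(config.phenotype),
            "exposure": pio.read_vector(config.exposure),
            "covariates": pio.read_covariates(config.covariates)}


def _stage(name):
    log.info("pipeline stage: %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the report bundle in memory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    _stage("inputs")
    data = _load_inputs(config, outdir)
    genotypes, variants = data["genotypes"], data["variants"]
    genes, pathways = data["genes"], data["pathways"]
    y, E, cov = data["phenotype"], data["exposure"], data["covariates"]

    _stage("variant filters")
    variants, genotypes = pio.apply_variant_filters(variants, genotypes,
                                                    config.maf_min, config.info_min)

    _stage("gwas")
    scan_spec = ScanSpec(mode="gwas", covariate_preset="methods")
    gwas = run_gwas(genotypes, variants, y, cov, scan_spec)
    pio.write_sumstats(gwas, outdir / "gwas_sumstats.tsv")

    _stage("gwis")
    gwis_spec = ScanSpec(mode="gwis", covariate_preset="methods")
    gwis = run_gwis(genotypes, variants, y, E, cov, gwis_spec)
    pio.write_sumstats(gwis, outdir / "gwis_sumstats.tsv")

    _stage("annotation")
    vg = map_variants_to_genes(variants, genes, config.upstream_bp, config.downstream_bp)
    pv = build_pathway_variant_sets(vg, pathways)
    rows = [(p, v) for p in pathways.names for v in sorted(pv[p])]
    pd.DataFrame(rows, columns=["pathway", "variant_id"]).to_csv(
        outdir / "pathway_variants.tsv", sep="\t", index=False)

    _stage("pgs")
    variants_pgs = remove_ambiguous(variants)
    keep_ids = set(variants_pgs["variant_id"])
    gwas_pgs = gwas[gwas["variant_id"].isin(keep_ids)].reset_index(drop=True)
    pv_pgs = {p: frozenset(v for v in pv[p] if v in keep_ids) for p in pathways.names}
    scores, weight_sets = build_all_scores(gwas_pgs, genotypes, variants_pgs,
                                           pv_pgs, config.clump)
    pio.write_weights(weight_sets, outdir / "weights.tsv")
    pio.write_scores(scores, outdir / "scores.tsv")

    _stage("interaction tests")
    results, bonferroni = test_all(scores, y, E, cov, alpha=config.alpha,
                                   covariate_preset=config.covariate_preset)
    res_df = results_table(results)
    res_df.to_csv(outdir / "results.tsv", sep="\t", index=False,
                  float_format="%.12g", na_rep="NA")

    _stage("lrt")
    lrt = lrt_full_vs_restricted(scores, y, E, cov,
                                 covariate_preset=config.covariate_preset)
    with open(outdir / "lrt.txt", "w") as fh:
        fh.write(f"loglik_restricted\t{lrt.loglik_restricted:.12g}\n"
                 f"loglik_full\t{lrt.loglik_full:.12g}\n"
                 f"statistic\t{lrt.statistic:.12g}\ndf\t{lrt.df}\np\t{lrt.p:.12g}\n")

    _stage("gwis loci + explained overlap")
    loci = prune_loci(gwis, config.gwis_threshold, config.locus_radius_bp)
    loci.leads.to_csv(outdir / "gwis_loci.tsv", sep="\t", index=False,
                      float_format="%.12g")
    sig_pathways = [r.score_name for r in results
                    if r.significant and r.score_name != GENOME_WIDE]
    overlap = annotate_explained(sig_pathways, loci, genes, pathways,
                                 config.explain_window_bp)
    ov_rows = [(p, overlap.explained[p],
                ";".join(f"{l}:{g}" for l, g in overlap.implicated[p]) or "NA")
               for p in sig_pathways]
    pd.DataFrame(ov_rows, columns=["pathway", "explained", "implicated"]).to_csv(
        outdir / "explain.tsv", sep="\t", index=False)
    if sig_pathways:
        n_un, frac, pct = unexplained_fraction(overlap)
    else:
        n_un, frac, pct = 0, float("nan"), -1
    table1 = pd.DataFrame([{
        "n_gwis_loci": len(loci), "n_significant_pathways": len(sig_pathways),
        "n_unexplained": n_un, "fraction_unexplained": frac,
        "percent_unexplained": pct}])
    table1.to_csv(outdir / "overlap_summary.tsv", sep="\t", index=False,
                  float_format="%.12g", na_rep="NA")

    _stage("effective count")
    if sig_pathways:
        eff = effective_count(scores.values[sig_pathways])
    else:
        eff = effective_count(scores.values[[]])
    with open(outdir / "effective_count.txt", "w") as fh:
        fh.write(f"n_significant\t{len(sig_pathways)}\n"
                 f"n_eff\t{eff.n_eff:.12g}\n"
                 f"eigenvalues\t{','.join(f'{v:.12g}' for v in eff.eigenvalues)}\n")

    _stage("plots")
    _manhattan(gwis, config.gwis_threshold, outdir / "gwis_manhattan.png")
    _pathway_bars(res_df, bonferroni, outdir / "pathway_neglog10p.png")

    manifest = {
        "seed": config.seed, "maf_min": config.maf_min, "info_min": config.info_min,
        "upstream_bp": config.upstream_bp, "downstream_bp": config.downstream_bp,
        "p_threshold": config.clump.p_threshold, "radius_bp": config.clump.radius_bp,
        "r2_max": config.clump.r2_max, "alpha": config.alpha,
        "bonferroni_threshold": bonferroni,
        "gwis_threshold": config.gwis_threshold,
        "locus_radius_bp": config.locus_radius_bp,
        "explain_window_bp": config.explain_window_bp,
        "covariate_preset": config.covariate_preset,
        "n_individuals": int(genotypes.n_individuals),
        "n_variants_tested": int(genotypes.n_variants),
        "n_pathways": len(pathways),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {"results": res_df, "bonferroni": bonferroni, "lrt": lrt,
            "loci": loci, "overlap": overlap, "overlap_summary": table1,
            "effective_count": eff, "scores": scores, "gwas": gwas, "gwis": gwis,
            "significant_pathways": sig_pathways, "manifest": manifest}


def _manhattan(gwis: pd.DataFrame, threshold: float, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 3))
    offset = 0
    for chrom, grp in gwis.groupby("chrom", sort=False):
        with np.errstate(divide="ignore"):
            ax.scatter(grp["pos"] + offset, -np.log10(grp["p_int"]), s=4, label=None)
        offset += grp["pos"].max() + 1
    ax.axhline(-np.log10(threshold), color="red", lw=0.8, ls="--")
    ax.set_xlabel("genomic position (concatenated chromosomes)")
    ax.set_ylabel("-log10 p (interaction)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _pathway_bars(res_df: pd.DataFrame, bonferroni: float, path: Path) -> None:
    sub = res_df[res_df["score_name"] != GENOME_WIDE].copy()
    with np.errstate(divide="ignore"):
        sub["neglog10p"] = -np.log10(sub["p_int"])
    sub = sub.sort_values("neglog10p", ascending=False).head(40)
    fig, ax = plt.subplots(figsize=(8, max(3, 0.2 * len(sub))))
    ax.barh(sub["score_name"], sub["neglog10p"])
    ax.axvline(-np.log10(bonferroni), color="red", lw=0.8, ls="--")
    ax.invert_yaxis()
    ax.set_xlabel("-log10 p (pPGS x E)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def compare_collections(config: PipelineConfig, gmt_paths: list[str]) -> pd.DataFrame:
    """Rerun annotation -> scoring -> testing per pathway collection.

    Shares the simulated/loaded data, GWAS and variant filtering across
    collections; each collection gets its own Bonferroni threshold.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = _load_inputs(config, outdir)
    genotypes, variants = data["genotypes"], data["variants"]
    genes = data["genes"]
    y, E, cov = data["phenotype"], data["exposure"], data["covariates"]
    variants, genotypes = pio.apply_variant_filters(variants, genotypes,
                                                    config.maf_min, config.info_min)
    gwas = run_gwas(genotypes, variants, y, cov, ScanSpec(mode="gwas"))
    variants_pgs = remove_ambiguous(variants)
    keep_ids = set(variants_pgs["variant_id"])
    gwas_pgs = gwas[gwas["variant_id"].isin(keep_ids)].reset_index(drop=True)
    vg = map_variants_to_genes(variants, genes, config.upstream_bp, config.downstream_bp)

    rows = []
    for path in gmt_paths:
        coll = pio.read_gmt(path)
        pv = build_pathway_variant_sets(vg, coll)
        pv_pgs = {p: frozenset(v for v in pv[p] if v in keep_ids) for p in coll.names}
        scores, _ = build_all_scores(gwas_pgs, genotypes, variants_pgs, pv_pgs,
                                     config.clump)
        results, thr = test_all(scores, y, E, cov, alpha=config.alpha,
                                covariate_preset=config.covariate_preset)
        n_sig = sum(r.significant for r in results if r.score_name != GENOME_WIDE)
        rows.append({"collection": str(path), "n_pathways": len(coll),
                     "bonferroni_threshold": thr, "n_significant": n_sig})
    out = pd.DataFrame(rows)
    out.to_csv(outdir / "collection_comparison.tsv", sep="\t", index=False,
               float_format="%.12g")
    return out
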