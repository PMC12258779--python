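"""Monte-Carlo evaluation studies of the interaction-testing pipeline.

Two studies, shared by the test suite and the acceptance script:

* ``type_one_error_study`` — empirical size of the pPGS x E test on null
  cohorts (no interaction anywhere).  Cohorts of n individuals are simulated;
  within each cohort the genotypes, GWAS and trained pathway score are held
  fixed while the null phenotype and exposure are redrawn independently, so
  each redraw is an independent draw of the test statistic conditional on G —
  which is exactly what the regression test's size refers to.

* ``power_ordering_study`` — the motivating power comparison: with the
  interaction confined to one small pathway, the causal pathway's pPGS x E
  test should out-rank both the genome-wide PGS x E test and the best
  single-variant interaction p-value inside the pathway.

Problem sizes default to the documented desk-scale study conditions (see
docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .config import ClumpSpec, ScanSpec, SimConfig
from .interactions import pgs_by_e_test, test_all
from .pgs import GENOME_WIDE, build_all_scores
from .scan import run_gwas, run_gwis
from .synthetic import simulate_cohort, simulate_phenotype

log = logging.getLogger(__name__)

__all__ = ["null_sim_config", "power_sim_config", "type_one_error_study",
           "power_ordering_study", "PowerOrderingResult"]


def null_sim_config(n: int = 5000, seed: int = 0) -> SimConfig:
    """Null cohort: genetic main effects present, no interaction anywhere."""
    return SimConfig(
        n_individuals=n, n_chromosomes=2, n_blocks_per_chrom=5,
        variants_per_block=20, ld_rho=0.8, n_genes=20, n_pathways=10,
        genes_per_pathway=2, pathway_overlap_fraction=0.0,
        causal_pathways=("PWY_001",), h2_main=0.2, var_gxe=0.0,
        alpha_E=0.1, n_pcs=2, seed=seed,
    )


def power_sim_config(n: int = 20000, var_gxe: float = 0.02, seed: int = 0) -> SimConfig:
    """Interaction confined to one small pathway (~4% of causal variants)."""
    return SimConfig(
        n_individuals=n, n_chromosomes=2, n_blocks_per_chrom=10,
        variants_per_block=25, ld_rho=0.8, n_genes=50, n_pathways=25,
        genes_per_pathway=2, pathway_overlap_fraction=0.0,
        causal_pathways=("PWY_001",), h2_main=0.25, var_gxe=var_gxe,
        alpha_E=0.1, main_causal_fraction=1.0, gamma_mode="proportional",
        n_pcs=2, seed=seed,
    )


def type_one_error_study(n: int = 5000, n_replicates: int = 1000,
                         n_cohorts: int = 20, alpha: float = 0.05,
                         seed: int = 0) -> dict:
    """Empirical rejection rate of the causal pathway's pPGS x E test at
    nominal ``alpha`` under a fully null (var_gxe = 0) generative model."""
    if n_replicates % n_cohorts:
        raise ValueError("n_replicates must be a multiple of n_cohorts")
    redraws = n_replicates // n_cohorts
    clump_spec = ClumpSpec(p_threshold=1e-3, ld_panel_seed=seed)
    pvals: list[float] = []
    for c in range(n_cohorts):
        cfg = null_sim_config(n=n, seed=int(np.random.default_rng([seed, c]).integers(2 ** 31)))
        cohort = simulate_cohort(cfg)
        ss = run_gwas(cohort.genotypes, cohort.variants, cohort.phenotype,
                      cohort.covariates, ScanSpec(mode="gwas"))
        scores, _ = build_all_scores(ss, cohort.genotypes, cohort.variants,
                                     {p: cohort.pathway_variants[p]
                                      for p in cfg.causal_pathways}, clump_spec)
        pwy = cfg.causal_pathways[0]
        col = scores.values[pwy].to_numpy()
        if col.std() == 0:  # no variant survived P&T in this cohort; skip it
            log.warning("cohort %d: empty pathway score under the null; "
                        "substituting the genome-wide score", c)
            col = scores.values[GENOME_WIDE].to_numpy()
        rng = np.random.default_rng([seed, 1000 + c])
        for r in range(redraws):
            cfg_r = replace(cfg, seed=int(rng.integers(2 ** 31)))
            cov = cohort.covariates
            expo = np.random.default_rng([cfg_r.seed, 23]).standard_normal(n)
            y, _ = simulate_phenotype(cfg_r, cohort.genotypes, cohort.variants,
                                      cohort.genes, cohort.pathways, expo, cov,
                                      pathway_variants=cohort.pathway_variants)
            res = pgs_by_e_test(col, y, expo, cov, covariate_preset="results",
                                score_name=pwy)
            pvals.append(res.p_int)
    pvals_arr = np.asarray(pvals)
    return {
        "n_tests": len(pvals_arr),
        "alpha": alpha,
        "empirical_alpha": float(np.mean(pvals_arr < alpha)),
        "pvalues": pvals_arr,
    }


@dataclass
class PowerOrderingResult:
    n_replicates: int
    rank1_fraction: float                 # causal pathway ranks first among pPGS
    mean_neglog10p_causal_ppgs: float
    mean_neglog10p_gwpgs: float
    mean_neglog10p_best_gwis: float
    per_replicate: list


def power_ordering_study(n: int = 20000, var_gxe: float = 0.02,
                         n_replicates: int = 200, seed: int = 0
                         ) -> PowerOrderingResult:
    """Causal-pathway recovery and power ordering across replicates."""
    clump_spec = ClumpSpec(p_threshold=1e-3, ld_panel_seed=seed)
    rows = []
    for r in range(n_replicates):
        rep_seed = int(np.random.default_rng([seed, r]).integers(2 ** 31))
        cfg = power_sim_config(n=n, var_gxe=var_gxe, seed=rep_seed)
        cohort = simulate_cohort(cfg)
        ss = run_gwas(cohort.genotypes, cohort.variants, cohort.phenotype,
                      cohort.covariates, ScanSpec(mode="gwas"))
        scores, _ = build_all_scores(ss, cohort.genotypes, cohort.variants,
                                     cohort.pathway_variants, clump_spec)
        results, _ = test_all(scores, cohort.phenotype, cohort.exposure,
                              cohort.covariates, covariate_preset="results")
        by_name = {x.score_name: x for x in results}
        causal = cfg.causal_pathways[0]
        pwy_p = {x.score_name: np.nan_to_num(x.p_int, nan=1.0)
                 for x in results if x.score_name != GENOME_WIDE}
        rank = 1 + sum(p < pwy_p[causal] for q, p in pwy_p.items() if q != causal)

        # best single-variant interaction p inside the causal pathway
        sub = cohort.genotypes.subset_variants(sorted(cohort.pathway_variants[causal]))
        vsub = cohort.variants[cohort.variants["variant_id"]
                               .isin(cohort.pathway_variants[causal])].reset_index(drop=True)
        gwis = run_gwis(sub, vsub, cohort.phenotype, cohort.exposure,
                        cohort.covariates, ScanSpec(mode="gwis"))
        best_gwis_p = float(np.nanmin(gwis["p_int"].to_numpy()))

        rows.append({
            "rank": rank,
            "p_causal": pwy_p[causal],
            "p_gwpgs": np.nan_to_num(by_name[GENOME_WIDE].p_int, nan=1.0),
            "p_best_gwis": best_gwis_p,
        })

    def neglog10(x):
        return -np.log10(np.clip(x, 1e-320, None))

    return PowerOrderingResult(
        n_replicates=n_replicates,
        rank1_fraction=float(np.mean([row["rank"] == 1 for row in rows])),
        mean_neglog10p_causal_ppgs=float(np.mean([neglog10(row["p_causal"]) for row in rows])),
        mean_neglog10p_gwpgs=float(np.mean([neglog10(row["p_gwpgs"]) for row in rows])),
        mean_neglog10p_best_gwis=float(np.mean([neglog10(row["p_best_gwis"]) for row in rows])),
        per_replicate=rows,
    )
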