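"""Synthetic cohort generator.

Emulates, at desk scale, the statistical structure the pipeline assumes:
common biallelic SNPs in LD blocks, genes tiled along chromosomes, pathway
gene sets with configurable overlap, standard GWAS covariates (age, sex,
genotype principal components), a continuous exposure, and a quantitative
trait

    Y = sum_j beta_j g_j + alpha_E * E + sum_{j in S} gamma_j g_j * E
        + c' delta + eps

whose interaction effects are confined to the variant set S of one or more
designated causal pathways.  Every operation is fully determined by
``SimConfig.seed``.

LD within a block follows an AR(1) latent Gaussian copula: each of the two
haplotypes per individual is a latent AR(1) Gaussian series along the block,
thresholded at the quantile of the minor allele frequency, so dosages are
hard Binomial(2, maf) counts with adjacent-variant correlation governed by
``ld_rho``.  Blocks are mutually independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .annotation import build_pathway_variant_sets, map_variants_to_genes
from .config import ConfigurationError, SimConfig
from .io import GenotypeMatrix, PathwayCollection

log = logging.getLogger(__name__)

__all__ = ["Truth", "SyntheticCohort", "simulate_genotypes", "simulate_annotations",
           "simulate_covariates_and_exposure", "simulate_phenotype", "simulate_cohort"]

# distinct RNG stream tags per operation so each is deterministic standalone
_TAG_GENO, _TAG_ANNO, _TAG_COV, _TAG_PHENO = 11, 13, 17, 19

_UNAMBIGUOUS_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                      ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class Truth:
    """Generative record: which variants carry effects, and with what weights."""

    beta: np.ndarray                  # length m, scaled main effects (trait units)
    gamma: np.ndarray                 # length m, scaled interaction effects
    causal_main_idx: np.ndarray
    causal_gxe_idx: np.ndarray
    causal_pathways: tuple[str, ...]
    h2_main: float
    var_gxe: float

    def to_dict(self, variant_ids: list[str]) -> dict:
        vid = np.asarray(variant_ids)
        return {
            "causal_pathways": list(self.causal_pathways),
            "h2_main": self.h2_main,
            "var_gxe": self.var_gxe,
            "causal_main_variants": {
                str(vid[j]): float(self.beta[j]) for j in self.causal_main_idx},
            "causal_gxe_variants": {
                str(vid[j]): float(self.gamma[j]) for j in self.causal_gxe_idx},
        }


@dataclass
class SyntheticCohort:
    config: SimConfig
    genotypes: GenotypeMatrix
    variants: pd.DataFrame
    genes: pd.DataFrame
    pathways: PathwayCollection
    covariates: pd.DataFrame
    exposure: np.ndarray
    phenotype: np.ndarray = field(default=None)
    truth: Truth = field(default=None)
    pathway_variants: dict = field(default_factory=dict)


def _rng(config: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag])


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _ar1_latent(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    """n x m latent Gaussian with AR(1) correlation along the m axis."""
    z = rng.standard_normal((n, m), dtype=np.float32)
    if rho > 0:
        rho32 = np.float32(rho)
        s = np.float32(np.sqrt(1.0 - rho ** 2))
        for j in range(1, m):
            z[:, j] = rho32 * z[:, j - 1] + s * z[:, j]
    return z


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """LD-blocked hard-call dosages plus the matching variant table."""
    config.validate()
    rng = _rng(config, _TAG_GENO)
    n = config.n_individuals
    mb = config.variants_per_block
    block_span = mb * config.variant_spacing

    dosage_cols, rows = [], []
    for c in range(1, config.n_chromosomes + 1):
        chrom = str(c)
        for b in range(config.n_blocks_per_chrom):
            maf = rng.uniform(*config.maf_range, size=mb)
            thr = stats.norm.ppf(maf)
            hap1 = _ar1_latent(rng, n, mb, config.ld_rho) < thr
            hap2 = _ar1_latent(rng, n, mb, config.ld_rho) < thr
            d = (hap1.astype(np.float64) + hap2)
            if config.fractional_dosage_noise > 0:
                f = config.fractional_dosage_noise
                d = np.clip(d + rng.uniform(-f, f, size=d.shape), 0.0, 2.0)
            dosage_cols.append(d)
            start = 1 + b * (block_span + config.block_gap)
            for j in range(mb):
                pos = start + j * config.variant_spacing
                if rng.uniform() < config.ambiguous_fraction:
                    oth, eff = _AMBIGUOUS_PAIRS[rng.integers(len(_AMBIGUOUS_PAIRS))]
                else:
                    oth, eff = _UNAMBIGUOUS_PAIRS[rng.integers(len(_UNAMBIGUOUS_PAIRS))]
                rows.append((f"snp_{chrom}_{pos}", chrom, pos, oth, eff, maf[j]))

    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos",
                                           "allele_other", "allele_effect", "maf"])
    dosages = np.concatenate(dosage_cols, axis=1)
    ids = [f"ind_{i:06d}" for i in range(n)]
    gm = GenotypeMatrix(dosages, ids, variants["variant_id"].tolist())
    return gm, variants


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def simulate_annotations(config: SimConfig, variants: pd.DataFrame
                         ) -> tuple[pd.DataFrame, PathwayCollection]:
    """Genes tiling the variant territory; pathway gene sets over them.

    Each chromosome's variants are split into consecutive runs and each gene
    spans one run, so every gene maps at least one variant; strands alternate.
    With overlap fraction f, every pathway draws round(f * genes_per_pathway)
    genes from one shared pool and the rest from its exclusive slice (f = 0
    gives pairwise-disjoint sets).
    """
    config.validate()
    if variants.empty:
        raise ConfigurationError("variant table is empty")
    if config.genes_per_pathway < 2:
        raise ConfigurationError("each pathway needs at least 2 genes")
    rng = _rng(config, _TAG_ANNO)

    chroms = list(pd.unique(variants["chrom"]))
    per_chrom = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes % len(chroms)):
        per_chrom[i] += 1

    rows = []
    gene_counter = 0
    for chrom, k in zip(chroms, per_chrom):
        pos = np.sort(variants.loc[variants["chrom"] == chrom, "pos"].to_numpy())
        if k > len(pos):
            raise ConfigurationError(
                f"chromosome {chrom}: {k} genes requested but only {len(pos)} "
                f"variant positions available to tile")
        runs = np.array_split(pos, k)
        for run in runs:
            gene_counter += 1
            start, end = int(run[0]), int(max(run[-1], run[0] + 1))
            strand = "+" if gene_counter % 2 else "-"
            rows.append((f"GENE{gene_counter:04d}", chrom, start, end, strand))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])

    gpp = config.genes_per_pathway
    n_shared = int(round(config.pathway_overlap_fraction * gpp))
    n_excl = gpp - n_shared
    order = rng.permutation(genes["gene_id"].to_numpy())
    shared_pool = list(order[:n_shared])
    excl_pool = list(order[n_shared:])
    if config.n_pathways * n_excl > len(excl_pool):
        raise ConfigurationError(
            f"{config.n_pathways} pathways x {n_excl} exclusive genes exceed the "
            f"{len(excl_pool)} genes available; increase n_genes or the overlap fraction")

    coll = PathwayCollection()
    for i in range(config.n_pathways):
        members = shared_pool + excl_pool[i * n_excl:(i + 1) * n_excl]
        coll.add(f"PWY_{i + 1:03d}", "synthetic pathway", members)
    missing = [p for p in config.causal_pathways if p not in coll]
    if missing:
        raise ConfigurationError(f"causal pathway(s) not generated: {missing}")
    return genes, coll


# ---------------------------------------------------------------------------
# Covariates and exposure
# ---------------------------------------------------------------------------

def simulate_covariates_and_exposure(config: SimConfig, genotypes: GenotypeMatrix
                                     ) -> tuple[pd.DataFrame, np.ndarray]:
    """age, age^2, sex, age x sex, top-k genotype PCs; standardized exposure.

    The exposure is optionally correlated with a configured covariate via
    E = r * z_cov + sqrt(1 - r^2) * w, then affinely shifted if a BMI-like
    scale was requested.
    """
    config.validate()
    rng = _rng(config, _TAG_COV)
    n = genotypes.n_individuals
    m = genotypes.n_variants
    if config.n_pcs > min(n, m):
        raise ConfigurationError(f"n_pcs={config.n_pcs} exceeds min(n, m)={min(n, m)}")

    age = rng.uniform(40.0, 70.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    cov = pd.DataFrame({"age": age, "age2": age ** 2, "sex": sex,
                        "age_sex": age * sex})

    if config.n_pcs > 0:
        # PCs from an evenly thinned variant subset (the usual practice of
        # computing ancestry PCs on an LD-pruned SNP panel), capped at 256
        take = np.linspace(0, m - 1, num=min(m, 256)).round().astype(int)
        take = np.unique(take)
        D = genotypes.dosages[:, take].astype(np.float64, copy=True)
        miss = np.isnan(D)
        if miss.any():
            mean = np.nanmean(D, axis=0)
            idx = np.where(miss)
            D[idx] = mean[idx[1]]
        sd = D.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (D - D.mean(axis=0)) / sd
        pca = PCA(n_components=config.n_pcs, svd_solver="randomized",
                  random_state=int(config.seed % (2 ** 31)))
        pcs = pca.fit_transform(Z)
        for k in range(config.n_pcs):
            cov[f"gPC{k + 1}"] = pcs[:, k]

    w = rng.standard_normal(n)
    r = config.exposure_corr
    if config.exposure_corr_covariate is not None and r != 0.0:
        c = cov[config.exposure_corr_covariate].to_numpy()
        z = (c - c.mean()) / c.std()
        e = r * z + np.sqrt(1.0 - r ** 2) * w
    else:
        e = w
    exposure = config.exposure_mean + config.exposure_scale * e
    return cov, exposure


# ---------------------------------------------------------------------------
# Phenotype
# ---------------------------------------------------------------------------

def simulate_phenotype(config: SimConfig, genotypes: GenotypeMatrix,
                       variants: pd.DataFrame, genes: pd.DataFrame,
                       pathways: PathwayCollection, exposure: np.ndarray,
                       covariates: pd.DataFrame,
                       pathway_variants: dict | None = None
                       ) -> tuple[np.ndarray, Truth]:
    """Trait with main effects genome-wide and G x E confined to the causal
    pathways' variant set S (through the same annotation windows the pipeline
    uses).  Components are scaled so the genetic-main and interaction shares
    of the core variance (main + interaction + noise) equal ``h2_main`` and
    ``var_gxe``; with both zero, var(Y) = noise_sd^2.
    """
    config.validate()
    rng = _rng(config, _TAG_PHENO)
    n, m = genotypes.dosages.shape
    vid = variants["variant_id"].to_numpy()

    if pathway_variants is None:
        vg = map_variants_to_genes(variants, genes)
        pathway_variants = build_pathway_variant_sets(vg, pathways)
    s_ids: set[str] = set()
    for p in config.causal_pathways:
        if p not in pathway_variants:
            raise ConfigurationError(f"causal pathway {p!r} has no variant set")
        s_ids |= set(pathway_variants[p])
    s_idx = np.where(np.isin(vid, list(s_ids)))[0]
    if config.var_gxe > 0 and s_idx.size == 0:
        raise ConfigurationError("var_gxe > 0 but the causal pathways map to no variants")

    e_std = (exposure - exposure.mean()) / exposure.std()
    T = config.noise_sd ** 2 / (1.0 - config.h2_main - config.var_gxe)

    # mean-imputed dosage copy for component construction
    G = genotypes.dosages.astype(float, copy=True)
    miss = np.isnan(G)
    if miss.any():
        cm = np.nanmean(G, axis=0)
        idx = np.where(miss)
        G[idx] = cm[idx[1]]

    beta = np.zeros(m)
    main_idx = np.array([], dtype=int)
    if config.h2_main > 0:
        k = int(round(config.main_causal_fraction * m))
        if k == 0:
            raise ConfigurationError("h2_main > 0 requires main_causal_fraction > 0")
        main_idx = np.sort(rng.choice(m, size=k, replace=False))
        if config.gamma_mode == "proportional":
            main_idx = np.union1d(main_idx, s_idx)  # gamma ∝ beta needs beta on S
        beta[main_idx] = rng.standard_normal(main_idx.size)
        M = G[:, main_idx] @ beta[main_idx]
        scale = np.sqrt(config.h2_main * T) / M.std()
        beta *= scale
        M = M * scale
    else:
        M = np.zeros(n)

    gamma = np.zeros(m)
    if config.var_gxe > 0:
        if config.gamma_mode == "proportional":
            gamma[s_idx] = beta[s_idx]
        else:
            gamma[s_idx] = rng.standard_normal(s_idx.size)
        I = (G[:, s_idx] @ gamma[s_idx]) * e_std
        i_sd = I.std()
        if i_sd == 0:
            raise ConfigurationError("interaction component degenerate (zero variance)")
        scale = np.sqrt(config.var_gxe * T) / i_sd
        gamma *= scale
        I = I * scale
    else:
        I = np.zeros(n)

    C = np.zeros(n)
    for name, delta in (config.covariate_effects or {}).items():
        col = covariates[name].to_numpy(dtype=float)
        C += delta * np.sqrt(T) * (col - col.mean()) / col.std()

    eps = rng.normal(0.0, config.noise_sd, size=n)
    y = M + config.alpha_E * np.sqrt(T) * e_std + I + C + eps
    truth = Truth(beta=beta, gamma=gamma, causal_main_idx=main_idx,
                  causal_gxe_idx=s_idx if config.var_gxe > 0 else np.array([], dtype=int),
                  causal_pathways=tuple(config.causal_pathways),
                  h2_main=config.h2_main, var_gxe=config.var_gxe)
    return y, truth


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Run all four generator stages; the pathway variant map is cached."""
    gm, variants = simulate_genotypes(config)
    genes, pathways = simulate_annotations(config, variants)
    covariates, exposure = simulate_covariates_and_exposure(config, gm)
    vg = map_variants_to_genes(variants, genes)
    pv = build_pathway_variant_sets(vg, pathways)
    phenotype, truth = simulate_phenotype(config, gm, variants, genes, pathways,
                                          exposure, covariates, pathway_variants=pv)
    return SyntheticCohort(config=config, genotypes=gm, variants=variants,
                           genes=genes, pathways=pathways, covariates=covariates,
                           exposure=exposure, phenotype=phenotype, truth=truth,
                           pathway_variants=pv)
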