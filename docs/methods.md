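# Methods

## The model

The package tests whether an environmental exposure E (a BMI-like continuous
variable) modifies genetic effects on a quantitative trait Y (a log-biomarker
analog), and whether that modification is concentrated in particular
biological pathways rather than spread across the genome.  Three nested views
of the same question are implemented:

1. **GWIS** — per-variant interaction scan,
   `Y = G + E + G×E + C`, with heteroskedasticity-robust (sandwich) standard
   errors on the interaction coefficient and E×gPC product terms in the
   covariates to guard against confounding of the interaction by ancestry.
2. **gwPGS×E** — a genome-wide polygenic score built by pruning and
   thresholding (P&T) from the main-effect GWAS, tested in
   `Y = PGS + E + PGS×E + C`.
3. **pPGS×E** — the same P&T procedure run separately inside each pathway's
   variant set (variants mapped to genes by physical windows, genes to
   pathways by GMT gene sets), giving one score per pathway, each tested
   marginally and judged against a Bonferroni threshold of
   `alpha / (number of pathways tested)`.

Supporting analyses: a nested likelihood-ratio test asking whether the
pathway-score interactions jointly explain more than the genome-wide score's
interaction alone; greedy distance pruning of GWIS hits into loci and an
"explained" annotation of significant pathways (a pathway is explained when
a GWIS lead variant lies within a window of some member gene's TSS); and an
effective discovery count `n_eff = (Σλ)² / Σλ²` over the eigenvalues of the
correlation matrix of the significant pathway scores, which discounts
correlated discoveries.

## Defaults that mirror the published analysis

| parameter | default | unit |
|---|---|---|
| MAF filter | > 0.01 (strict) | allele frequency |
| INFO filter | > 0.5 (strict, only if column present) | imputation quality |
| P&T p-value threshold | 0.001 (5e-8 as strict preset) | p-value |
| clumping radius | 1,000,000 | bp |
| clumping r² threshold | 0.1 | squared correlation |
| LD reference panel | min(n, 20,000) seeded random individuals | count |
| gene window | 2,000 upstream / 1,000 downstream of the gene span, strand-aware | bp |
| GWIS significance | p < 5e-8 (strict) | p-value |
| locus pruning radius | ±500,000 | bp |
| "explained" TSS window | ±100,000, inclusive | bp |
| family-wise alpha | 0.05, Bonferroni over pathway scores only | — |

Ambiguous (A/T, C/G) variants are removed before P&T because their strand
cannot be resolved from alleles alone.  Coordinates are 1-based fully closed
throughout, and all window bounds are inclusive; the gene window is applied
to the whole gene interval with the upstream extent on the 5' side and the
downstream extent on the 3' side (so the two are swapped for minus-strand
genes).  Clumping ties on p break by (chrom, pos), making every run
deterministic.

## Regression details

Per-variant scans use the Frisch–Waugh–Lovell decomposition: outcome and the
variant-specific columns are residualized once against the shared covariate
block, after which each variant needs a 1×1 (GWAS) or 2×2 (GWIS) solve.
Coefficients, residuals, and the relevant block of the sandwich covariance
are identical to the full-design fit (verified against statsmodels in the
test suite).  The robust flavor is HC0 by default, with HC1 and HC3
available.  p-values use the t reference with the full model's residual
degrees of freedom — indistinguishable from the normal reference at study
sample sizes, exact at toy sizes where tests compare against closed-form
solutions.  Missing dosages are mean-imputed per variant by default; a
"drop" policy refits affected variants on complete rows.

Interaction tests standardize Y, the score, and E to unit SD in-sample, so
the reported interaction coefficient is in SD_Y per SD_score per SD_E, the
usual reporting convention for PGS×E effects.  Scores themselves are
unnormalized weighted sums of effect-allele dosages; because the tests
standardize, per-allele averaging would not change any p-value.  Missing
dosages in scoring are imputed as twice the observed effect-allele
frequency.  The LRT uses Gaussian OLS log-likelihoods and a chi-square
reference with one degree of freedom per added pathway×E term;
near-duplicate score columns (|r| > 0.999) are dropped from the joint model
with a log message to keep it full rank.

The GWIS covariate preset (`methods`: age, age², sex, gPCs) and the PGS-test
preset (`results`: adds age×sex) are both shipped and config-driven.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes; it is
the package's study substrate, not a haplotype simulator.

* **Genotypes.** Biallelic common SNPs in LD blocks.  Within a block each of
  the two haplotypes per individual is a latent AR(1) Gaussian series
  (parameter `ld_rho`) thresholded at the MAF quantile; dosages are hard
  Binomial(2, maf) counts and blocks are mutually independent.  An optional
  fractional-dosage noise flag exercises the scoring path with imputed-style
  dosages.  This gives clumping realistic correlated neighbors while keeping
  every oracle exact; it does not model recombination maps, haplotype
  sharing, or ancestry structure.
* **Annotations.** Each chromosome's variants are split into consecutive
  runs; each gene spans one run (so every gene maps variants), strands
  alternate.  Pathways draw `round(overlap_fraction × genes_per_pathway)`
  genes from a common shared pool and the rest from exclusive slices;
  overlap 0 gives pairwise-disjoint sets.
* **Covariates and exposure.** age ~ U(40, 70), sex ~ Bernoulli(0.5), age²,
  age×sex, and the top-k principal components of the standardized dosages
  (computed on an evenly thinned subset of up to 256 variants, the analog of
  running PCA on an LD-pruned panel).  The exposure is standard normal,
  optionally correlated with a chosen covariate by
  `E = r·z + sqrt(1−r²)·w`; a BMI-like affine rescale is cosmetic.
* **Phenotype.**
  `Y = Σ β_j g_j + α_E·E + Σ_{j∈S} γ_j g_j E + c'δ + ε`, where S is the
  variant set of the designated causal pathways obtained through the same
  annotation windows the pipeline uses (so the truth record is closed under
  the pipeline's own variant→gene→pathway chain).  β is drawn N(0, 1) on a
  configured fraction of variants and scaled so the main-genetic share of
  the core variance (main + interaction + noise) equals `h2_main`; γ is
  proportional to β within S by default — interactions as amplification of
  main effects — with an independent mode for robustness checks, scaled to
  `var_gxe`.  With all genetic shares zero, var(Y) = `noise_sd²`.

What passing tests on this generator do **not** show: behavior under
realistic LD decay, rare variants, ancestry confounding, binary traits, or
assortative structure.  The generator's role is to make every pipeline stage
verifiable against exact oracles and to express the qualitative power
claim, not to reproduce any cohort's magnitudes.

## Evaluation studies and problem sizes

Two Monte-Carlo studies characterize the pPGS×E test; the package's test
suite and `scripts/acceptance.py` both run them at the same sizes.

* **Size (type-I error).**  1,000 null tests at n = 5,000: 20 independently
  simulated cohorts (100 variants in 10 LD blocks, 10 disjoint two-gene
  pathways, h² = 0.2, no interaction anywhere) × 50 independent
  phenotype/exposure redraws each.  Genotypes and the trained pathway score
  are held fixed within a cohort; since the regression's size is a statement
  conditional on the design, redrawing Y and E draws fresh, independent test
  statistics.  Expected empirical rejection at nominal 0.05: within
  Monte-Carlo error of 0.05.
* **Power ordering.**  200 replicates at n = 20,000 with 500 variants in 20
  LD blocks, 25 disjoint two-gene pathways, h² = 0.25 spread over all
  variants, and interaction variance 0.02 confined to one pathway covering
  ~4% of the causal main-effect variants (γ ∝ β inside it).  Per replicate
  the full chain runs: GWAS → per-pathway P&T → all pPGS×E tests, plus a
  GWIS restricted to the causal pathway's variants.  Reported: how often the
  causal pathway ranks first among pathways, and mean −log₁₀p for the causal
  pPGS×E, the gwPGS×E, and the best within-pathway single-variant GWIS hit.
  The expected ordering — pathway score strongest, genome-wide score weakest
  — is the motivating property of pathway-level testing: the pathway score
  aggregates the entire interaction signal while the genome-wide score
  dilutes it across ~25× more variance.

These sizes are the package's desk-scale study conditions; they verify the
method's qualitative claims and calibration, not any cohort-specific
magnitudes.

## Numerical choices and degenerate inputs

* Constant genotype columns yield NA summary rows, never a crash; a constant
  exposure is an error (rank-deficient design).
* Constant (e.g. empty-pathway) scores yield NA interaction rows in batch
  testing and a typed error in the single-score API.
* Zero significant pathways: `n_eff` is defined as 0 with a flag, and the
  unexplained fraction is undefined (error).
* Strict inequalities at every published threshold (MAF, INFO, P&T p, 5e-8).
* Unexplained percentages round half-up to integer percent for report
  parity; exact fractions are kept in machine output.
* Eigenvalues are clipped at zero before forming n_eff (guards tiny negative
  round-off).

## Known limitations

No mixed-model relatedness correction, no binary traits, no X chromosome, no
cross-dataset allele harmonization beyond flip detection, no permutation
based multiple-testing control for correlated pathways (the Bonferroni
correction is conservative when pathways overlap), and no functional
(eQTL-style) variant-to-gene mapping — assignments are purely positional.
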