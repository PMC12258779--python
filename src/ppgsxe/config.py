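"""Configuration dataclasses for the synthetic cohort, clumping, and the pipeline.

All distances are base pairs (1-based, fully closed intervals), frequencies are
allele frequencies in (0, 0.5], and variance parameters are proportions of the
core trait variance (genetic main + interaction + noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

__all__ = ["ConfigurationError", "SimConfig", "ClumpSpec", "ScanSpec", "PipelineConfig"]


class ConfigurationError(ValueError):
    """Raised when a configuration value is out of its documented range."""


# Covariate presets: the interaction tests add age_sex on top of the scan set.
COVARIATE_PRESETS = {
    "methods": ("age", "age2", "sex"),
    "results": ("age", "age2", "sex", "age_sex"),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    The generative model is

        Y = sum_j beta_j g_j + alpha_E * E + sum_{j in S} gamma_j g_j * E
            + c' delta + eps,

    where S is the set of variants mapping (through the gene windows) into the
    designated causal pathways.  ``h2_main`` and ``var_gxe`` are the variance
    shares of the genetic main-effect and interaction components relative to
    the core variance (main + interaction + noise); with both zero the trait
    is pure noise of variance ``noise_sd**2``.
    """

    n_individuals: int = 5000
    n_chromosomes: int = 2
    n_blocks_per_chrom: int = 8
    variants_per_block: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.8
    n_genes: int = 32
    genes_per_pathway: int = 2
    n_pathways: int = 16
    pathway_overlap_fraction: float = 0.0
    causal_pathways: tuple[str, ...] = ("PWY_001",)
    h2_main: float = 0.2
    var_gxe: float = 0.02
    alpha_E: float = 0.1
    gamma_mode: str = "proportional"
    noise_sd: float = 1.0
    seed: int = 0

    # Implementation knobs (defaults documented in docs/methods.md).
    main_causal_fraction: float = 1.0
    n_pcs: int = 4
    exposure_corr_covariate: Optional[str] = None
    exposure_corr: float = 0.0
    # cosmetic affine transform of the standardized exposure (e.g. BMI-like 27 + 4.5*E)
    exposure_mean: float = 0.0
    exposure_scale: float = 1.0
    ambiguous_fraction: float = 0.05
    fractional_dosage_noise: float = 0.0
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.1, "sex": 0.1}
    )
    # Physical layout (bp).
    variant_spacing: int = 2000
    block_gap: int = 200_000
    gene_length: int = 20_000

    def validate(self) -> None:
        if min(self.n_individuals, self.n_chromosomes, self.n_blocks_per_chrom,
               self.variants_per_block, self.n_genes, self.n_pathways,
               self.genes_per_pathway) <= 0:
            raise ConfigurationError("all counts must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigurationError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        for name in ("pathway_overlap_fraction", "h2_main", "var_gxe",
                     "main_causal_fraction", "ambiguous_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.h2_main + self.var_gxe >= 1.0:
            raise ConfigurationError("h2_main + var_gxe must be < 1")
        if self.gamma_mode not in ("proportional", "independent"):
            raise ConfigurationError(f"unknown gamma_mode {self.gamma_mode!r}")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")

    @property
    def n_variants(self) -> int:
        return self.n_chromosomes * self.n_blocks_per_chrom * self.variants_per_block

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["causal_pathways"] = list(self.causal_pathways)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "causal_pathways" in d:
            d["causal_pathways"] = tuple(d["causal_pathways"])
        return cls(**d)


@dataclass
class ClumpSpec:
    """Pruning-and-thresholding parameters.

    Defaults mirror the published analysis: p-value threshold 0.001 (5e-8 as
    the stricter preset), clumping radius 1 Mb, r^2 threshold 0.1, and an LD
    reference panel of up to 20,000 individuals.
    """

    p_threshold: float = 1e-3
    radius_bp: int = 1_000_000
    r2_max: float = 0.1
    ld_panel: Optional[Sequence[int]] = None
    ld_panel_size: int = 20_000
    ld_panel_seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.p_threshold <= 1.0):
            raise ConfigurationError(f"p_threshold must be in (0, 1], got {self.p_threshold}")
        if self.radius_bp <= 0:
            raise ConfigurationError("radius_bp must be positive")
        if not (0.0 <= self.r2_max <= 1.0):
            raise ConfigurationError(f"r2_max must be in [0, 1], got {self.r2_max}")
        if self.ld_panel is not None and len(self.ld_panel) == 0:
            raise ConfigurationError("ld_panel must be non-empty when given")


@dataclass
class ScanSpec:
    """Options for the per-variant association scans."""

    mode: str = "gwas"  # "gwas" or "gwis"
    covariate_preset: str = "methods"
    include_e_by_gpc: bool = True
    robust_se: bool = True
    robust_kind: str = "HC0"  # HC0 | HC1 | HC3
    missing_dosage_policy: str = "mean_impute"  # or "drop"

    def validate(self) -> None:
        if self.mode not in ("gwas", "gwis"):
            raise ConfigurationError(f"unknown scan mode {self.mode!r}")
        if self.covariate_preset not in COVARIATE_PRESETS:
            raise ConfigurationError(f"unknown covariate preset {self.covariate_preset!r}")
        if self.robust_kind not in ("HC0", "HC1", "HC3"):
            raise ConfigurationError(f"unknown robust_kind {self.robust_kind!r}")
        if self.missing_dosage_policy not in ("mean_impute", "drop"):
            raise ConfigurationError(
                f"unknown missing_dosage_policy {self.missing_dosage_policy!r}")

    def covariate_columns(self, n_pcs: int) -> list[str]:
        cols = list(COVARIATE_PRESETS[self.covariate_preset])
        cols += [f"gPC{i + 1}" for i in range(n_pcs)]
        return cols


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (synthetic mode when sim is set)."""

    outdir: str = "ppgsxe_run"
    sim: Optional[SimConfig] = None
    # Non-synthetic mode input paths.
    genotypes: Optional[str] = None
    variants: Optional[str] = None
    genes: Optional[str] = None
    gmt: Optional[str] = None
    phenotype: Optional[str] = None
    exposure: Optional[str] = None
    covariates: Optional[str] = None

    maf_min: float = 0.01
    info_min: float = 0.5
    upstream_bp: int = 2000
    downstream_bp: int = 1000
    clump: ClumpSpec = field(default_factory=ClumpSpec)
    covariate_preset: str = "results"
    alpha: float = 0.05
    gwis_threshold: float = 5e-8
    locus_radius_bp: int = 500_000
    explain_window_bp: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if self.sim is None:
            missing = [k for k in ("genotypes", "variants", "genes", "gmt",
                                   "phenotype", "exposure", "covariates")
                       if getattr(self, k) is None]
            if missing:
                raise ConfigurationError(
                    f"non-synthetic mode requires input paths: {', '.join(missing)}")
        else:
            self.sim.validate()
        self.clump.validate()
        for name in ("maf_min", "info_min", "alpha", "gwis_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if min(self.upstream_bp, self.downstream_bp) < 0:
            raise ConfigurationError("annotation windows must be non-negative")
        if min(self.locus_radius_bp, self.explain_window_bp) <= 0:
            raise ConfigurationError("locus radius and explain window must be positive")
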