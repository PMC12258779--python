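"""Pruning-and-thresholding polygenic scores, genome-wide and per pathway.

Clumping is the greedy PLINK/PRSice-style procedure: among variants passing
the p-value threshold, repeatedly take the smallest-p remaining variant as an
index and remove every same-chromosome variant within the clumping radius
whose dosage r^2 with the index (computed on the LD reference panel) exceeds
the r^2 threshold.  Ties on p break by (chrom, pos).  Weights are the GWAS
main-effect betas of the index variants; a score is the weighted sum of
effect-allele dosages, with allele flips handled by g -> 2 - g.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import ClumpSpec
from .io import GenotypeMatrix, ScoreMatrix, WeightSet

log = logging.getLogger(__name__)

__all__ = ["remove_ambiguous", "ld_panel_indices", "clump", "build_weights",
           "score", "build_all_scores", "GENOME_WIDE"]

GENOME_WIDE = "genome_wide"
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


def remove_ambiguous(variants: pd.DataFrame) -> pd.DataFrame:
    """Drop strand-ambiguous (A/T or C/G) variants; order preserved."""
    pairs = [{a, b} for a, b in zip(variants["allele_other"], variants["allele_effect"])]
    keep = [p not in _AMBIGUOUS for p in pairs]
    removed = len(keep) - sum(keep)
    if removed:
        log.info("removed %d ambiguous (A/T or C/G) variant(s)", removed)
    return variants.loc[keep].reset_index(drop=True)


def ld_panel_indices(n_individuals: int, spec: ClumpSpec) -> np.ndarray:
    """LD reference panel: explicit indices or a seeded random subset."""
    if spec.ld_panel is not None:
        return np.asarray(list(spec.ld_panel), dtype=int)
    size = min(n_individuals, spec.ld_panel_size)
    rng = np.random.default_rng(spec.ld_panel_seed)
    return np.sort(rng.choice(n_individuals, size=size, replace=False))


def _panel_dosages(genotypes: GenotypeMatrix, panel: np.ndarray) -> np.ndarray:
    """Mean-imputed panel dosages for r^2 computation."""
    D = genotypes.dosages[panel].astype(float, copy=True)
    miss = np.isnan(D)
    if miss.any():
        mean = np.nanmean(D, axis=0)
        idx = np.where(miss)
        D[idx] = mean[idx[1]]
    return D


def clump(sumstats: pd.DataFrame, genotypes: GenotypeMatrix,
          variants: pd.DataFrame, spec: ClumpSpec,
          restrict_to: set | frozenset | None = None,
          panel_dosages: np.ndarray | None = None) -> list[str]:
    """Greedy p-ordered LD clumping; returns index-variant IDs in pick order.

    ``panel_dosages`` lets callers that clump repeatedly (one pass per
    pathway) reuse the mean-imputed LD-panel matrix.
    """
    spec.validate()
    ss = sumstats
    if restrict_to is not None:
        ss = ss[ss["variant_id"].isin(restrict_to)]
    p = ss["p_main"].to_numpy(dtype=float)
    ss = ss.loc[np.nan_to_num(p, nan=np.inf) < spec.p_threshold]
    if ss.empty:
        log.info("clump: no variant passes p < %g", spec.p_threshold)
        return []
    ss = ss.sort_values(["p_main", "chrom", "pos"], kind="stable").reset_index(drop=True)

    col_of = {v: j for j, v in enumerate(genotypes.variant_ids)}
    missing = [v for v in ss["variant_id"] if v not in col_of]
    if missing:
        raise ValueError(f"summary statistics cover variants absent from the "
                         f"genotype data, e.g. {missing[0]!r}")
    if panel_dosages is not None:
        D = panel_dosages
    else:
        panel = ld_panel_indices(genotypes.n_individuals, spec)
        D = _panel_dosages(genotypes, panel)

    vid = ss["variant_id"].to_numpy()
    chrom = ss["chrom"].to_numpy()
    pos = ss["pos"].to_numpy()

    # center+normalize the candidate columns once; r then is a dot product
    C = D[:, [col_of[v] for v in vid]].astype(float)
    C -= C.mean(axis=0)
    norm = np.sqrt(np.einsum("ij,ij->j", C, C))
    norm[norm == 0] = np.inf  # constant column: r := 0 against everything

    alive = np.ones(len(ss), dtype=bool)
    picked: list[str] = []
    for i in range(len(ss)):
        if not alive[i]:
            continue
        picked.append(vid[i])
        alive[i] = False
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= spec.radius_bp)
        idx = np.where(near)[0]
        if idx.size:
            r = (C[:, i] @ C[:, idx]) / (norm[i] * norm[idx])
            alive[idx[r ** 2 > spec.r2_max]] = False
    return picked


def build_weights(sumstats: pd.DataFrame, index_variants: list[str],
                  score_name: str, p_threshold: float) -> WeightSet:
    """Attach GWAS betas (on the effect allele) to the clumped index variants."""
    ss = sumstats.set_index("variant_id")
    rows = [(v, ss.at[v, "allele_effect"], float(ss.at[v, "beta_main"]))
            for v in index_variants]
    entries = pd.DataFrame(rows, columns=["variant_id", "allele_effect", "weight"])
    return WeightSet(score_name=score_name, p_threshold=p_threshold, entries=entries)


def score(weights: WeightSet, genotypes: GenotypeMatrix,
          variants: pd.DataFrame) -> np.ndarray:
    """score_i = sum over weight entries of weight * effect-allele dosage.

    If the genotype data's effect allele is the weight's "other" allele the
    dosage is flipped (2 - g).  Missing dosages are imputed as twice the
    observed effect-allele frequency.  Weight variants absent from the
    genotype data are logged and skipped; an allele pair that matches neither
    orientation is an error.
    """
    col_of = {v: j for j, v in enumerate(genotypes.variant_ids)}
    vt = variants.set_index("variant_id")
    cols, signed_w, offsets = [], [], []
    for v, allele, w in weights.entries.itertuples(index=False):
        if v not in col_of:
            log.warning("score %s: variant %s absent from genotypes; skipped",
                        weights.score_name, v)
            continue
        eff, oth = vt.at[v, "allele_effect"], vt.at[v, "allele_other"]
        if allele == eff:
            cols.append(col_of[v]); signed_w.append(w); offsets.append(0.0)
        elif allele == oth:
            # flipped orientation: dosage of the weight's allele is 2 - g
            cols.append(col_of[v]); signed_w.append(-w); offsets.append(2.0 * w)
        else:
            raise ValueError(
                f"variant {v}: weight effect allele {allele!r} matches "
                f"neither genotype allele ({oth!r}/{eff!r})")
    if not cols:
        return np.zeros(genotypes.n_individuals)
    G = genotypes.dosages[:, cols].astype(float, copy=True)
    miss = np.isnan(G)
    if miss.any():
        af2 = np.nanmean(G, axis=0)  # = 2 x effect-allele frequency, observed
        idx = np.where(miss)
        G[idx] = af2[idx[1]]
    return G @ np.asarray(signed_w) + float(np.sum(offsets))


def build_all_scores(sumstats: pd.DataFrame, genotypes: GenotypeMatrix,
                     variants: pd.DataFrame,
                     pathway_variant_sets: dict[str, frozenset],
                     spec: ClumpSpec,
                     individual_ids: list[str] | None = None
                     ) -> tuple[ScoreMatrix, list[WeightSet]]:
    """One clump+weight+score pass per pathway plus the genome-wide pass."""
    cols: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    weight_sets: list[WeightSet] = []
    panel = ld_panel_indices(genotypes.n_individuals, spec)
    D = _panel_dosages(genotypes, panel)

    def one(name: str, restrict: frozenset | None) -> None:
        idx = clump(sumstats, genotypes, variants, spec, restrict_to=restrict,
                    panel_dosages=D)
        ws = build_weights(sumstats, idx, name, spec.p_threshold)
        weight_sets.append(ws)
        cols[name] = score(ws, genotypes, variants)
        counts[name] = len(ws)

    one(GENOME_WIDE, None)
    for name, vs in pathway_variant_sets.items():
        one(name, vs)

    ids = individual_ids if individual_ids is not None else genotypes.individual_ids
    values = pd.DataFrame(cols, index=ids)
    return ScoreMatrix(values=values, variant_counts=counts), weight_sets
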