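"""PGS x E interaction tests, multiple-testing control, the nested LRT, and
the effective number of correlated discoveries.

Each score is tested marginally in
``Y = b0 + b1*score + b2*E + b3*(score x E) + C'd (+ E x gPC terms)``
with Y, score and E standardized in-sample to unit SD, so ``b3`` is reported
in SD_Y per SD_score per SD_E — the field's usual reporting convention for
PGS x E effects.  Pathway scores are judged against a Bonferroni threshold of
alpha divided by the number of pathway scores tested; the genome-wide score
is tested too but judged at alpha.

The LRT compares the Gaussian OLS likelihoods of a restricted model (all
covariates, main effects for every score, interaction for the genome-wide
score only) against the full model that adds every pathway-score x E term;
2*(llf_full - llf_restricted) is referred to chi-square with one degree of
freedom per added interaction term.

The effective discovery count discounts correlated pathway scores:
``n_eff = (sum lambda)^2 / sum lambda^2`` over the eigenvalues of the
correlation matrix of the significant scores' columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import COVARIATE_PRESETS
from .io import ScoreMatrix
from .pgs import GENOME_WIDE

log = logging.getLogger(__name__)

__all__ = ["InteractionResult", "LrtResult", "EffectiveCount",
           "DegenerateScoreError", "pgs_by_e_test", "test_all",
           "lrt_full_vs_restricted", "effective_count", "results_table"]


class DegenerateScoreError(ValueError):
    """A score column is constant and cannot be standardized or tested."""


@dataclass
class InteractionResult:
    score_name: str
    n: int
    beta_int: float          # SD_Y per SD_score per SD_E
    se_int: float
    p_int: float
    beta_main_score: float
    threshold_used: float = np.nan
    significant: bool = False


@dataclass
class LrtResult:
    loglik_restricted: float
    loglik_full: float
    statistic: float
    df: int
    p: float
    dropped_scores: tuple[str, ...] = ()


@dataclass
class EffectiveCount:
    eigenvalues: np.ndarray
    n_eff: float
    empty: bool = False


def _std(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    s = x.std()
    if s == 0:
        raise DegenerateScoreError(f"{what} is constant; cannot standardize")
    return (x - x.mean()) / s


def _interaction_design(score_std: np.ndarray, e_std: np.ndarray,
                        covariates: pd.DataFrame, covariate_preset: str,
                        include_e_by_gpc: bool) -> pd.DataFrame:
    n_pcs = sum(c.startswith("gPC") for c in covariates.columns)
    cov_cols = [c for c in COVARIATE_PRESETS[covariate_preset] if c in covariates.columns]
    cov_cols += [f"gPC{i + 1}" for i in range(n_pcs)]
    X = pd.DataFrame({"const": np.ones(len(score_std)),
                      "score": score_std, "E": e_std,
                      "score_x_E": score_std * e_std})
    for c in cov_cols:
        X[c] = covariates[c].to_numpy(dtype=float)
    if include_e_by_gpc:
        for i in range(n_pcs):
            X[f"E_x_gPC{i + 1}"] = e_std * covariates[f"gPC{i + 1}"].to_numpy(dtype=float)
    return X


def pgs_by_e_test(score_col: np.ndarray, phenotype: np.ndarray,
                  exposure: np.ndarray, covariates: pd.DataFrame,
                  include_e_by_gpc: bool = True,
                  covariate_preset: str = "results",
                  score_name: str = "score") -> InteractionResult:
    """Marginal PGS x E regression; model-based SE and t-reference p-value."""
    y = _std(phenotype, "phenotype")
    s = _std(score_col, f"score {score_name!r}")
    e = _std(exposure, "exposure")
    X = _interaction_design(s, e, covariates, covariate_preset, include_e_by_gpc)
    fit = sm.OLS(y, X).fit()
    return InteractionResult(
        score_name=score_name,
        n=len(y),
        beta_int=float(fit.params["score_x_E"]),
        se_int=float(fit.bse["score_x_E"]),
        p_int=float(fit.pvalues["score_x_E"]),
        beta_main_score=float(fit.params["score"]),
    )


def test_all(scores: ScoreMatrix, phenotype: np.ndarray, exposure: np.ndarray,
             covariates: pd.DataFrame, alpha: float = 0.05,
             include_e_by_gpc: bool = True, covariate_preset: str = "results"
             ) -> tuple[list[InteractionResult], float]:
    """Test every score; Bonferroni over the pathway scores only.

    The genome-wide score is judged at alpha; constant scores (e.g. empty
    pathways) yield NA rows rather than aborting the batch.
    """
    pathway_names = [n for n in scores.score_names if n != GENOME_WIDE]
    threshold = alpha / len(pathway_names) if pathway_names else alpha
    results: list[InteractionResult] = []
    for name in scores.score_names:
        judged_at = alpha if name == GENOME_WIDE else threshold
        try:
            r = pgs_by_e_test(scores.values[name].to_numpy(), phenotype, exposure,
                              covariates, include_e_by_gpc, covariate_preset,
                              score_name=name)
        except DegenerateScoreError:
            log.warning("score %s is constant; emitting NA result", name)
            r = InteractionResult(score_name=name, n=len(phenotype),
                                  beta_int=np.nan, se_int=np.nan, p_int=np.nan,
                                  beta_main_score=np.nan)
        r.threshold_used = judged_at
        r.significant = bool(np.nan_to_num(r.p_int, nan=1.0) < judged_at)
        results.append(r)
    return results, threshold


def results_table(results: list[InteractionResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "score_name": r.score_name, "n": r.n, "beta_int": r.beta_int,
        "se_int": r.se_int, "p_int": r.p_int,
        "beta_main_score": r.beta_main_score,
        "threshold_used": r.threshold_used, "significant": r.significant,
    } for r in results])


def _gaussian_ols_llf(y: np.ndarray, X: np.ndarray) -> float:
    return float(sm.OLS(y, X).fit().llf)


def lrt_full_vs_restricted(scores: ScoreMatrix, phenotype: np.ndarray,
                           exposure: np.ndarray, covariates: pd.DataFrame,
                           include_e_by_gpc: bool = True,
                           covariate_preset: str = "results",
                           dedup_r: float = 0.999) -> LrtResult:
    """Do the pathway-score x E terms jointly improve on the genome-wide one?

    Restricted: covariates + all score main effects + genome-wide x E.
    Full: restricted + one x E term per pathway score.  Near-duplicate
    pathway columns (|r| > dedup_r with an earlier column or the genome-wide
    score) are dropped with a log message to keep the design full rank.
    """
    y = _std(phenotype, "phenotype")
    e = _std(exposure, "exposure")
    gw = _std(scores.values[GENOME_WIDE].to_numpy(), GENOME_WIDE)

    kept: list[str] = []
    dropped: list[str] = []
    cols: list[np.ndarray] = []
    for name in scores.score_names:
        if name == GENOME_WIDE:
            continue
        try:
            s = _std(scores.values[name].to_numpy(), name)
        except DegenerateScoreError:
            dropped.append(name)
            continue
        r_prev = [abs(np.corrcoef(s, c)[0, 1]) for c in cols + [gw]]
        if any(r > dedup_r for r in r_prev):
            dropped.append(name)
            continue
        kept.append(name)
        cols.append(s)
    if dropped:
        log.info("LRT: dropped %d near-duplicate/degenerate score column(s): %s",
                 len(dropped), ", ".join(dropped))

    X = _interaction_design(gw, e, covariates, covariate_preset, include_e_by_gpc)
    for name, s in zip(kept, cols):
        X[f"main_{name}"] = s
    Xr = np.asarray(X, dtype=float)
    Xf = np.column_stack([Xr] + [s * e for s in cols]) if cols else Xr

    if Xf.shape[1] > Xf.shape[0]:
        raise ValueError("full model has more parameters than observations")
    llr = _gaussian_ols_llf(y, Xr)
    llf = _gaussian_ols_llf(y, Xf)
    df = len(kept)
    statistic = max(0.0, 2.0 * (llf - llr))
    p = 1.0 if df == 0 else float(stats.chi2.sf(statistic, df))
    return LrtResult(loglik_restricted=llr, loglik_full=llf,
                     statistic=statistic, df=df, p=p,
                     dropped_scores=tuple(dropped))


def effective_count(score_values: pd.DataFrame) -> EffectiveCount:
    """(sum lambda)^2 / sum lambda^2 over eigenvalues of the score correlation.

    Columns are standardized before the eigen-decomposition (equivalently the
    correlation matrix is used).  Zero significant pathways is defined as
    n_eff = 0 with an ``empty`` flag.
    """
    if score_values.shape[1] == 0:
        return EffectiveCount(eigenvalues=np.array([]), n_eff=0.0, empty=True)
    M = np.asarray(score_values, dtype=float)
    sd = M.std(axis=0)
    if (sd == 0).any():
        bad = list(score_values.columns[sd == 0])
        raise DegenerateScoreError(f"constant score column(s): {', '.join(map(str, bad))}")
    corr = np.corrcoef(M, rowvar=False)
    corr = np.atleast_2d(corr)
    lam = np.linalg.eigvalsh(corr)[::-1]
    lam = np.clip(lam, 0.0, None)
    n_eff = float(lam.sum() ** 2 / (lam ** 2).sum())
    return EffectiveCount(eigenvalues=lam, n_eff=n_eff)
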