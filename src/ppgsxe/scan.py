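"""Per-variant association scans.

GWAS fits, for each variant g, the linear model  Y = b0 + b1*g + C'd  and
reports b1 with model-based standard errors.  GWIS fits
Y = b0 + b1*g + b2*E + b3*(g*E) + C'd (+ E x gPC terms) and reports both the
main (b1) and interaction (b3) coefficients with heteroskedasticity-robust
sandwich standard errors (HC0 by default).

The per-variant fits are computed by the Frisch-Waugh-Lovell route: the
outcome and the variant-specific regressors are residualized against the
shared covariate block once, after which each variant needs only a 1x1 or
2x2 solve.  Coefficients, residuals, and the corresponding block of the
sandwich covariance are identical to the full-design fit; tests cross-check
against statsmodels on toy data.  p-values use the t reference with the full
model's residual degrees of freedom.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import ScanSpec
from .io import GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = ["run_gwas", "run_gwis", "genomewide_significant"]

_CHUNK = 512


def _fixed_design(covariates: pd.DataFrame, cov_cols: list[str],
                  exposure: np.ndarray | None,
                  include_e_by_gpc: bool) -> np.ndarray:
    n = len(covariates)
    cols = [np.ones(n)]
    for c in cov_cols:
        if c not in covariates.columns:
            raise ValueError(f"covariate column {c!r} not present")
        cols.append(covariates[c].to_numpy(dtype=float))
    if exposure is not None:
        cols.append(exposure)
        if include_e_by_gpc:
            gpc_cols = [c for c in cov_cols if c.startswith("gPC")]
            for c in gpc_cols:
                cols.append(exposure * covariates[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def _residualize(F: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on the fixed design F (via lstsq)."""
    coef, *_ = np.linalg.lstsq(F, M, rcond=None)
    return M - F @ coef


def _q_factor(F: np.ndarray) -> np.ndarray:
    """Thin orthonormal basis of the fixed design, for repeated residualizing."""
    return np.linalg.qr(F, mode="reduced")[0]


def _resid_q(Q: np.ndarray, M: np.ndarray) -> np.ndarray:
    return M - Q @ (Q.T @ M)


def _constant_columns(dosages: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        lo = np.nanmin(dosages, axis=0)
        hi = np.nanmax(dosages, axis=0)
    return ~(hi > lo)


def _prepare_dosages(gm: GenotypeMatrix, policy: str
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-impute missing dosages; return (matrix, n_used, redo_mask).

    The vectorized path always runs on the mean-imputed matrix.  Under the
    "drop" policy, variants with any missing dosage are re-fit per variant on
    their complete rows; ``redo_mask`` marks them.
    """
    G = gm.dosages.astype(float, copy=True)
    miss = np.isnan(G)
    n_used = np.full(G.shape[1], G.shape[0], dtype=int)
    redo = np.zeros(G.shape[1], dtype=bool)
    if miss.any():
        col_mean = np.nanmean(G, axis=0)
        idx = np.where(miss)
        G[idx] = col_mean[idx[1]]
        if policy == "drop":
            redo = miss.any(axis=0)
            n_used = (~miss).sum(axis=0)
    return G, n_used, redo


def _single_fit(y: np.ndarray, F: np.ndarray, V: np.ndarray, robust: bool,
                robust_kind: str) -> tuple[np.ndarray, np.ndarray, int]:
    """Exact OLS of y on [V, F]; returns (coef_V, se_V, df_resid)."""
    X = np.column_stack([V, F])
    n, p = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    coef = XtX_inv @ (X.T @ y)
    e = y - X @ coef
    df = n - p
    k = V.shape[1]
    if robust:
        w = e ** 2
        if robust_kind == "HC1":
            w = w * (n / df)
        elif robust_kind == "HC3":
            h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
            w = w / (1.0 - np.clip(h, 0.0, 1.0 - 1e-10)) ** 2
        V_cov = XtX_inv @ (X.T * w) @ X @ XtX_inv
    else:
        V_cov = XtX_inv * (e @ e / df)
    return coef[:k], np.sqrt(np.diag(V_cov)[:k]), df


def _base_frame(variants: pd.DataFrame) -> pd.DataFrame:
    cols = ["variant_id", "chrom", "pos", "allele_other", "allele_effect", "maf"]
    return variants[cols].reset_index(drop=True).copy()


def run_gwas(genotypes: GenotypeMatrix, variants: pd.DataFrame,
             phenotype: np.ndarray, covariates: pd.DataFrame,
             spec: ScanSpec | None = None) -> pd.DataFrame:
    """Main-effect scan: per variant, OLS of Y on [1, g, C]."""
    spec = spec or ScanSpec(mode="gwas")
    spec.validate()
    n_pcs = sum(c.startswith("gPC") for c in covariates.columns)
    cov_cols = [c for c in spec.covariate_columns(n_pcs) if c in covariates.columns]
    F = _fixed_design(covariates, cov_cols, exposure=None, include_e_by_gpc=False)
    y = np.asarray(phenotype, dtype=float)
    G, n_used, redo = _prepare_dosages(genotypes, spec.missing_dosage_policy)

    n, m = G.shape
    p_full = F.shape[1] + 1
    df_resid = n - p_full
    Q = _q_factor(F)
    yt = _resid_q(Q, y[:, None])[:, 0]
    out = _base_frame(variants)
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pval = np.full(m, np.nan)

    const = _constant_columns(genotypes.dosages)
    for s in range(0, m, _CHUNK):
        sl = slice(s, min(s + _CHUNK, m))
        Gt = _resid_q(Q, G[:, sl])
        gg = np.einsum("ij,ij->j", Gt, Gt)
        gy = Gt.T @ yt
        ok = (gg > 1e-12) & ~const[sl]
        b = np.where(ok, gy / np.where(gg > 0, gg, 1.0), np.nan)
        resid = yt[:, None] - Gt * b[None, :]
        rss = np.einsum("ij,ij->j", resid, resid)
        sigma2 = rss / df_resid
        s_ = np.sqrt(np.where(ok, sigma2 / np.where(gg > 0, gg, 1.0), np.nan))
        beta[sl], se[sl] = b, s_
        with np.errstate(invalid="ignore", divide="ignore"):
            t = b / s_
        pval[sl] = 2 * stats.t.sf(np.abs(t), df_resid)
    if const.any():
        log.warning("%d variant(s) with constant dosage emitted as NA", int(const.sum()))

    for j in np.where(redo & ~const)[0]:
        rows = ~np.isnan(genotypes.dosages[:, j])
        b, s_, df = _single_fit(y[rows], F[rows], genotypes.dosages[rows, j][:, None],
                                robust=False, robust_kind=spec.robust_kind)
        beta[j], se[j] = b[0], s_[0]
        pval[j] = 2 * stats.t.sf(abs(b[0] / s_[0]), df)

    out["n_used"] = n_used
    out["beta_main"] = beta
    out["se_main"] = se
    out["p_main"] = pval
    return out


def run_gwis(genotypes: GenotypeMatrix, variants: pd.DataFrame,
             phenotype: np.ndarray, exposure: np.ndarray,
             covariates: pd.DataFrame, spec: ScanSpec | None = None) -> pd.DataFrame:
    """Interaction scan: per variant, OLS of Y on [1, g, E, g*E, C, E x gPCs].

    Sandwich (robust) SEs for both the g and g*E coefficients; HC0 unless the
    spec requests HC1 (small-sample scaling) or HC3 (leverage-adjusted).
    """
    spec = spec or ScanSpec(mode="gwis")
    spec.validate()
    E = np.asarray(exposure, dtype=float)
    if np.std(E) == 0:
        raise ValueError("exposure is constant; interaction design is rank-deficient")
    n_pcs = sum(c.startswith("gPC") for c in covariates.columns)
    cov_cols = [c for c in spec.covariate_columns(n_pcs) if c in covariates.columns]
    F = _fixed_design(covariates, cov_cols, E, spec.include_e_by_gpc)
    y = np.asarray(phenotype, dtype=float)
    G, n_used, redo = _prepare_dosages(genotypes, spec.missing_dosage_policy)

    n, m = G.shape
    p_full = F.shape[1] + 2
    df_resid = n - p_full
    Q = _q_factor(F)
    yt = _resid_q(Q, y[:, None])[:, 0]
    out = _base_frame(variants)
    res = {k: np.full(m, np.nan) for k in
           ("beta_main", "se_main", "p_main", "beta_int", "se_int", "p_int")}
    const = _constant_columns(genotypes.dosages)

    # FWL projection matrix reused for HC3 leverages of the fixed block
    FtF_inv = np.linalg.pinv(F.T @ F)
    h_fixed = np.einsum("ij,jk,ik->i", F, FtF_inv, F)

    for s in range(0, m, _CHUNK):
        sl = slice(s, min(s + _CHUNK, m))
        Gt = _resid_q(Q, G[:, sl])
        Ht = _resid_q(Q, G[:, sl] * E[:, None])
        a11 = np.einsum("ij,ij->j", Gt, Gt)
        a12 = np.einsum("ij,ij->j", Gt, Ht)
        a22 = np.einsum("ij,ij->j", Ht, Ht)
        b1r = Gt.T @ yt
        b2r = Ht.T @ yt
        det = a11 * a22 - a12 ** 2
        ok = (det > 1e-12) & ~const[sl]
        det_safe = np.where(ok, det, 1.0)
        c1 = (a22 * b1r - a12 * b2r) / det_safe
        c2 = (a11 * b2r - a12 * b1r) / det_safe
        e = yt[:, None] - Gt * c1[None, :] - Ht * c2[None, :]
        if spec.robust_se:
            w = e ** 2
            if spec.robust_kind == "HC1":
                w = w * (n / df_resid)
            elif spec.robust_kind == "HC3":
                # leverage of full design = fixed-block leverage + FWL part
                h_v = (Gt * (a22[None, :] * Gt - a12[None, :] * Ht)
                       + Ht * (a11[None, :] * Ht - a12[None, :] * Gt)) / det_safe[None, :]
                h = np.clip(h_fixed[:, None] + h_v, 0.0, 1.0 - 1e-10)
                w = w / (1.0 - h) ** 2
            m11 = np.einsum("ij,ij->j", Gt * w, Gt)
            m12 = np.einsum("ij,ij->j", Gt * w, Ht)
            m22 = np.einsum("ij,ij->j", Ht * w, Ht)
            # V = A^{-1} M A^{-1}; A^{-1} = [[a22,-a12],[-a12,a11]]/det
            inv11, inv12, inv22 = a22 / det_safe, -a12 / det_safe, a11 / det_safe
            v11 = inv11 * (m11 * inv11 + m12 * inv12) + inv12 * (m12 * inv11 + m22 * inv12)
            v22 = inv12 * (m11 * inv12 + m12 * inv22) + inv22 * (m12 * inv12 + m22 * inv22)
        else:
            rss = np.einsum("ij,ij->j", e, e)
            sigma2 = rss / df_resid
            v11 = sigma2 * a22 / det_safe
            v22 = sigma2 * a11 / det_safe
        se1 = np.sqrt(np.where(ok, v11, np.nan))
        se2 = np.sqrt(np.where(ok, v22, np.nan))
        c1 = np.where(ok, c1, np.nan)
        c2 = np.where(ok, c2, np.nan)
        res["beta_main"][sl], res["se_main"][sl] = c1, se1
        res["beta_int"][sl], res["se_int"][sl] = c2, se2
        with np.errstate(invalid="ignore", divide="ignore"):
            res["p_main"][sl] = 2 * stats.t.sf(np.abs(c1 / se1), df_resid)
            res["p_int"][sl] = 2 * stats.t.sf(np.abs(c2 / se2), df_resid)
    if const.any():
        log.warning("%d variant(s) with constant dosage emitted as NA", int(const.sum()))

    for j in np.where(redo & ~const)[0]:
        rows = ~np.isnan(genotypes.dosages[:, j])
        g = genotypes.dosages[rows, j]
        V = np.column_stack([g, g * E[rows]])
        b, s_, df = _single_fit(y[rows], F[rows], V,
                                robust=spec.robust_se, robust_kind=spec.robust_kind)
        res["beta_main"][j], res["se_main"][j] = b[0], s_[0]
        res["beta_int"][j], res["se_int"][j] = b[1], s_[1]
        res["p_main"][j] = 2 * stats.t.sf(abs(b[0] / s_[0]), df)
        res["p_int"][j] = 2 * stats.t.sf(abs(b[1] / s_[1]), df)

    out["n_used"] = n_used
    for k in ("beta_main", "se_main", "p_main", "beta_int", "se_int", "p_int"):
        out[k] = res[k]
    return out


def genomewide_significant(stats_df: pd.DataFrame, threshold: float = 5e-8
                           ) -> pd.DataFrame:
    """Rows with p_int strictly below the genome-wide threshold."""
    if "p_int" not in stats_df.columns:
        raise ValueError("summary statistics lack a p_int column")
    mask = stats_df["p_int"].to_numpy() < threshold
    return stats_df.loc[np.nan_to_num(mask, nan=False)].reset_index(drop=True)
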