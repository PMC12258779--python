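"""Scan correctness: closed-form OLS oracles, statsmodels cross-checks,
robust-SE behaviour, null calibration, and invariance laws."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from ppgsxe.config import ScanSpec, SimConfig
from ppgsxe.io import GenotypeMatrix
from ppgsxe.scan import genomewide_significant, run_gwas, run_gwis
from ppgsxe.synthetic import simulate_cohort, simulate_genotypes


def _tiny(n=6, m=2, seed=3, missing=False):
    rng = np.random.default_rng(seed)
    d = rng.integers(0, 3, size=(n, m)).astype(float)
    d[:, 0] = [0, 1, 2, 0, 1, 2][:n] if n <= 6 else d[:, 0]
    if missing:
        d[1, 1] = np.nan
    gm = GenotypeMatrix(d, [f"i{k}" for k in range(n)], [f"v{k}" for k in range(m)])
    variants = pd.DataFrame({
        "variant_id": gm.variant_ids, "chrom": "1",
        "pos": 1000 * (1 + np.arange(m)), "allele_other": "A",
        "allele_effect": "G", "maf": 0.3})
    cov = pd.DataFrame({"age": rng.uniform(40, 70, n)})
    cov["age2"] = cov["age"] ** 2
    cov["sex"] = rng.integers(0, 2, n).astype(float)
    y = rng.standard_normal(n)
    e = rng.standard_normal(n)
    return gm, variants, y, e, cov


def test_gwas_equals_normal_equations_on_toy_table():
    """Single-variant fit vs a hand-built 3x3 normal-equations solve."""
    gm, variants, y, _, cov = _tiny(n=6, m=1)
    spec = ScanSpec(mode="gwas", covariate_preset="methods")
    # restrict covariates to one column for the hand solve
    cov1 = cov[["age"]].copy()
    ss = run_gwas(gm, variants, y, cov1, spec)

    X = np.column_stack([np.ones(6), gm.dosages[:, 0], cov1["age"]])
    XtX, Xty = X.T @ X, X.T @ y
    beta = np.linalg.solve(XtX, Xty)
    resid = y - X @ beta
    sigma2 = resid @ resid / (6 - 3)
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[1, 1])
    p = 2 * stats.t.sf(abs(beta[1] / se), 6 - 3)
    assert np.isclose(ss["beta_main"][0], beta[1], rtol=1e-10)
    assert np.isclose(ss["se_main"][0], se, rtol=1e-10)
    assert np.isclose(ss["p_main"][0], p, rtol=1e-10)


def test_gwas_recovers_planted_effect():
    rng = np.random.default_rng(7)
    n = 5000
    g = rng.binomial(2, 0.3, n).astype(float)
    y = 0.5 * g + rng.standard_normal(n)
    gm = GenotypeMatrix(g[:, None], [f"i{k}" for k in range(n)], ["v0"])
    variants = pd.DataFrame({"variant_id": ["v0"], "chrom": "1", "pos": 100,
                             "allele_other": "A", "allele_effect": "G", "maf": 0.3})
    cov = pd.DataFrame(index=range(n))
    ss = run_gwas(gm, variants, y, cov, ScanSpec(mode="gwas"))
    assert abs(ss["beta_main"][0] - 0.5) < 1.96 * ss["se_main"][0]


def test_gwis_matches_statsmodels_all_robust_flavors():
    gm, variants, y, e, cov = _tiny(n=40, m=3, seed=9)
    cov["gPC1"] = np.random.default_rng(1).standard_normal(40)
    for kind in ("HC0", "HC1", "HC3"):
        spec = ScanSpec(mode="gwis", covariate_preset="methods", robust_kind=kind)
        ss = run_gwis(gm, variants, y, e, cov, spec)
        for j in range(3):
            g = gm.dosages[:, j]
            X = pd.DataFrame({
                "const": 1.0, "g": g, "E": e, "gxE": g * e,
                "age": cov["age"], "age2": cov["age2"], "sex": cov["sex"],
                "gPC1": cov["gPC1"], "ExgPC1": e * cov["gPC1"]})
            fit = sm.OLS(y, X).fit(cov_type=kind)
            assert np.isclose(ss["beta_int"][j], fit.params["gxE"], rtol=1e-8)
            assert np.isclose(ss["se_int"][j], fit.bse["gxE"], rtol=1e-6), kind
            assert np.isclose(ss["beta_main"][j], fit.params["g"], rtol=1e-8)


def test_gwas_matches_statsmodels_model_se():
    gm, variants, y, _, cov = _tiny(n=30, m=2, seed=5)
    ss = run_gwas(gm, variants, y, cov, ScanSpec(mode="gwas"))
    for j in range(2):
        X = pd.DataFrame({"const": 1.0, "g": gm.dosages[:, j],
                          "age": cov["age"], "age2": cov["age2"], "sex": cov["sex"]})
        fit = sm.OLS(y, X).fit()
        assert np.isclose(ss["beta_main"][j], fit.params["g"], rtol=1e-9)
        assert np.isclose(ss["se_main"][j], fit.bse["g"], rtol=1e-9)
        assert np.isclose(ss["p_main"][j], fit.pvalues["g"], rtol=1e-9)


def test_null_pvalues_uniform():
    """Many independent null variants: p_main ~ Uniform(0,1) by the KS test."""
    cfg = SimConfig(n_individuals=300, n_chromosomes=2, n_blocks_per_chrom=10,
                    variants_per_block=100, ld_rho=0.0, n_genes=20,
                    n_pathways=2, genes_per_pathway=2, h2_main=0.0,
                    var_gxe=0.0, alpha_E=0.0, seed=31)
    gm, variants = simulate_genotypes(cfg)
    rng = np.random.default_rng(17)
    y = rng.standard_normal(300)
    ss = run_gwas(gm, variants, y, pd.DataFrame(index=range(300)),
                  ScanSpec(mode="gwas"))
    ks = stats.kstest(ss["p_main"], "uniform")
    assert ks.pvalue > 0.01


def test_robust_vs_model_se_agree_under_homoskedasticity():
    cfg = SimConfig(n_individuals=2000, n_chromosomes=1, n_blocks_per_chrom=25,
                    variants_per_block=20, ld_rho=0.0, n_genes=25, n_pathways=2,
                    genes_per_pathway=2, h2_main=0.0, var_gxe=0.0, seed=12)
    gm, variants = simulate_genotypes(cfg)
    rng = np.random.default_rng(4)
    y = rng.standard_normal(2000)
    e = rng.standard_normal(2000)
    cov = pd.DataFrame(index=range(2000))
    robust = run_gwis(gm, variants, y, e, cov,
                      ScanSpec(mode="gwis", robust_se=True))
    model = run_gwis(gm, variants, y, e, cov,
                     ScanSpec(mode="gwis", robust_se=False))
    ratio = (robust["se_int"] / model["se_int"]).to_numpy()
    assert 0.95 < np.nanmean(ratio) < 1.05


def test_planted_interaction_is_top_hit_in_block():
    cfg = SimConfig(n_individuals=10_000, n_chromosomes=1, n_blocks_per_chrom=1,
                    variants_per_block=12, ld_rho=0.8, n_genes=2, n_pathways=1,
                    genes_per_pathway=2, h2_main=0.0, var_gxe=0.0, seed=21)
    gm, variants = simulate_genotypes(cfg)
    rng = np.random.default_rng(8)
    e = rng.standard_normal(10_000)
    target = 5
    y = 0.1 * gm.dosages[:, target] * e + rng.standard_normal(10_000)
    ss = run_gwis(gm, variants, y, e, pd.DataFrame(index=range(10_000)),
                  ScanSpec(mode="gwis"))
    assert int(np.nanargmin(ss["p_int"].to_numpy())) == target


def test_constant_exposure_rejected():
    gm, variants, y, _, cov = _tiny()
    with pytest.raises(ValueError, match="constant"):
        run_gwis(gm, variants, y, np.zeros(6), cov, ScanSpec(mode="gwis"))


def test_constant_genotype_yields_na_row():
    gm, variants, y, e, cov = _tiny(n=20, m=2, seed=2)
    d = gm.dosages.copy()
    d[:, 1] = 1.0
    gm2 = GenotypeMatrix(d, gm.individual_ids, gm.variant_ids)
    ss = run_gwas(gm2, variants, y, cov, ScanSpec(mode="gwas"))
    assert np.isnan(ss["beta_main"][1]) and not np.isnan(ss["beta_main"][0])
    gw = run_gwis(gm2, variants, y, e, cov, ScanSpec(mode="gwis"))
    assert np.isnan(gw["p_int"][1])


def test_scale_equivariance():
    gm, variants, y, e, cov = _tiny(n=50, m=3, seed=13)
    a = run_gwis(gm, variants, y, e, cov, ScanSpec(mode="gwis"))
    b = run_gwis(gm, variants, 3.7 * y, e, cov, ScanSpec(mode="gwis"))
    assert np.allclose(b["beta_int"], 3.7 * a["beta_int"])
    assert np.allclose(b["se_int"], 3.7 * a["se_int"])
    assert np.allclose(b["p_int"], a["p_int"], rtol=1e-9)


def test_exposure_centering_invariance():
    gm, variants, y, e, cov = _tiny(n=50, m=3, seed=14)
    cov["gPC1"] = np.random.default_rng(3).standard_normal(50)
    a = run_gwis(gm, variants, y, e, cov, ScanSpec(mode="gwis"))
    b = run_gwis(gm, variants, y, e - e.mean() + 5.0, cov, ScanSpec(mode="gwis"))
    assert np.allclose(b["beta_int"], a["beta_int"], rtol=1e-7)
    assert np.allclose(b["se_int"], a["se_int"], rtol=1e-6)


def test_missing_policy_drop_vs_statsmodels():
    gm, variants, y, e, cov = _tiny(n=30, m=2, seed=6, missing=True)
    spec = ScanSpec(mode="gwis", missing_dosage_policy="drop")
    ss = run_gwis(gm, variants, y, e, cov, spec)
    assert ss["n_used"][1] == 29
    rows = ~np.isnan(gm.dosages[:, 1])
    g = gm.dosages[rows, 1]
    X = pd.DataFrame({"const": 1.0, "g": g, "E": e[rows], "gxE": g * e[rows],
                      "age": cov.loc[rows, "age"], "age2": cov.loc[rows, "age2"],
                      "sex": cov.loc[rows, "sex"]})
    fit = sm.OLS(y[rows], X).fit(cov_type="HC0")
    assert np.isclose(ss["beta_int"][1], fit.params["gxE"], rtol=1e-8)
    assert np.isclose(ss["se_int"][1], fit.bse["gxE"], rtol=1e-6)


def test_genomewide_significant_strict_threshold():
    df = pd.DataFrame({"variant_id": ["a", "b", "c"], "chrom": "1",
                       "pos": [1, 2, 3], "allele_other": "A",
                       "allele_effect": "G", "maf": 0.2, "n_used": 10,
                       "beta_main": 0.0, "se_main": 1.0, "p_main": 0.5,
                       "beta_int": 0.0, "se_int": 1.0,
                       "p_int": [5e-8, 4.9e-8, 1e-7]})
    out = genomewide_significant(df, 5e-8)
    assert out["variant_id"].tolist() == ["b"]  # exactly 5e-8 is excluded
    assert genomewide_significant(df.assign(p_int=1e-7), 5e-8).empty


def test_null_cohort_no_genomewide_hits():
    cohort = simulate_cohort(SimConfig(
        n_individuals=2000, n_chromosomes=2, n_blocks_per_chrom=10,
        variants_per_block=25, n_genes=20, n_pathways=5, genes_per_pathway=2,
        h2_main=0.0, var_gxe=0.0, seed=77))
    ss = run_gwis(cohort.genotypes, cohort.variants, cohort.phenotype,
                  cohort.exposure, cohort.covariates, ScanSpec(mode="gwis"))
    assert genomewide_significant(ss, 5e-8).empty
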