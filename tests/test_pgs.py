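"""P&T construction: ambiguous-variant removal, clumping vs an exhaustive
greedy oracle, scoring laws (flip invariance, linearity), monotonicity."""

import numpy as np
import pandas as pd
import pytest

from ppgsxe.config import ClumpSpec, SimConfig
from ppgsxe.io import GenotypeMatrix, WeightSet
from ppgsxe.pgs import (GENOME_WIDE, build_all_scores, build_weights, clump,
                        remove_ambiguous, score)
from ppgsxe.synthetic import simulate_genotypes


def _variants(n, rng=None, chrom="1", spacing=10_000):
    rng = rng or np.random.default_rng(0)
    pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    rows = []
    for i in range(n):
        a, b = pairs[rng.integers(len(pairs))]
        rows.append((f"v{i}", chrom, 1 + i * spacing, a, b, 0.3))
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos",
                                       "allele_other", "allele_effect", "maf"])


def _sumstats(variants, p, beta=None):
    df = variants.copy()
    df["n_used"] = 100
    df["beta_main"] = beta if beta is not None else np.linspace(0.1, 0.5, len(df))
    df["se_main"] = 0.01
    df["p_main"] = p
    return df


def test_remove_ambiguous_examples():
    df = pd.DataFrame({
        "variant_id": ["v1", "v2", "v3", "v4"], "chrom": "1",
        "pos": [1, 2, 3, 4],
        "allele_other": ["A", "A", "G", "T"],
        "allele_effect": ["T", "G", "C", "A"],
        "maf": 0.2})
    out = remove_ambiguous(df)
    assert out["variant_id"].tolist() == ["v2"]  # A/T, G/C, T/A all ambiguous


def test_remove_ambiguous_counts_match_predicate_oracle(rng):
    alleles = np.array(list("ACGT"))
    n = 300
    oth = rng.choice(alleles, n)
    eff = np.array([rng.choice([a for a in alleles if a != o]) for o in oth])
    df = pd.DataFrame({"variant_id": [f"v{i}" for i in range(n)], "chrom": "1",
                       "pos": np.arange(1, n + 1), "allele_other": oth,
                       "allele_effect": eff, "maf": 0.2})
    out = remove_ambiguous(df)
    keep = sum({o, e} not in ({"A", "T"}, {"C", "G"}) for o, e in zip(oth, eff))
    assert len(out) == keep


def _clump_oracle(sumstats, dosages, spec):
    """Exhaustive greedy re-implementation with fresh pairwise r^2 each step."""
    ss = sumstats[sumstats["p_main"] < spec.p_threshold]
    ss = ss.sort_values(["p_main", "chrom", "pos"], kind="stable")
    remaining = list(ss.itertuples(index=False))
    col = {v: i for i, v in enumerate(sumstats["variant_id"])}
    picked = []
    while remaining:
        lead = remaining.pop(0)
        picked.append(lead.variant_id)
        survivors = []
        for r in remaining:
            if r.chrom == lead.chrom and abs(r.pos - lead.pos) <= spec.radius_bp:
                r2 = np.corrcoef(dosages[:, col[lead.variant_id]],
                                 dosages[:, col[r.variant_id]])[0, 1] ** 2
                if r2 > spec.r2_max:
                    continue
            survivors.append(r)
        remaining = survivors
    return picked


def test_clump_dominance_of_correlated_pair():
    g = np.random.default_rng(0).binomial(2, 0.3, 200).astype(float)
    gm = GenotypeMatrix(np.column_stack([g, g]), [f"i{k}" for k in range(200)],
                        ["v0", "v1"])
    variants = _variants(2, spacing=10_000)
    ss = _sumstats(variants, p=[1e-6, 1e-4])
    spec = ClumpSpec(p_threshold=1e-3, radius_bp=1_000_000, r2_max=0.1)
    assert clump(ss, gm, variants, spec) == ["v0"]


def test_clump_radius_bound_keeps_distant_duplicates():
    g = np.random.default_rng(0).binomial(2, 0.3, 200).astype(float)
    gm = GenotypeMatrix(np.column_stack([g, g]), [f"i{k}" for k in range(200)],
                        ["v0", "v1"])
    variants = _variants(2, spacing=2_000_000)  # 2 Mb apart, r^2 = 1
    ss = _sumstats(variants, p=[1e-6, 1e-4])
    spec = ClumpSpec(p_threshold=1e-3, radius_bp=1_000_000, r2_max=0.1)
    assert clump(ss, gm, variants, spec) == ["v0", "v1"]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_clump_matches_exhaustive_oracle(seed):
    cfg = SimConfig(n_individuals=400, n_chromosomes=2, n_blocks_per_chrom=5,
                    variants_per_block=5, ld_rho=0.85, n_genes=4, n_pathways=2,
                    genes_per_pathway=2, seed=seed)
    gm, variants = simulate_genotypes(cfg)
    rng = np.random.default_rng(seed + 100)
    ss = _sumstats(variants, p=rng.uniform(0, 2e-3, len(variants)))
    spec = ClumpSpec(p_threshold=1e-3, radius_bp=50_000, r2_max=0.2)
    got = clump(ss, gm, variants, spec)
    want = _clump_oracle(ss, gm.dosages, spec)
    assert got == want


def test_clumped_leads_pairwise_below_r2(small_cohort):
    rng = np.random.default_rng(0)
    variants = small_cohort.variants
    ss = _sumstats(variants, p=rng.uniform(0, 5e-3, len(variants)))
    spec = ClumpSpec(p_threshold=1e-2, radius_bp=100_000, r2_max=0.1)
    picked = clump(ss, small_cohort.genotypes, variants, spec)
    col = {v: i for i, v in enumerate(small_cohort.genotypes.variant_ids)}
    pos = variants.set_index("variant_id")
    for i, a in enumerate(picked):
        for b in picked[i + 1:]:
            if pos.at[a, "chrom"] != pos.at[b, "chrom"]:
                continue
            if abs(pos.at[a, "pos"] - pos.at[b, "pos"]) > spec.radius_bp:
                continue
            r2 = np.corrcoef(small_cohort.genotypes.dosages[:, col[a]],
                             small_cohort.genotypes.dosages[:, col[b]])[0, 1] ** 2
            assert r2 <= spec.r2_max


def test_threshold_monotonicity(small_cohort):
    rng = np.random.default_rng(9)
    variants = small_cohort.variants
    ss = _sumstats(variants, p=rng.uniform(0, 1, len(variants)))
    spec_hi = ClumpSpec(p_threshold=0.5, radius_bp=100_000, r2_max=0.1)
    spec_lo = ClumpSpec(p_threshold=0.05, radius_bp=100_000, r2_max=0.1)
    hi = clump(ss, small_cohort.genotypes, variants, spec_hi)
    lo = clump(ss, small_cohort.genotypes, variants, spec_lo)
    assert len(lo) <= len(hi)


def test_empty_after_threshold_returns_empty(small_cohort):
    ss = _sumstats(small_cohort.variants, p=0.5)
    assert clump(ss, small_cohort.genotypes, small_cohort.variants,
                 ClumpSpec(p_threshold=1e-4)) == []
    assert len(build_weights(ss, [], "x", 1e-4)) == 0


def test_weights_are_sumstats_betas():
    variants = _variants(5)
    ss = _sumstats(variants, p=1e-5, beta=[0.1, -0.2, 0.3, -0.4, 0.5])
    ws = build_weights(ss, ["v3", "v0"], "s", 1e-3)
    assert ws.entries["weight"].tolist() == [-0.4, 0.1]
    assert ws.entries["allele_effect"].tolist() == \
        [ss.set_index("variant_id").at[v, "allele_effect"] for v in ["v3", "v0"]]


def test_score_simple_and_flip_invariance():
    variants = _variants(3)
    d = np.array([[2.0, 1.0, 0.0], [0.0, 2.0, 1.0]])
    gm = GenotypeMatrix(d, ["a", "b"], ["v0", "v1", "v2"])
    ws = WeightSet("s", 1e-3, pd.DataFrame({
        "variant_id": ["v0"], "allele_effect": [variants["allele_effect"][0]],
        "weight": [0.5]}))
    assert np.allclose(score(ws, gm, variants), [1.0, 0.0])

    # recode every column: swap alleles and g -> 2 - g; scores must not move
    ws_all = WeightSet("s2", 1e-3, pd.DataFrame({
        "variant_id": ["v0", "v1", "v2"],
        "allele_effect": variants["allele_effect"],
        "weight": [0.5, -1.0, 2.0]}))
    base = score(ws_all, gm, variants)
    recoded_variants = variants.assign(
        allele_other=variants["allele_effect"],
        allele_effect=variants["allele_other"])
    recoded_gm = GenotypeMatrix(2.0 - d, ["a", "b"], ["v0", "v1", "v2"])
    assert np.allclose(score(ws_all, recoded_gm, recoded_variants), base)


def test_score_allele_mismatch_rejected():
    variants = _variants(1)
    gm = GenotypeMatrix(np.array([[1.0]]), ["a"], ["v0"])
    bad_allele = ({"A", "C", "G", "T"} -
                  {variants["allele_other"][0], variants["allele_effect"][0]}).pop()
    ws = WeightSet("s", 1e-3, pd.DataFrame({
        "variant_id": ["v0"], "allele_effect": [bad_allele], "weight": [1.0]}))
    with pytest.raises(ValueError, match="neither"):
        score(ws, gm, variants)


def test_score_missing_imputed_as_twice_effect_freq():
    variants = _variants(1)
    d = np.array([[2.0], [1.0], [np.nan], [1.0]])
    gm = GenotypeMatrix(d, list("abcd"), ["v0"])
    ws = WeightSet("s", 1e-3, pd.DataFrame({
        "variant_id": ["v0"], "allele_effect": [variants["allele_effect"][0]],
        "weight": [1.0]}))
    out = score(ws, gm, variants)
    assert np.isclose(out[2], (2 + 1 + 1) / 3)  # 2 x observed effect-allele freq


def test_scoring_linearity():
    variants = _variants(4)
    rng = np.random.default_rng(1)
    d = rng.integers(0, 3, size=(30, 4)).astype(float)
    gm = GenotypeMatrix(d, [f"i{k}" for k in range(30)], list(variants["variant_id"]))
    eff = variants["allele_effect"]
    w1 = WeightSet("a", 1e-3, pd.DataFrame({
        "variant_id": ["v0", "v1"], "allele_effect": eff[:2], "weight": [0.3, -0.7]}))
    w2 = WeightSet("b", 1e-3, pd.DataFrame({
        "variant_id": ["v2", "v3"], "allele_effect": eff[2:].tolist(),
        "weight": [1.1, 0.2]}))
    w12 = WeightSet("ab", 1e-3, pd.concat([w1.entries, w2.entries],
                                          ignore_index=True))
    assert np.allclose(score(w12, gm, variants),
                       score(w1, gm, variants) + score(w2, gm, variants))


def test_pathway_weightset_contained_in_pathway(small_cohort):
    rng = np.random.default_rng(3)
    variants = small_cohort.variants
    ss = _sumstats(variants, p=rng.uniform(0, 2e-3, len(variants)))
    spec = ClumpSpec(p_threshold=1e-3, radius_bp=100_000, r2_max=0.1)
    scores, wsets = build_all_scores(ss, small_cohort.genotypes, variants,
                                     small_cohort.pathway_variants, spec)
    for ws in wsets:
        if ws.score_name == GENOME_WIDE:
            continue
        assert set(ws.entries["variant_id"]) <= \
            set(small_cohort.pathway_variants[ws.score_name])
        assert scores.variant_counts[ws.score_name] == len(ws)


def test_pathway_equal_to_universe_matches_genome_wide(small_cohort):
    rng = np.random.default_rng(6)
    variants = small_cohort.variants
    ss = _sumstats(variants, p=rng.uniform(0, 2e-3, len(variants)))
    spec = ClumpSpec(p_threshold=1e-3, radius_bp=100_000, r2_max=0.1)
    universe = frozenset(variants["variant_id"])
    scores, _ = build_all_scores(ss, small_cohort.genotypes, variants,
                                 {"ALL": universe}, spec)
    assert np.allclose(scores.values["ALL"], scores.values[GENOME_WIDE])
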