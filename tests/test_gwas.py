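"""ssGBLUP GWAS: back-solved effects, sampling SDs, FDR, QTL regions,
LD, window variance, allele substitution."""

import numpy as np
import pandas as pd
import pytest

from microherit.animal_model import ModelFrame
from microherit.gwas import (
    QtlRegion,
    allele_substitution,
    backsolve_snp_effects,
    fdr_adjust,
    fit_ssgblup,
    group_qtl_regions,
    ld_r2,
    snp_pvalues,
    snp_sampling_sd,
    window_variance_explained,
)
from microherit.relationship import GenotypeSet, RelationshipMatrix, build_A
from microherit.reml import solve_mme


def _frame(y, X, ids):
    return ModelFrame(["y"], np.asarray(y, float)[:, None],
                      [np.atleast_2d(X)], [["x"]], list(ids))


@pytest.fixture(scope="module")
def geno_instance():
    rng = np.random.default_rng(21)
    n, m = 80, 200
    p = rng.uniform(0.15, 0.5, m)
    counts = rng.binomial(2, p, size=(n, m)).astype(float)
    ids = [f"A{i}" for i in range(n)]
    pos = np.concatenate(
        [np.sort(rng.choice(10**8, m // 4, replace=False)) for _ in range(4)]
    )
    smap = pd.DataFrame(
        {"snp_id": [f"s{j}" for j in range(m)],
         "chromosome": np.repeat([1, 2, 3, 4], m // 4), "position": pos}
    )
    geno = GenotypeSet(counts, ids, smap, allele_freqs=p)
    Z = geno.centered()
    k = 1.0 / (2.0 * np.sum(p * (1 - p)))
    G = Z @ Z.T * k + 0.02 * np.eye(n)
    Gm = RelationshipMatrix(0.5 * (G + G.T), ids, "G_blended",
                            meta={"a": 0.0, "b": 1.0, "alpha": 0.0})
    return geno, Z, k, Gm


# ---------------------------------------------------------------------------
# ssGBLUP solving
# ---------------------------------------------------------------------------


def test_ssgblup_with_H_equal_A_is_pedigree_blup(small_dataset, small_A):
    ds = small_dataset
    ids = ds.phenotypes["animal"].astype(str).tolist()
    y = ds.phenotypes["fat_content"].to_numpy()
    X = np.ones((len(y), 1))
    frame = _frame(y, X, ids)
    Hlike = RelationshipMatrix(small_A.values, small_A.ids, "H")
    b1, g1, _ = fit_ssgblup(frame, Hlike, 0.4, 0.9)
    pos = {a: i for i, a in enumerate(small_A.ids)}
    sol = solve_mme(y, [X], np.array([pos[a] for a in ids]),
                    np.linalg.inv(small_A.values), [[0.4]], [[0.9]])
    np.testing.assert_allclose(g1.to_numpy(), sol.u[:, 0], atol=1e-8)


def test_ssgblup_shrinks_to_zero_without_genetic_variance(geno_instance):
    geno, Z, k, Gm = geno_instance
    rng = np.random.default_rng(1)
    y = rng.normal(size=len(Gm.ids))
    frame = _frame(y, np.ones((len(y), 1)), Gm.ids)
    _, g_hat, _ = fit_ssgblup(frame, Gm, 1e-10, 1.0)
    assert np.abs(g_hat.to_numpy()).max() < 1e-6


def test_ssgblup_pev_bounded_by_prior_variance(geno_instance):
    geno, Z, k, Gm = geno_instance
    rng = np.random.default_rng(2)
    sg2, se2 = 0.5, 0.5
    y = rng.normal(size=len(Gm.ids))
    frame = _frame(y, np.ones((len(y), 1)), Gm.ids)
    _, _, Cu2u2 = fit_ssgblup(frame, Gm, sg2, se2, Gm.ids)
    assert np.all(np.diag(Cu2u2) <= np.diag(Gm.values) * sg2 + 1e-10)


# ---------------------------------------------------------------------------
# back-solving and sampling variance
# ---------------------------------------------------------------------------


def test_backsolve_zero_breeding_values(geno_instance):
    _, Z, k, Gm = geno_instance
    Ginv = np.linalg.inv(Gm.values)
    a = backsolve_snp_effects(np.zeros(Z.shape[0]), Z, Ginv, k, 1.0, 0.0)
    np.testing.assert_array_equal(a, 0.0)


def test_backsolve_projection_identity_alpha_zero():
    """With G = ZZ'/2*sum(pq) exactly, Z a_hat reproduces g_hat2."""
    from microherit.validation import gblup_snpblup_equivalence

    res = gblup_snpblup_equivalence(seed=3, n=120, m=600)
    assert res["max_abs_diff_projection"] < 1e-8
    assert res["max_abs_diff_snp_blup"] < 1e-6


def test_sampling_sd_collapses_without_information(geno_instance):
    _, Z, k, Gm = geno_instance
    sg2 = 0.4
    Ginv = np.linalg.inv(Gm.values)
    sd, flagged = snp_sampling_sd(Z, Ginv, Gm.values, Gm.values * sg2,
                                  sg2, k, 1.0, 0.0)
    assert np.abs(sd).max() < 1e-8
    # a monomorphic (zero after centring) SNP has sd exactly 0
    Z2 = Z.copy()
    Z2[:, 0] = 0.0
    sd2, _ = snp_sampling_sd(Z2, Ginv, Gm.values, Gm.values * sg2 * 0.5,
                             sg2, k, 1.0, 0.0)
    assert sd2[0] == 0.0


def test_sampling_sd_floors_negative_variance(geno_instance):
    _, Z, k, Gm = geno_instance
    Ginv = np.linalg.inv(Gm.values)
    # PEC exceeding the prior makes the bracket negative definite
    sd, flagged = snp_sampling_sd(Z, Ginv, Gm.values, Gm.values * 2.0,
                                  1.0, k, 1.0, 0.0)
    assert flagged.all() and (sd == 0.0).all()


def test_pvalues_normal_identities():
    p = snp_pvalues(np.array([0.0]), np.array([1.0]))
    assert p[0] == pytest.approx(1.0)
    p = snp_pvalues(np.array([1.959964]), np.array([1.0]))
    assert p[0] == pytest.approx(0.05, abs=1e-6)
    a = np.array([0.3, -0.2, 0.05, 0.0])
    sd = np.array([0.1, 0.1, 0.0, 0.2])
    vec = snp_pvalues(a, sd)
    for i in range(4):
        one = snp_pvalues(a[i : i + 1], sd[i : i + 1])[0]
        if np.isnan(one):
            assert np.isnan(vec[i])
        else:
            assert vec[i] == pytest.approx(one)
    assert np.isnan(vec[2])  # sd == 0 -> untestable


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def test_bh_hand_enumeration():
    q = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.8]))
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.8], atol=1e-12)


def test_bh_equal_pvalues_and_monotonicity():
    q = fdr_adjust(np.full(7, 0.2))
    np.testing.assert_allclose(q, 0.2, atol=1e-12)
    rng = np.random.default_rng(5)
    p = rng.uniform(size=200)
    q = fdr_adjust(p)
    assert (q >= p - 1e-12).all()
    assert (q <= 1.0).all()


def test_bh_handles_untestable_nans():
    q = fdr_adjust(np.array([0.01, np.nan, 0.5]))
    assert np.isnan(q[1]) and np.isfinite(q[0])


# ---------------------------------------------------------------------------
# QTL regions
# ---------------------------------------------------------------------------


def _table(rows):
    df = pd.DataFrame(rows, columns=["snp_id", "chromosome", "position", "p_value"])
    df["significant"] = df["p_value"] < 1e-3
    return df


def test_regions_empty_and_singleton():
    assert group_qtl_regions(_table([("a", 1, 100, 0.5)])) == []
    regs = group_qtl_regions(_table([("a", 1, 100, 1e-6)]))
    assert len(regs) == 1 and regs[0].lead_snp == "a" and regs[0].members == ["a"]


def test_regions_hand_traced_rule():
    """Lead -log10p 6.0 at 10 Mbp; 10.5 Mbp (5.0) joins, 10.8 Mbp (3.5)
    fails the upper-third rule, 30 Mbp (5.5) forms its own region."""
    rows = [
        ("lead", 1, 10_000_000, 1e-6),
        ("near_tall", 1, 10_500_000, 1e-5),
        ("near_short", 1, 10_800_000, 10 ** -3.5),
        ("far", 1, 30_000_000, 10 ** -5.5),
    ]
    df = _table(rows)
    df["significant"] = True
    regs = group_qtl_regions(df, distance_limit=1_000_000, peak_fraction=1 / 3)
    by_lead = {r.lead_snp: r for r in regs}
    assert set(by_lead) == {"lead", "far", "near_short"}
    assert sorted(by_lead["lead"].members) == ["lead", "near_tall"]
    assert by_lead["far"].members == ["far"]
    # every lead is a member of its own region
    for r in regs:
        assert r.lead_snp in r.members
        assert isinstance(r, QtlRegion)


# ---------------------------------------------------------------------------
# LD and window variance
# ---------------------------------------------------------------------------


def test_ld_identical_and_complement():
    g = np.array([0, 1, 2, 1, 0, 2, 1], dtype=float)
    assert ld_r2(g, g) == pytest.approx(1.0)
    assert ld_r2(g, 2 - g) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        ld_r2(g, np.ones_like(g))


def test_ld_independent_snps_near_zero():
    rng = np.random.default_rng(6)
    g1 = rng.binomial(2, 0.3, 5000).astype(float)
    g2 = rng.binomial(2, 0.4, 5000).astype(float)
    assert ld_r2(g1, g2) < 0.01


def test_window_variance_zero_effects(geno_instance):
    geno, Z, k, Gm = geno_instance
    wv = window_variance_explained(np.zeros(Z.shape[1]), Z, geno.snp_map, 1.0)
    np.testing.assert_array_equal(wv, 0.0)


def test_window_variance_single_causal_matches_2pqa2():
    rng = np.random.default_rng(7)
    n, m = 4000, 40
    p = np.full(m, 0.3)
    counts = rng.binomial(2, p, size=(n, m)).astype(float)
    smap = pd.DataFrame({"snp_id": [f"s{j}" for j in range(m)],
                         "chromosome": 1, "position": np.arange(1, m + 1) * 1000})
    geno = GenotypeSet(counts, [f"A{i}" for i in range(n)], smap, p)
    Z = geno.centered()
    a = np.zeros(m)
    a[20] = 0.7
    sigma_p2 = 2.0
    wv = window_variance_explained(a, Z, smap, sigma_p2, window=20)
    expected = 2 * 0.3 * 0.7 * 0.7**2 / sigma_p2 * 100
    assert wv[20] == pytest.approx(expected, rel=0.1)
    # windows not containing the causal SNP explain nothing
    assert wv[0] == 0.0 or wv[0] < 1e-12


def test_region_variance_at_least_max_member_window(small_dataset, small_A):
    """Empirical monotonicity: a region's union-window variance is not
    below the largest member window's variance."""
    from microherit.gwas import SingleStepGwas, make_single_step
    from microherit.animal_model import build_model_frame
    from microherit.pipeline import default_fixed_effects

    ds = small_dataset
    ids = ds.phenotypes["animal"].astype(str).tolist()
    geno = ds.genotypes.subset(ids)
    ssm = make_single_step(small_A, geno, alpha=0.05)
    f, c = default_fixed_effects("fat_content")
    frame = build_model_frame(ds.phenotypes, ["fat_content"],
                              {"fat_content": f}, {"fat_content": c},
                              ds.pedigree)
    res = SingleStepGwas(frame, ssm, 0.5, 0.8).fit()
    t = res.table.copy()
    # force a couple of regions regardless of significance
    t.loc[t["p_value"].nsmallest(5).index, "significant"] = True
    res.table = t
    for reg in res.qtl_regions():
        members_wv = res.table.set_index("snp_id").loc[reg.members,
                                                       "var_window_pct"]
        assert reg.variance_pct >= members_wv.max() - 1e-9


# ---------------------------------------------------------------------------
# allele substitution
# ---------------------------------------------------------------------------


def test_allele_substitution_recovers_effect():
    rng = np.random.default_rng(8)
    n = 400
    g = rng.binomial(2, 0.4, n).astype(float)
    y = 0.5 * g + rng.normal(size=n)
    X = np.ones((n, 1))
    eff, se = allele_substitution(y, g, X, np.arange(n), np.eye(n),
                                  sigma_g2=1e-8, sigma_e2=1.0)
    assert abs(eff - 0.5) < 2 * se
    eff2, _ = allele_substitution(y, 2 - g, X, np.arange(n), np.eye(n),
                                  sigma_g2=1e-8, sigma_e2=1.0)
    assert eff2 == pytest.approx(-eff, abs=1e-8)


def test_allele_substitution_rejects_constant_snp():
    n = 20
    with pytest.raises(ValueError, match="monomorphic"):
        allele_substitution(np.zeros(n), np.ones(n), np.ones((n, 1)),
                            np.arange(n), np.eye(n))
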