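"""Relationship matrices: A (tabular), G (VanRaden), blending and H."""

import numpy as np
import pandas as pd
import pytest

from microherit.relationship import (
    GenotypeSet,
    Pedigree,
    RelationshipMatrix,
    blend_G,
    build_A,
    build_H,
    compute_G_raw,
    extract_A22,
    partition_A,
)


def _ped(rows):
    return Pedigree(pd.DataFrame(rows, columns=["animal", "sire", "dam"]))


@pytest.fixture(scope="module")
def family_pedigree():
    # founders F1..F4, one full-sib pair and a grandchild
    return _ped(
        [
            ("F1", "0", "0"),
            ("F2", "0", "0"),
            ("F3", "0", "0"),
            ("F4", "0", "0"),
            ("C1", "F1", "F2"),
            ("C2", "F1", "F2"),
            ("C3", "F3", "F4"),
            ("G1", "C1", "C3"),
        ]
    )


# ---------------------------------------------------------------------------
# pedigree / A
# ---------------------------------------------------------------------------


def test_pedigree_rejects_offspring_before_parent_without_sort():
    with pytest.raises(ValueError, match="appears after"):
        _ped([("C", "S", "0"), ("S", "0", "0")])
    ped = Pedigree(
        pd.DataFrame([("C", "S", "0"), ("S", "0", "0")],
                     columns=["animal", "sire", "dam"]),
        sort=True,
    )
    assert ped.ids == ["S", "C"]


def test_pedigree_rejects_cycles_and_duplicates():
    with pytest.raises(ValueError, match="cycle"):
        Pedigree(
            pd.DataFrame([("A", "B", "0"), ("B", "A", "0")],
                         columns=["animal", "sire", "dam"]),
            sort=True,
        )
    with pytest.raises(ValueError, match="duplicate"):
        _ped([("A", "0", "0"), ("A", "0", "0")])


def test_A_founders_identity():
    A = build_A(_ped([(f"F{i}", "0", "0") for i in range(6)]))
    np.testing.assert_allclose(A.values, np.eye(6), atol=1e-14)


def test_A_classical_relationships(family_pedigree):
    A = build_A(family_pedigree).to_dataframe()
    assert A.loc["F1", "C1"] == pytest.approx(0.5)   # sire-offspring
    assert A.loc["C1", "C2"] == pytest.approx(0.5)   # full sibs
    assert A.loc["F1", "G1"] == pytest.approx(0.25)  # grandparent
    assert A.loc["G1", "G1"] == pytest.approx(1.0)   # non-inbred


def test_A_inbred_diagonal():
    # sire x daughter mating: F = 0.25
    A = build_A(
        _ped([("S", "0", "0"), ("D", "0", "0"), ("X", "S", "D"), ("I", "S", "X")])
    ).to_dataframe()
    assert A.loc["I", "I"] == pytest.approx(1.25)


def test_A_founder_order_invariance(family_pedigree):
    rows = family_pedigree.records.iloc[[3, 2, 1, 0, 4, 5, 6, 7]]
    A1 = build_A(family_pedigree).to_dataframe()
    A2 = build_A(Pedigree(rows.reset_index(drop=True))).to_dataframe()
    ids = A1.index
    np.testing.assert_allclose(A1.values, A2.loc[ids, ids].values, atol=1e-14)


def test_A_matches_gene_dropping_ibd(family_pedigree):
    """Gene-dropping Monte-Carlo: a(i,j) = 2 * P(random alleles IBD)."""
    ped = family_pedigree
    n = len(ped)
    sidx, didx = ped.parent_indices()
    rng = np.random.default_rng(0)
    loci = 200_000 // n * n  # ~200k total drops across unlinked loci
    R = loci // n
    alleles = np.empty((n, 2, R), dtype=np.int32)
    counter = 0
    for i in range(n):
        for a, p in enumerate((sidx[i], didx[i])):
            if p < 0:
                alleles[i, a] = counter
                counter += 1
            else:
                pick = rng.integers(0, 2, size=R)
                alleles[i, a] = alleles[p, pick, np.arange(R)]
    A = build_A(ped).values
    for i in range(n):
        for j in range(i, n):
            ibd = np.mean(
                [
                    alleles[i, a] == alleles[j, b]
                    for a in range(2)
                    for b in range(2)
                    if not (i == j and a == b)
                ],
                axis=0,
            ).mean()
            if i == j:
                # a(i,i) = 1 + F, F = P(own alleles IBD)
                est = 1.0 + np.mean(alleles[i, 0] == alleles[i, 1])
            else:
                est = 2.0 * ibd
            assert abs(est - A[i, j]) < 0.02, (i, j)


# ---------------------------------------------------------------------------
# partition
# ---------------------------------------------------------------------------


def test_partition_all_genotyped_gives_A22_equal_A(family_pedigree):
    A = build_A(family_pedigree)
    A22 = extract_A22(A, A.ids)
    np.testing.assert_array_equal(A22.values, A.values)


def test_partition_reassembly_exact(family_pedigree):
    A = build_A(family_pedigree)
    gids = ["C2", "G1", "F3"]
    b = partition_A(A, gids)
    order = b.nongenotyped + b.genotyped
    n1 = len(b.nongenotyped)
    H = np.block([[b.A11, b.A12], [b.A21, b.A22]])
    df = pd.DataFrame(H, index=order, columns=order)
    np.testing.assert_array_equal(
        df.loc[A.ids, A.ids].values, A.values
    )
    assert H.shape == (len(A.ids),) * 2 and n1 == len(A.ids) - 3


def test_partition_unknown_id_raises(family_pedigree):
    A = build_A(family_pedigree)
    with pytest.raises(KeyError):
        partition_A(A, ["nope"])


# ---------------------------------------------------------------------------
# G
# ---------------------------------------------------------------------------


def _geno(counts, freqs=None):
    counts = np.asarray(counts, float)
    n, m = counts.shape
    smap = pd.DataFrame(
        {"snp_id": [f"s{j}" for j in range(m)], "chromosome": 1,
         "position": np.arange(1, m + 1)}
    )
    return GenotypeSet(counts, [f"A{i}" for i in range(n)], smap, freqs)


def test_G_single_snp_arithmetic():
    g = _geno([[0], [1], [2]], freqs=np.array([0.5]))
    G = compute_G_raw(g).values
    np.testing.assert_allclose(np.diag(G), [2.0, 0.0, 2.0], atol=1e-12)
    assert G[0, 2] == pytest.approx(-2.0)


def test_G_matches_dense_oracle():
    rng = np.random.default_rng(5)
    p = rng.uniform(0.1, 0.5, 500)
    counts = rng.binomial(2, p, size=(50, 500)).astype(float)
    g = _geno(counts)
    G = compute_G_raw(g).values
    pf = counts.mean(axis=0) / 2
    Z = counts - 2 * pf
    oracle = np.zeros((50, 50))
    for i in range(50):
        for j in range(50):
            oracle[i, j] = Z[i] @ Z[j]
    oracle /= 2 * np.sum(pf * (1 - pf))
    np.testing.assert_allclose(G, oracle, atol=1e-10)


def test_G_duplicated_individuals():
    rng = np.random.default_rng(6)
    counts = rng.binomial(2, 0.5, size=(5, 100)).astype(float)
    counts[4] = counts[0]
    p = counts.mean(axis=0) / 2
    counts = counts[:, (p > 0) & (p < 1)]  # drop monomorphic columns
    G = compute_G_raw(_geno(counts)).values
    assert G[0, 4] == pytest.approx(G[0, 0], abs=1e-12)
    assert G[4, 4] == pytest.approx(G[0, 0], abs=1e-12)


def test_G_monomorphic_error():
    counts = np.array([[0.0, 1], [0, 2], [0, 1]])
    with pytest.raises(ValueError, match="QC"):
        compute_G_raw(_geno(counts))


# ---------------------------------------------------------------------------
# blending
# ---------------------------------------------------------------------------


def test_blend_fixed_point():
    rng = np.random.default_rng(7)
    M = rng.normal(size=(6, 12))
    A22v = M @ M.T / 12 + 0.5 * np.eye(6)
    ids = [f"A{i}" for i in range(6)]
    A22 = RelationshipMatrix(A22v, ids, "A22")
    G_raw = RelationshipMatrix(A22v.copy(), ids, "G_raw")
    out = blend_G(G_raw, A22, alpha=0.05)
    assert out.meta["a"] == pytest.approx(0.0, abs=1e-10)
    assert out.meta["b"] == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(out.values, A22v, atol=1e-10)


def test_blend_alpha_zero_identity():
    rng = np.random.default_rng(8)
    M = rng.normal(size=(5, 20))
    V = M @ M.T / 20 + 0.3 * np.eye(5)
    ids = [f"A{i}" for i in range(5)]
    out = blend_G(
        RelationshipMatrix(V, ids, "G_raw"), RelationshipMatrix(V, ids, "A22"), 0.0
    )
    np.testing.assert_allclose(out.values, V, atol=1e-12)


def test_blend_ab_match_independent_2x2_solver():
    rng = np.random.default_rng(9)
    M = rng.normal(size=(5, 30))
    Gv = M @ M.T / 30 + 0.2 * np.eye(5)
    N = rng.normal(size=(5, 30))
    Av = N @ N.T / 30 + 0.8 * np.eye(5)
    ids = [f"A{i}" for i in range(5)]
    out = blend_G(RelationshipMatrix(Gv, ids, "G_raw"),
                  RelationshipMatrix(Av, ids, "A22"), 0.05)
    off = ~np.eye(5, dtype=bool)
    # independent 2x2 elimination
    m11, m12 = 1.0, np.diag(Gv).mean()
    m21, m22 = 1.0, Gv[off].mean()
    r1, r2 = np.diag(Av).mean(), Av[off].mean()
    b = (r2 - r1) / (m22 - m12)
    a = r1 - b * m12
    assert out.meta["a"] == pytest.approx(a, rel=1e-10)
    assert out.meta["b"] == pytest.approx(b, rel=1e-10)


def test_blend_constant_G_singular():
    ids = ["A0", "A1"]
    with pytest.raises(ValueError, match="singular"):
        blend_G(RelationshipMatrix(np.ones((2, 2)), ids, "G_raw"),
                RelationshipMatrix(np.eye(2), ids, "A22"))


# ---------------------------------------------------------------------------
# H
# ---------------------------------------------------------------------------


def test_H_collapses_to_A_when_G_is_A22(family_pedigree):
    A = build_A(family_pedigree)
    gids = ["C1", "C3", "G1"]
    A22 = extract_A22(A, gids)
    H = build_H(A, RelationshipMatrix(A22.values, gids, "G_blended"))
    np.testing.assert_allclose(H.values, A.values, atol=1e-10)
    assert H.ids == A.ids


def test_H_all_genotyped_equals_G(family_pedigree):
    A = build_A(family_pedigree)
    rng = np.random.default_rng(10)
    M = rng.normal(size=(len(A.ids), 30))
    Gv = M @ M.T / 30 + 0.5 * np.eye(len(A.ids))
    G = RelationshipMatrix(Gv, A.ids, "G_blended")
    H = build_H(A, G)
    np.testing.assert_array_equal(H.values, Gv)


def test_H_inverse_identity_oracle():
    """H^-1 = A^-1 + block(G^-1 - A22^-1) on a simulated pedigree."""
    from microherit.simulate import SimulationConfig, TraitSpec, simulate_genotypes, simulate_pedigree

    cfg = SimulationConfig(seed=3, n_founders=12, n_generations=3,
                           n_snps=80, n_otus=30,
                           trait_specs=[TraitSpec("t", 0.3, 0, 1)])
    ped = simulate_pedigree(cfg)
    A = build_A(ped)
    gids = ped.ids[-10:]
    geno = simulate_genotypes(ped, cfg).subset(gids)
    Gb = blend_G(compute_G_raw(geno), extract_A22(A, gids), alpha=0.05)
    H = build_H(A, Gb)
    pos = {a: i for i, a in enumerate(A.ids)}
    gi = np.array([pos[g] for g in gids])
    delta = np.zeros_like(A.values)
    delta[np.ix_(gi, gi)] = (
        np.linalg.inv(Gb.values) - np.linalg.inv(extract_A22(A, gids).values)
    )
    np.testing.assert_allclose(
        np.linalg.inv(H.values), np.linalg.inv(A.values) + delta, atol=1e-8
    )
    # genotyped block of H is exactly G; blended G is PD
    np.testing.assert_allclose(H.submatrix(gids), Gb.values, atol=1e-12)
    assert np.linalg.eigvalsh(Gb.values)[0] > 0
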