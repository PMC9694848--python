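"""Multi-trait REML engine, mixed-model equations, model frames."""

import numpy as np
import pandas as pd
import pytest

from microherit.animal_model import (
    AnimalModel,
    DesignError,
    build_model_frame,
    genetic_correlation,
    heritability,
    reml_ai,
    reml_em,
)
from microherit.relationship import Pedigree, build_A
from microherit.reml import MultiTraitREML, solve_mme


def _halfsib(rng, s=40, k=10, sg2=0.3, se2=0.7, mu=5.0):
    n = s * k
    sire_bv = rng.normal(0, np.sqrt(sg2), s)
    sire_of = np.repeat(np.arange(s), k)
    bv = 0.5 * sire_bv[sire_of] + rng.normal(0, np.sqrt(0.75 * sg2), n)
    y = mu + bv + rng.normal(0, np.sqrt(se2), n)
    recs = [(f"S{i}", "0", "0") for i in range(s)] + [
        (f"P{j}", f"S{sire_of[j]}", "0") for j in range(n)
    ]
    ped = Pedigree(pd.DataFrame(recs, columns=["animal", "sire", "dam"]))
    A_phi = build_A(ped).submatrix([f"P{j}" for j in range(n)])
    return y, A_phi


# ---------------------------------------------------------------------------
# model frames
# ---------------------------------------------------------------------------


def _phen(n=30, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "animal": [f"A{i}" for i in range(n)],
            "y": rng.normal(size=n),
            "grp": rng.integers(0, 3, n).astype(str),
            "grp2": rng.integers(0, 2, n).astype(str),
            "dim": rng.integers(28, 134, n),
        }
    )


def test_frame_intercept_coding_columns():
    frame = build_model_frame(_phen(), ["y"], {"y": ["grp"]}, {"y": []})
    assert frame.Xs[0].shape[1] == 3  # intercept + 2 dummies
    assert frame.x_names[0][0] == "intercept"


def test_frame_dim_covariate_range_warning():
    df = _phen()
    frame = build_model_frame(df, ["y"], {"y": []}, {"y": ["dim"]})
    assert frame.Xs[0].shape[1] == 2
    df.loc[0, "dim"] = 200
    with pytest.warns(UserWarning, match="dim"):
        build_model_frame(df, ["y"], {"y": []}, {"y": ["dim"]})


def test_frame_duplicated_factor_rank_error():
    with pytest.raises(DesignError, match="aliased"):
        build_model_frame(_phen(), ["y"], {"y": ["grp", "grp"]}, {"y": []})


def test_frame_orphan_animal_rejected():
    df = _phen(5)
    ped = Pedigree(
        pd.DataFrame(
            [(f"A{i}", "0", "0") for i in range(4)],
            columns=["animal", "sire", "dam"],
        )
    )
    with pytest.raises(DesignError, match="A4"):
        build_model_frame(df, ["y"], {"y": []}, {"y": []}, pedigree=ped)


def test_frame_complete_case_restriction():
    df = _phen(20)
    df.loc[3, "y"] = np.nan
    frame = build_model_frame(df, ["y"], {"y": []}, {"y": []})
    assert frame.n == 19 and "A3" not in frame.animal_ids


# ---------------------------------------------------------------------------
# mixed-model equations
# ---------------------------------------------------------------------------


def test_mme_matches_ridge_regression():
    """Single trait, K=I: BLUP equals ridge with penalty se2/sg2."""
    rng = np.random.default_rng(1)
    n, sg2, se2 = 40, 0.3, 0.7
    y = rng.normal(size=n)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    sol = solve_mme(y, [X], np.arange(n), np.eye(n), [[sg2]], [[se2]])
    Xf = np.hstack([X, np.eye(n)])
    Pen = np.zeros((n + 2, n + 2))
    Pen[2:, 2:] = np.eye(n) * se2 / sg2
    beta = np.linalg.solve(Xf.T @ Xf + Pen, Xf.T @ y)
    np.testing.assert_allclose(
        np.concatenate([sol.b, sol.u[:, 0]]), beta, atol=1e-10
    )


def test_mme_gls_limit_as_genetic_variance_vanishes():
    rng = np.random.default_rng(2)
    n = 60
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ [1.0, 2.0] + rng.normal(size=n)
    sol = solve_mme(y, [X], np.arange(n), np.eye(n), [[1e-10]], [[1.0]])
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    np.testing.assert_allclose(sol.b, ols, atol=1e-5)


def test_mme_self_consistency_residual():
    """The returned solutions satisfy the assembled equations."""
    rng = np.random.default_rng(3)
    n, q, T = 25, 12, 2
    idx = rng.integers(0, q, n)
    Y = rng.normal(size=(n, T))
    Xs = [np.column_stack([np.ones(n), rng.normal(size=n)]) for _ in range(T)]
    M = rng.normal(size=(q, q))
    K = M @ M.T / q + np.eye(q)
    P = np.array([[0.5, 0.1], [0.1, 0.4]])
    R = np.array([[1.0, -0.2], [-0.2, 0.8]])
    sol = solve_mme(Y, Xs, idx, np.linalg.inv(K), P, R)
    # rebuild the coefficient matrix and right-hand side independently
    Rinv, Pinv = np.linalg.inv(R), np.linalg.inv(P)
    W = np.zeros((n, q))
    W[np.arange(n), idx] = 1.0
    Xb = np.zeros((n * T, 2 * T))
    Wb = np.zeros((n * T, q * T))
    for t in range(T):
        Xb[t * n : (t + 1) * n, t * 2 : (t + 1) * 2] = Xs[t]
        Wb[t * n : (t + 1) * n, t * q : (t + 1) * q] = W
    Rfull_inv = np.kron(Rinv, np.eye(n))
    Gfull_inv = np.kron(Pinv, np.linalg.inv(K))
    Tm = np.hstack([Xb, Wb])
    C = Tm.T @ Rfull_inv @ Tm
    C[2 * T :, 2 * T :] += Gfull_inv
    rhs = Tm.T @ Rfull_inv @ Y.T.ravel()
    solvec = np.concatenate([sol.b, sol.u.T.ravel()])
    assert np.abs(C @ solvec - rhs).max() < 1e-8


# ---------------------------------------------------------------------------
# EM-REML
# ---------------------------------------------------------------------------


def test_em_monotone_loglik_100_rounds():
    rng = np.random.default_rng(4)
    y, A_phi = _halfsib(rng, s=50, k=8)
    frame_y = y[:, None]
    eng = MultiTraitREML(frame_y, [np.ones((len(y), 1))], A=A_phi)
    _, _, path = eng.run_em(np.array([[0.1]]), np.array([[0.9]]), 100)
    assert len(path) == 100
    diffs = np.diff(path)
    assert (diffs >= -1e-8 * (1 + np.abs(path[:-1]))).all()


def test_em_fixed_point_at_reml_optimum():
    rng = np.random.default_rng(5)
    y, A_phi = _halfsib(rng)
    eng = MultiTraitREML(y, [np.ones((len(y), 1))], A=A_phi)
    vc = eng.fit(np.array([[0.2]]), np.array([[0.8]]), em_rounds=30,
                 tol=1e-13, max_iter=300)
    P1, R1, _ = eng.em_step(vc.P, vc.R)
    assert abs(P1[0, 0] - vc.P[0, 0]) < 1e-6
    assert abs(R1[0, 0] - vc.R[0, 0]) < 1e-6


def test_em_keeps_P_R_psd_two_traits():
    rng = np.random.default_rng(6)
    n = 150
    M = rng.normal(size=(n, n))
    A = M @ M.T / n + np.eye(n)
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d) + 0.5 * np.eye(n)
    Y = rng.normal(size=(n, 2))
    eng = MultiTraitREML(Y, [np.ones((n, 1))] * 2, A=A)
    P, R = np.eye(2) * 0.5, np.eye(2) * 0.5
    for _ in range(25):
        P, R, _ = eng.em_step(P, R)
        assert np.linalg.eigvalsh(P)[0] >= -1e-12
        assert np.linalg.eigvalsh(R)[0] >= -1e-12


# ---------------------------------------------------------------------------
# AI-REML
# ---------------------------------------------------------------------------


def test_ai_matches_halfsib_anova_closed_form():
    from microherit.validation import halfsib_closed_form

    res = halfsib_closed_form(17)
    assert res["max_abs_diff"] < 1e-4


def test_ai_flags_confounded_model():
    """A = I with one record per animal: sigma_g2 and sigma_e2 are not
    separately identifiable; the fit must not claim convergence."""
    rng = np.random.default_rng(7)
    n = 80
    y = rng.normal(size=n)
    eng = MultiTraitREML(y, [np.ones((n, 1))], A=np.eye(n))
    vc = eng.fit(np.array([[0.5]]), np.array([[0.5]]), em_rounds=10, max_iter=30)
    assert not vc.converged
    assert "identifiable" in vc.message


def test_ai_improves_on_em_warm_start(small_dataset, small_A, effects_for):
    traits = ["lscs", "cv_milk", "fat_content"]
    f, c = effects_for(traits)
    frame = build_model_frame(
        small_dataset.phenotypes, traits, f, c, small_dataset.pedigree
    )
    warm = reml_em(frame, small_A, n_rounds=40)
    assert not warm.converged and warm.n_iterations == 40
    final = reml_ai(frame, small_A, warm, tol=1e-9, max_iter=80)
    assert final.loglik >= warm.loglik - 1e-6


def test_estimates_invariant_to_record_order(small_dataset, small_A, effects_for):
    traits = ["lscs", "fat_content"]
    f, c = effects_for(traits)
    phen = small_dataset.phenotypes
    frame1 = build_model_frame(phen, traits, f, c, small_dataset.pedigree)
    rng = np.random.default_rng(8)
    shuffled = phen.sample(frac=1.0, random_state=12).reset_index(drop=True)
    frame2 = build_model_frame(shuffled, traits, f, c, small_dataset.pedigree)
    r1 = AnimalModel(frame1, small_A).fit(em_rounds=30, tol=1e-11)
    r2 = AnimalModel(frame2, small_A).fit(em_rounds=30, tol=1e-11)
    np.testing.assert_allclose(r1.P, r2.P, atol=1e-6)
    np.testing.assert_allclose(r1.R, r2.R, atol=1e-6)
    del rng


# ---------------------------------------------------------------------------
# heritability / genetic correlation
# ---------------------------------------------------------------------------


def _vc(P, R, cov=None):
    from microherit.reml import VarianceComponents, _vech_basis

    T = P.shape[0]
    names = [f"{w}[{i},{j}]" for w, i, j in _vech_basis(T)]
    return VarianceComponents(
        P=P, R=R, cov_params=cov, param_names=names, loglik=0.0,
        converged=True, n_iterations=1,
    )


def test_h2_equal_variances_is_half():
    vc = _vc(np.array([[1.0]]), np.array([[1.0]]), np.eye(2) * 0.01)
    h2, se = heritability(vc, 0)
    assert h2 == pytest.approx(0.5)
    assert se >= 0


def test_h2_null_case_and_zero_total_error():
    vc = _vc(np.array([[0.0]]), np.array([[1.0]]), np.eye(2) * 0.01)
    h2, se = heritability(vc, 0)
    assert h2 == 0.0 and se >= 0
    with pytest.raises(ValueError):
        heritability(_vc(np.array([[0.0]]), np.array([[0.0]])), 0)


def test_h2_delta_se_close_to_parametric_bootstrap():
    rng = np.random.default_rng(9)
    y, A_phi = _halfsib(rng, s=40, k=8)
    n = len(y)
    eng = MultiTraitREML(y, [np.ones((n, 1))], A=A_phi)
    vc = eng.fit(np.array([[0.2]]), np.array([[0.8]]), em_rounds=30)
    h2, se_delta = heritability(vc, 0)
    L = np.linalg.cholesky(A_phi * vc.P[0, 0] + 1e-10 * np.eye(n))
    boots = []
    for _ in range(300):
        yb = L @ rng.standard_normal(n) + rng.normal(0, np.sqrt(vc.R[0, 0]), n)
        eng_b = MultiTraitREML(yb, [np.ones((n, 1))], A=A_phi)
        vb = eng_b.fit(vc.P, vc.R, em_rounds=5, tol=1e-6, max_iter=30)
        boots.append(vb.P[0, 0] / (vb.P[0, 0] + vb.R[0, 0]))
    se_boot = np.std(boots, ddof=1)
    assert abs(se_delta - se_boot) / se_boot < 0.25


def test_rg_diagonal_and_rank_one():
    P = np.diag([1.0, 2.0])
    vc = _vc(P, np.eye(2), np.eye(6) * 1e-4)
    rg, se, sig = genetic_correlation(vc, 0, 1)
    assert rg == 0.0 and not sig
    v = np.array([1.0, 0.5])
    vc2 = _vc(np.outer(v, v) + 1e-12 * np.eye(2), np.eye(2), np.eye(6) * 1e-4)
    rg2, _, _ = genetic_correlation(vc2, 0, 1)
    assert rg2 == pytest.approx(1.0, abs=1e-6)


def test_rg_zero_genetic_variance_error():
    vc = _vc(np.diag([0.0, 1.0]), np.eye(2))
    with pytest.raises(ValueError, match="undefined"):
        genetic_correlation(vc, 0, 1)


# ---------------------------------------------------------------------------
# selection-bias guard
# ---------------------------------------------------------------------------


def test_multitrait_frame_reduces_selection_bias():
    """Truncation selection on trait 1 biases the single-trait h2 of a
    correlated trait 3; including the selection trait in the frame
    should reduce the average absolute bias."""
    from microherit.simulate import SimulationConfig, TraitSpec, simulate_dataset
    from microherit.pipeline import default_fixed_effects

    bias_single, bias_multi = [], []
    true_h2 = 0.4
    for seed in range(10):
        cfg = SimulationConfig(
            seed=1000 + seed, n_founders=150, n_generations=4, n_snps=10,
            n_otus=30, depth_range=(300, 600),
            trait_specs=[
                TraitSpec("sel", 0.4, 0.0, 1.0),
                TraitSpec("cv_milk", 0.22, 54.0, 148.0),
                TraitSpec("focal", true_h2, 0.0, 1.0),
            ],
            genetic_correlations=[("sel", "focal", 0.6)],
            divergent_selection=True,
            selection_fraction=0.4,
        )
        ds = simulate_dataset(cfg)
        A = ds.pedigree._A
        ids = ds.phenotypes["animal"].astype(str).tolist()
        pos = {a: i for i, a in enumerate(ds.pedigree.ids)}
        idx = np.array([pos[a] for a in ids])
        A_phi = pd.DataFrame(A[np.ix_(idx, idx)], index=ids, columns=ids)
        f = {t: default_fixed_effects(t)[0] for t in ("sel", "cv_milk", "focal")}
        c = {t: default_fixed_effects(t)[1] for t in ("sel", "cv_milk", "focal")}
        fr1 = build_model_frame(ds.phenotypes, ["focal"], f, c, ds.pedigree)
        fr3 = build_model_frame(
            ds.phenotypes, ["sel", "cv_milk", "focal"], f, c, ds.pedigree
        )
        r1 = AnimalModel(fr1, A_phi).fit(em_rounds=20, tol=1e-7, max_iter=40)
        r3 = AnimalModel(fr3, A_phi).fit(em_rounds=20, tol=1e-7, max_iter=40)
        bias_single.append(r1.heritability(0)[0] - true_h2)
        bias_multi.append(r3.heritability(2)[0] - true_h2)
    assert abs(np.mean(bias_multi)) <= abs(np.mean(bias_single)) + 0.02


def test_summary_renders(small_dataset, small_A, effects_for):
    traits = ["lscs", "fat_content"]
    f, c = effects_for(traits)
    frame = build_model_frame(
        small_dataset.phenotypes, traits, f, c, small_dataset.pedigree
    )
    res = AnimalModel(frame, small_A).fit(em_rounds=20, tol=1e-8)
    text = res.summary()
    assert "REML" in text and "fat_content" in text and "rg" in text
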