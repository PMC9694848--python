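"""Reproducible validation studies for the whole pipeline.

Each function runs one self-contained study — simulating data with the
package's own generator, fitting the corresponding model, and
measuring how well a known quantity is recovered or how exactly an
algebraic identity holds.  They are used by the test suite and by
``scripts/acceptance.py``; all randomness flows from the ``seed``
argument.

Problem sizes are chosen so every study runs in minutes on one CPU
while leaving enough information for the target quantity (e.g. 2,000
phenotyped ewes for variance-component recovery, 300 animals x 2,000
SNPs for the GBLUP/SNP-BLUP equivalence).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .animal_model import AnimalModel, build_model_frame
from .compositional import clr, filter_low_abundance, impute_zeros, standardise_columns
from .gwas import (
    SingleStepGwas,
    backsolve_snp_effects,
    fit_ssgblup,
    make_single_step,
    snp_sampling_sd,
)
from .pipeline import default_fixed_effects, rg_pair_table
from .relationship import (
    GenotypeSet,
    RelationshipMatrix,
    blend_G,
    build_A,
    build_H,
    compute_G_raw,
    extract_A22,
)
from .reml import MultiTraitREML
from .significance import empirical_threshold, permute_and_refit
from .simulate import (
    DAIRY_TRAITS,
    Qtl,
    SimulationConfig,
    TraitSpec,
    simulate_dataset,
    simulate_genotypes,
    simulate_pedigree,
)

__all__ = [
    "rg_stage_rows",
    "gblup_snpblup_equivalence",
    "h_matrix_identities",
    "h2_recovery",
    "rg_recovery",
    "halfsib_closed_form",
    "permutation_calibration",
    "gwas_power_and_null",
    "compositional_identities",
    "eq5_sampling_variance",
]

_LSCS = TraitSpec("lscs", 0.37, 3.29, 2.25)
_CVM = TraitSpec("cv_milk", 0.22, 53.93, 148.35)


def _frame_effects(traits):
    f = {t: default_fixed_effects(t)[0] for t in traits}
    c = {t: default_fixed_effects(t)[1] for t in traits}
    return f, c


# ---------------------------------------------------------------------------


def rg_stage_rows(n_otus: int = 306, n_traits: int = 18) -> dict:
    """Combinatorics of the genetic-correlation stage: one emitted row
    per (heritable OTU, dairy trait) pair."""
    otus = [f"OTU{i + 1:04d}" for i in range(n_otus)]
    traits = DAIRY_TRAITS[:n_traits]
    table = rg_pair_table(otus, traits)
    return {"n_rows": int(len(table)), "n_otus": n_otus, "n_traits": len(traits)}


def gblup_snpblup_equivalence(seed: int, n: int = 300, m: int = 2000) -> dict:
    """GBLUP <-> SNP-BLUP projection identity on an all-genotyped set.

    With alpha = 0, a = 0, b = 1 (G = ZZ'/2*sum(pq) exactly, centred at
    the true founder frequencies so G is full rank), the back-solved
    SNP effects must equal direct ridge SNP-BLUP and Z a_hat must
    reproduce the breeding values.
    """
    cfg = SimulationConfig(
        seed=seed, n_founders=n, n_generations=1, n_snps=m, n_otus=40,
        depth_range=(200, 400),
        trait_specs=[TraitSpec("t1", 0.4, 0.0, 1.0)],
        qtl_list=[Qtl(target="t1", variance_fraction=0.2, snp_index=0)],
    )
    ds = simulate_dataset(cfg)
    ids = ds.phenotypes["animal"].astype(str).tolist()
    geno = ds.genotypes.subset(ids)
    p = geno.frequencies()
    Z = geno.centered()
    denom = 2.0 * np.sum(p * (1.0 - p))
    k = 1.0 / denom
    G = Z @ Z.T / denom
    Gm = RelationshipMatrix(
        0.5 * (G + G.T), ids, "G_blended", meta={"a": 0.0, "b": 1.0, "alpha": 0.0}
    )
    sg2, se2 = 0.4, 0.6
    f, c = _frame_effects(["t1"])
    frame = build_model_frame(ds.phenotypes, ["t1"], f, c, ds.pedigree)
    _, g_hat, _ = fit_ssgblup(frame, Gm, sg2, se2, ids)
    Ginv = np.linalg.inv(Gm.values)
    a_hat = backsolve_snp_effects(g_hat.to_numpy(), Z, Ginv, k, 1.0, 0.0)
    # oracle: direct dense SNP-BLUP system (independent code path)
    X = np.hstack([x for x in frame.Xs])
    lam = se2 / (sg2 * k)
    pdim = X.shape[1]
    order = {a: i for i, a in enumerate(ids)}
    rows = [order[a] for a in frame.animal_ids]
    Zr = Z[rows]
    C = np.zeros((pdim + m, pdim + m))
    C[:pdim, :pdim] = X.T @ X
    C[:pdim, pdim:] = X.T @ Zr
    C[pdim:, :pdim] = Zr.T @ X
    C[pdim:, pdim:] = Zr.T @ Zr + lam * np.eye(m)
    rhs = np.concatenate([X.T @ frame.Y[:, 0], Zr.T @ frame.Y[:, 0]])
    a_direct = np.linalg.solve(C, rhs)[pdim:]
    return {
        "n": n,
        "m": m,
        "max_abs_diff_snp_blup": float(np.abs(a_hat - a_direct).max()),
        "max_abs_diff_projection": float(
            np.abs(Z @ a_hat - g_hat.to_numpy()).max()
        ),
    }


def h_matrix_identities(seed: int) -> dict:
    """H = A when G = A22, and the classical block inverse identity."""
    cfg = SimulationConfig(
        seed=seed, n_founders=12, n_generations=3, n_offspring_per_mating=2,
        n_snps=80, n_otus=40, depth_range=(300, 500),
        trait_specs=[TraitSpec("t1", 0.3, 0.0, 1.0)],
    )
    ped = simulate_pedigree(cfg)
    A = build_A(ped)
    gids = ped.ids[-10:]
    A22 = extract_A22(A, gids)
    H_collapse = build_H(
        A, RelationshipMatrix(A22.values, gids, "G_blended")
    )
    err_collapse = float(np.abs(H_collapse.values - A.values).max())
    geno = simulate_genotypes(ped, cfg).subset(gids)
    Gb = blend_G(compute_G_raw(geno), A22, alpha=0.05)
    H = build_H(A, Gb)
    Hinv = np.linalg.inv(H.values)
    Ainv = np.linalg.inv(A.values)
    pos = {a: i for i, a in enumerate(A.ids)}
    gi = np.array([pos[g] for g in gids])
    delta = np.zeros_like(Ainv)
    delta[np.ix_(gi, gi)] = np.linalg.inv(Gb.values) - np.linalg.inv(A22.values)
    err_inverse = float(np.abs(Hinv - (Ainv + delta)).max())
    return {
        "n_animals": len(ped),
        "h_equals_a_max_abs": err_collapse,
        "inverse_identity_max_abs": err_inverse,
    }


def h2_recovery(
    seed: int,
    n_replicates: int = 20,
    h2: float = 0.30,
    n_founders: int = 1000,
) -> dict:
    """Single-trait REML recovery of h2 on ~2,000 phenotyped ewes."""
    estimates = []
    for r in range(n_replicates):
        cfg = SimulationConfig(
            seed=seed + 101 * r, n_founders=n_founders, n_generations=5,
            n_snps=10, n_otus=40, depth_range=(200, 400),
            trait_specs=[TraitSpec("t1", h2, 0.0, 1.0)],
        )
        ds = simulate_dataset(cfg)
        A_phi = _phenotyped_A(ds)
        f, c = _frame_effects(["t1"])
        frame = build_model_frame(ds.phenotypes, ["t1"], f, c, ds.pedigree)
        res = AnimalModel(frame, A_phi).fit(em_rounds=30, tol=1e-8)
        estimates.append(res.heritability(0)[0])
    est = np.asarray(estimates)
    return {
        "true_h2": h2,
        "n_records": len(frame.animal_ids),
        "n_replicates": n_replicates,
        "mean_h2": float(est.mean()),
        "sd_h2": float(est.std(ddof=1)),
        "estimates": [float(e) for e in est],
    }


def _phenotyped_A(ds) -> pd.DataFrame:
    ids = ds.phenotypes["animal"].astype(str).tolist()
    A_full = getattr(ds.pedigree, "_A", None)
    if A_full is None:
        return build_A(ds.pedigree).to_dataframe().loc[ids, ids]
    pos = {a: i for i, a in enumerate(ds.pedigree.ids)}
    idx = np.array([pos[a] for a in ids])
    return pd.DataFrame(A_full[np.ix_(idx, idx)], index=ids, columns=ids)


def rg_recovery(
    seed: int, n_replicates: int = 20, rg: float = 0.6, n_founders: int = 1000
) -> dict:
    """4-trait frame recovery of a planted OTU-trait genetic correlation.

    The OTU enters the frame on its latent (log-abundance) scale, which
    is what the genetic correlation is defined on.
    """
    estimates = []
    for r in range(n_replicates):
        cfg = SimulationConfig(
            seed=seed + 211 * r, n_founders=n_founders, n_generations=5,
            n_snps=10, n_otus=30, depth_range=(200, 400),
            trait_specs=[_LSCS, _CVM, TraitSpec("fat_content", 0.5, 7.4, 1.3)],
            otu_h2=np.full(30, 0.25),
            genetic_correlations=[("OTU0001", "fat_content", rg)],
        )
        ds = simulate_dataset(cfg)
        A_phi = _phenotyped_A(ds)
        phen = ds.phenotypes.copy()
        latent = ds.truth["latent_otu"]
        phen["OTU0001"] = latent.loc[phen["animal"].astype(str), "OTU0001"].to_numpy()
        traits = ["lscs", "cv_milk", "OTU0001", "fat_content"]
        f, c = _frame_effects(traits)
        frame = build_model_frame(phen, traits, f, c, ds.pedigree)
        res = AnimalModel(frame, A_phi).fit(em_rounds=30, tol=1e-8)
        estimates.append(res.genetic_correlation(2, 3)[0])
    est = np.asarray(estimates)
    return {
        "true_rg": rg,
        "n_replicates": n_replicates,
        "mean_rg": float(est.mean()),
        "sd_rg": float(est.std(ddof=1)),
        "estimates": [float(e) for e in est],
    }


def halfsib_closed_form(
    seed: int, n_sires: int = 60, n_progeny: int = 15
) -> dict:
    """Animal-model AI-REML vs the balanced paternal-half-sib ANOVA
    closed form (sigma_s2 = (MSB - MSW)/k, sigma_g2 = 4 sigma_s2)."""
    rng = np.random.default_rng(seed)
    sg2, se2 = 0.3, 0.7
    s, k = n_sires, n_progeny
    n = s * k
    sire_bv = rng.normal(0.0, np.sqrt(sg2), s)
    sire_of = np.repeat(np.arange(s), k)
    bv = 0.5 * sire_bv[sire_of] + rng.normal(0.0, np.sqrt(0.75 * sg2), n)
    y = 10.0 + bv + rng.normal(0.0, np.sqrt(se2), n)
    recs = [(f"S{i}", "0", "0") for i in range(s)] + [
        (f"P{j}", f"S{sire_of[j]}", "0") for j in range(n)
    ]
    from .relationship import Pedigree

    ped = Pedigree(pd.DataFrame(recs, columns=["animal", "sire", "dam"]))
    A_phi = build_A(ped).submatrix([f"P{j}" for j in range(n)])
    eng = MultiTraitREML(y, [np.ones((n, 1))], A=A_phi)
    vc = eng.fit(np.array([[0.2]]), np.array([[0.8]]), em_rounds=30,
                 tol=1e-12, max_iter=200)
    ybar_s = y.reshape(s, k).mean(axis=1)
    MSB = k * np.sum((ybar_s - y.mean()) ** 2) / (s - 1)
    MSW = np.sum((y.reshape(s, k) - ybar_s[:, None]) ** 2) / (s * (k - 1))
    sg2_anova = 4.0 * (MSB - MSW) / k
    se2_anova = MSW - 0.75 * sg2_anova
    return {
        "sigma_g2_reml": float(vc.P[0, 0]),
        "sigma_g2_anova": float(sg2_anova),
        "sigma_e2_reml": float(vc.R[0, 0]),
        "sigma_e2_anova": float(se2_anova),
        "max_abs_diff": float(
            max(abs(vc.P[0, 0] - sg2_anova), abs(vc.R[0, 0] - se2_anova))
        ),
    }


def permutation_calibration(
    seed: int,
    n_null_otus: int = 100,
    n_perm: int = 200,
    n_founders: int = 100,
    error_rate: float = 0.05,
) -> dict:
    """Type-I error of the permutation threshold on truly null OTU.

    One reduced-size dataset carries ``n_null_otus`` OTU with h2 = 0;
    the empirical threshold comes from permutations of two
    representative OTU (one zero-rich, one zero-poor), and the
    false-positive rate is the fraction of null OTU whose estimated h2
    exceeds it.
    """
    cfg = SimulationConfig(
        seed=seed, n_founders=n_founders, n_generations=4,
        n_snps=10, n_otus=n_null_otus, otu_h2=np.zeros(n_null_otus),
        depth_range=(2000, 5000), trait_specs=[_LSCS, _CVM],
        # reduced-scale design: fewer environmental levels keep the
        # OTU model's fixed-effect dimension commensurate with n
        fixed_effect_levels={
            "year": 3, "lactation": 2, "litter_size": 2, "run": 3,
            "time_order": 4, "total_seq_class": 3, "test_day": 3,
        },
    )
    ds = simulate_dataset(cfg)
    A_phi = _phenotyped_A(ds)
    table = filter_low_abundance(ds.otu_counts, 0.0)
    clrm = standardise_columns(
        clr(impute_zeros(table), table.sample_ids, table.otu_ids)
    )
    clr_df = clrm.to_dataframe()
    animals = ds.phenotypes["animal"].astype(str).tolist()
    phen = ds.phenotypes.copy()
    oid0 = table.otu_ids[0]
    phen[oid0] = clr_df.loc[animals, oid0].to_numpy()
    traits = ["lscs", "cv_milk", oid0]
    f, c = _frame_effects(traits)
    frame = build_model_frame(phen, traits, f, c, ds.pedigree)

    zeros = (table.counts == 0).mean(axis=0)
    reps = [int(np.argmin(zeros)), int(np.argmax(zeros))]
    h2_null_perm = []
    for j, i_otu in enumerate(reps):
        values = clr_df.loc[animals, table.otu_ids[i_otu]].to_numpy()
        res = permute_and_refit(
            values, frame, A_phi, n_perm // 2, seed=seed + 7000 + j,
            error_rate=error_rate, em_rounds=10, tol=1e-6, max_iter=30,
        )
        h2_null_perm.append(res.h2_estimates)
    h2_null_perm = np.concatenate(h2_null_perm)
    threshold = empirical_threshold(h2_null_perm, error_rate)

    model = AnimalModel(frame, A_phi)
    engine = model.engine
    P0, R0 = model.default_start()
    h2_null = np.empty(n_null_otus)
    for i, oid in enumerate(table.otu_ids):
        engine.set_trait(2, clr_df.loc[animals, oid].to_numpy())
        vc = engine.fit(P0, R0, em_rounds=10, tol=1e-6, max_iter=30)
        tot = vc.P[2, 2] + vc.R[2, 2]
        h2_null[i] = vc.P[2, 2] / tot if tot > 0 else 0.0
    fp = int((h2_null > threshold).sum())
    fpr = fp / n_null_otus
    half = 1.96 * np.sqrt(max(fpr * (1 - fpr), 1e-12) / n_null_otus)
    return {
        "n_records": frame.n,
        "n_null_otus": n_null_otus,
        "n_perm": len(h2_null_perm),
        "threshold": float(threshold),
        "false_positive_rate": float(fpr),
        "ci_low": float(max(0.0, fpr - half)),
        "ci_high": float(min(1.0, fpr + half)),
        "null_h2_median": float(np.median(h2_null)),
        "null_h2_frac_below_0p02": float((h2_null < 0.02).mean()),
    }


def _gwas_one(seed: int, with_qtl: bool, n_founders: int = 400,
              n_snps: int = 5000) -> dict:
    qtl = [Qtl(target="t1", variance_fraction=0.10, snp_index=n_snps // 2)]
    cfg = SimulationConfig(
        seed=seed, n_founders=n_founders, n_generations=5, n_snps=n_snps,
        n_otus=40, depth_range=(200, 400),
        trait_specs=[TraitSpec("t1", 0.25, 0.0, 1.0)],
        qtl_list=qtl if with_qtl else [],
    )
    ds = simulate_dataset(cfg)
    A = build_A(ds.pedigree)
    ids = ds.phenotypes["animal"].astype(str).tolist()
    geno = ds.genotypes.subset(ids)
    ssm = make_single_step(A, geno, alpha=0.05)
    f, c = _frame_effects(["t1"])
    frame = build_model_frame(ds.phenotypes, ["t1"], f, c, ds.pedigree)
    # per-trait variance components re-estimated under the joint
    # relationship, as in a single-step evaluation
    H_phi = ssm.H.submatrix(frame.animal_ids)
    eng = MultiTraitREML(frame.Y, frame.Xs, A=H_phi)
    vc = eng.fit(*AnimalModel(frame, H_phi).default_start(), em_rounds=20,
                 tol=1e-8, max_iter=60)
    model = SingleStepGwas(frame, ssm, vc.P[0, 0], vc.R[0, 0])
    res = model.fit()
    out = {"n_genotyped": len(ids)}
    if with_qtl:
        truth = ds.truth["qtl"][0]
        regions = res.qtl_regions(distance_limit=1_000_000)
        sm = ssm.snp_map
        hit = False
        for reg in regions:
            row = sm.loc[sm["snp_id"] == reg.lead_snp].iloc[0]
            if (
                int(row["chromosome"]) == truth["chromosome"]
                and abs(int(row["position"]) - truth["position"]) <= 1_000_000
            ):
                hit = True
                break
        out["qtl_localised"] = bool(hit)
        mask = np.ones(len(res.table), dtype=bool)
        mask[truth["snp_index"]] = False
        out["null_frac_p05"] = float(
            (res.table.loc[mask, "p_value"] < 0.05).mean()
        )
    else:
        out["null_frac_p05"] = float((res.table["p_value"] < 0.05).mean())
    return out


def gwas_power_and_null(seed: int, n_replicates: int = 10) -> dict:
    """QTL localisation power and null p-value calibration of the
    ssGBLUP GWAS (one QTL at 10% of genetic variance, h2 = 0.25,
    ~800 genotyped ewes, 5,000 SNPs)."""
    hits = 0
    null_fracs = []
    for r in range(n_replicates):
        res_q = _gwas_one(seed + 307 * r, with_qtl=True)
        hits += int(res_q["qtl_localised"])
        res_n = _gwas_one(seed + 307 * r + 150, with_qtl=False)
        null_fracs.append(res_n["null_frac_p05"])
    fr = np.asarray(null_fracs)
    se = fr.std(ddof=1) / np.sqrt(len(fr))
    return {
        "n_replicates": n_replicates,
        "n_genotyped": res_q["n_genotyped"],
        "qtl_hits": int(hits),
        "power_pct": 100.0 * hits / n_replicates,
        "null_frac_mean": float(fr.mean()),
        "null_frac_se": float(se),
        "null_ci_low": float(fr.mean() - 2.262 * se),  # t(9), 95%
        "null_ci_high": float(fr.mean() + 2.262 * se),
    }


def compositional_identities(seed: int, n_tables: int = 20) -> dict:
    """CLR sum-to-zero and scale invariance on random count tables."""
    rng = np.random.default_rng(seed)
    max_rowsum = 0.0
    max_scale_dev = 0.0
    from .compositional import OtuTable

    for _ in range(n_tables):
        n, d = rng.integers(10, 30), rng.integers(20, 60)
        counts = rng.negative_binomial(2, 0.05, size=(n, d))
        counts[:, 0] += 1  # no all-zero samples
        table = OtuTable(counts, [f"s{i}" for i in range(n)],
                         [f"o{j}" for j in range(d)])
        comp = impute_zeros(table)
        V = clr(comp).values
        max_rowsum = max(max_rowsum, float(np.abs(V.sum(axis=1)).max()))
        # scaling a sample's counts leaves its CLR row unchanged
        row = comp[0] * 37.5
        V2 = clr(row[None, :]).values[0]
        max_scale_dev = max(max_scale_dev, float(np.abs(V2 - V[0]).max()))
    return {
        "n_tables": n_tables,
        "max_abs_row_sum": max_rowsum,
        "max_scale_invariance_dev": max_scale_dev,
    }


def eq5_sampling_variance(
    seed: int, n_founders: int = 60, n_snps: int = 300, n_mc: int = 2000
) -> dict:
    """Analytic SNP-effect sampling variance vs Monte-Carlo replicates.

    Phenotypes are redrawn ``n_mc`` times at fixed genotypes from the
    GBLUP model with known variance components; the empirical variance
    of each back-solved effect is compared with the analytic formula
    based on the prediction-error covariance.
    """
    cfg = SimulationConfig(
        seed=seed, n_founders=n_founders, n_generations=2, n_snps=n_snps,
        n_otus=40, depth_range=(200, 400),
        trait_specs=[TraitSpec("t1", 0.4, 0.0, 1.0)],
    )
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    A = build_A(ped)
    A22 = extract_A22(A, ped.ids)
    Gb = blend_G(compute_G_raw(geno, geno.frequencies()), A22, alpha=0.05)
    p = geno.frequencies()
    Z = geno.centered()
    k = 1.0 / (2.0 * np.sum(p * (1.0 - p)))
    n = len(ped.ids)
    sg2, se2 = 0.4, 0.6
    X = np.ones((n, 1))
    Ginv = np.linalg.inv(Gb.values)
    C = np.block(
        [
            [X.T @ X / se2, X.T / se2],
            [X / se2, np.eye(n) / se2 + Ginv / sg2],
        ]
    )
    Cinv = np.linalg.inv(C)
    Cu2u2 = Cinv[1:, 1:]
    b_fac = m_b = Gb.meta["b"]
    alpha = Gb.meta["alpha"]
    sd_analytic, _ = snp_sampling_sd(
        Z, Ginv, Gb.values, Cu2u2, sg2, k, b_fac, alpha
    )
    rng = np.random.default_rng(seed + 1)
    L = np.linalg.cholesky(Gb.values * sg2 + 1e-10 * np.eye(n))
    a_hats = np.empty((n_mc, n_snps))
    coef = k * (1.0 - alpha) * m_b
    for r in range(n_mc):
        y = 1.0 + L @ rng.standard_normal(n) + rng.normal(0, np.sqrt(se2), n)
        sol = Cinv @ np.concatenate([X.T @ y / se2, y / se2])
        a_hats[r] = coef * (Z.T @ (Ginv @ sol[1:]))
    var_mc = a_hats.var(axis=0)
    var_an = sd_analytic**2
    rel = np.abs(var_mc / var_an - 1.0)
    return {
        "n_animals": n,
        "n_snps": n_snps,
        "n_mc": n_mc,
        "mean_rel_err": float(rel.mean()),
        "p95_rel_err": float(np.quantile(rel, 0.95)),
        "max_rel_err": float(rel.max()),
    }
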