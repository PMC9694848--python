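"""Single-step GBLUP GWAS with back-solved SNP effects.

The single-trait model y = Xb + Wg + e with g ~ N(0, H sigma_g2) is
solved through Henderson's equations using the joint pedigree-genomic
relationship H.  SNP effects are recovered from the breeding values of
the genotyped animals,

    a_hat = (1 - alpha) * b * Z' G^-1 g_hat2 / (2 sum p_i q_i),

their sampling variances from the prediction-error covariance of those
breeding values,

    Var(a_hat_i) = k^2 (1-alpha)^2 b^2 z_i' G^-1 (G sigma_g2 - C^{u2u2}) G^-1 z_i,

with k = 1 / (2 sum p_i q_i), and two-sided normal p-values are
corrected by Benjamini-Hochberg FDR (genome-wide 0.10, suggestive
0.30).  Significant SNPs are grouped into QTL regions around lead
SNPs, and the phenotypic variance explained is summarised over sliding
windows of 20 adjacent SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .animal_model import ModelFrame
from .relationship import (
    GenotypeSet,
    RelationshipMatrix,
    blend_G,
    build_H,
    compute_G_raw,
    extract_A22,
)
from .reml import solve_mme

__all__ = [
    "SingleStepMatrices",
    "make_single_step",
    "SingleStepGwas",
    "GwasResults",
    "QtlRegion",
    "fit_ssgblup",
    "backsolve_snp_effects",
    "snp_sampling_sd",
    "snp_pvalues",
    "fdr_adjust",
    "group_qtl_regions",
    "ld_r2",
    "window_variance_explained",
    "allele_substitution",
]


@dataclass
class SingleStepMatrices:
    """A, blended G, H and the centred genotype matrix for one analysis."""

    A: RelationshipMatrix
    G: RelationshipMatrix  # blended
    H: RelationshipMatrix
    Z: np.ndarray  # centred allele counts, genotyped animals x SNPs
    k: float  # 1 / (2 sum p_i q_i)
    snp_map: pd.DataFrame
    genotyped_ids: list[str]
    Ginv: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.Ginv is None:
            self.Ginv = np.linalg.inv(self.G.values)

    @property
    def alpha(self) -> float:
        return self.G.meta.get("alpha", 0.0)

    @property
    def b(self) -> float:
        return self.G.meta.get("b", 1.0)


def make_single_step(
    A: RelationshipMatrix,
    genotypes: GenotypeSet,
    alpha: float = 0.05,
    freqs: np.ndarray | None = None,
) -> SingleStepMatrices:
    """Assemble G (VanRaden, tuned and blended with A22) and H."""
    p = genotypes.frequencies() if freqs is None else np.asarray(freqs, float)
    G_raw = compute_G_raw(genotypes, p)
    A22 = extract_A22(A, genotypes.ids)
    G = blend_G(G_raw, A22, alpha=alpha)
    H = build_H(A, G)
    Z = genotypes.centered(p)
    k = 1.0 / (2.0 * np.sum(p * (1.0 - p)))
    return SingleStepMatrices(
        A=A,
        G=G,
        H=H,
        Z=Z,
        k=k,
        snp_map=genotypes.snp_map.reset_index(drop=True),
        genotyped_ids=list(genotypes.ids),
    )


@dataclass
class QtlRegion:
    lead_snp: str
    chromosome: int
    start: int
    end: int
    members: list[str]
    lead_mlogp: float
    variance_pct: float | None = None


def fit_ssgblup(
    frame: ModelFrame,
    H: RelationshipMatrix,
    sigma_g2: float,
    sigma_e2: float,
    genotyped_ids=None,
):
    """Solve the single-trait ssGBLUP MME.

    Returns (b_hat, g_hat over all H animals as a pandas Series,
    C^{u2u2}: the prediction-error covariance block of the genotyped
    animals, or of all animals when ``genotyped_ids`` is None).
    """
    if frame.n_traits != 1:
        raise ValueError("ssGBLUP GWAS uses a single-trait frame")
    pos = {a: i for i, a in enumerate(H.ids)}
    try:
        animal_index = np.array([pos[a] for a in frame.animal_ids])
    except KeyError as exc:
        raise KeyError(f"phenotyped animal missing from H: {exc}") from exc
    Hinv = np.linalg.inv(H.values)
    sol = solve_mme(
        frame.Y,
        frame.Xs,
        animal_index,
        Hinv,
        np.array([[sigma_g2]]),
        np.array([[sigma_e2]]),
    )
    g_hat = pd.Series(sol.u[:, 0], index=H.ids)
    pev = sol.pev_block()
    if genotyped_ids is not None:
        gi = np.array([pos[str(a)] for a in genotyped_ids])
        pev = pev[np.ix_(gi, gi)]
    return sol.b, g_hat, pev


def backsolve_snp_effects(
    g_hat2: np.ndarray,
    Z: np.ndarray,
    Ginv: np.ndarray,
    k: float,
    b: float,
    alpha: float,
) -> np.ndarray:
    """a_hat = (1-alpha) b k Z' G^-1 g_hat2."""
    g_hat2 = np.asarray(g_hat2, float)
    return (1.0 - alpha) * b * k * (Z.T @ (Ginv @ g_hat2))


def snp_sampling_sd(
    Z: np.ndarray,
    Ginv: np.ndarray,
    G: np.ndarray,
    Cu2u2: np.ndarray,
    sigma_g2: float,
    k: float,
    b: float,
    alpha: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampling SD of each back-solved SNP effect.

    Negative computed variances (possible with a blended G) are floored
    at zero and flagged; monomorphic (all-zero after centring) SNPs get
    sd 0 and must be excluded from testing.
    """
    mid = Ginv @ (G * sigma_g2 - Cu2u2) @ Ginv
    c = k * (1.0 - alpha) * b
    M = mid @ Z
    var = c * c * np.einsum("sj,sj->j", Z, M)
    flagged = var < 0
    var = np.where(flagged, 0.0, var)
    return np.sqrt(var), flagged


def snp_pvalues(a_hat: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Two-sided normal p-values; NaN where sd == 0 (untestable SNP)."""
    a_hat = np.asarray(a_hat, float)
    sd = np.asarray(sd, float)
    p = np.full(a_hat.shape, np.nan)
    ok = sd > 0
    z = np.abs(a_hat[ok] / sd[ok])
    p[ok] = 2.0 * norm.sf(z)
    return p


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaN-safe)."""
    p = np.asarray(p_values, float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def group_qtl_regions(
    table: pd.DataFrame,
    distance_limit: float = 1_000_000,
    peak_fraction: float = 1.0 / 3.0,
    significance_col: str = "significant",
) -> list[QtlRegion]:
    """Group significant SNPs into QTL regions around lead SNPs.

    Iteratively, per chromosome: the most significant remaining SNP
    becomes a lead; significant SNPs within ``distance_limit`` of the
    lead whose -log10 p reaches the upper ``peak_fraction`` of the
    peak (i.e. >= (1 - peak_fraction) * lead's -log10 p) join its
    region; the rest seed further regions.  Singletons are allowed.
    """
    regions: list[QtlRegion] = []
    sig = table[table[significance_col] & table["p_value"].notna()].copy()
    if sig.empty:
        return regions
    sig["mlogp"] = -np.log10(np.clip(sig["p_value"].to_numpy(), 1e-300, None))
    for chrom, grp in sig.groupby("chromosome"):
        pool = grp.sort_values("position").reset_index(drop=True)
        while not pool.empty:
            lead = pool.loc[pool["mlogp"].idxmax()]
            near = (pool["position"] - lead["position"]).abs() <= distance_limit
            tall = pool["mlogp"] >= (1.0 - peak_fraction) * lead["mlogp"]
            take = near & tall
            members = pool[take]
            regions.append(
                QtlRegion(
                    lead_snp=str(lead["snp_id"]),
                    chromosome=int(chrom),
                    start=int(members["position"].min()),
                    end=int(members["position"].max()),
                    members=members["snp_id"].astype(str).tolist(),
                    lead_mlogp=float(lead["mlogp"]),
                )
            )
            pool = pool[~take].reset_index(drop=True)
    regions.sort(key=lambda r: -r.lead_mlogp)
    return regions


def ld_r2(gi: np.ndarray, gj: np.ndarray) -> float:
    """Squared Pearson correlation of allele counts of two SNPs."""
    gi = np.asarray(gi, float)
    gj = np.asarray(gj, float)
    if gi.std() == 0 or gj.std() == 0:
        raise ValueError("LD undefined for a monomorphic SNP")
    r = np.corrcoef(gi, gj)[0, 1]
    return float(r * r)


def _window_slices(snp_map: pd.DataFrame, window: int):
    """Centred, edge-truncated windows of adjacent SNPs per chromosome."""
    half_lo = window // 2
    half_hi = window - half_lo
    for _, grp in snp_map.groupby("chromosome", sort=False):
        idx = grp.index.to_numpy()
        m = len(idx)
        for loc in range(m):
            lo = max(0, loc - half_lo)
            hi = min(m, loc + half_hi)
            lo = max(0, min(lo, hi - window))
            yield idx[loc], idx[lo:hi]


def window_variance_explained(
    a_hat: np.ndarray,
    Z: np.ndarray,
    snp_map: pd.DataFrame,
    sigma_p2: float,
    window: int = 20,
) -> np.ndarray:
    """Percent phenotypic variance explained by each SNP's window.

    For SNP i, the window is the (up to) ``window`` adjacent SNPs on the
    same chromosome centred on i; the statistic is
    Var_individuals(Z_w a_w) / sigma_p2 * 100 with centred counts.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    a_hat = np.asarray(a_hat, float)
    out = np.zeros(len(a_hat))
    sm = snp_map.reset_index(drop=True)
    for i, cols in _window_slices(sm, window):
        score = Z[:, cols] @ a_hat[cols]
        out[i] = score.var() / sigma_p2 * 100.0
    return out


def allele_substitution(
    y: np.ndarray,
    snp_column: np.ndarray,
    X: np.ndarray,
    animal_index: np.ndarray,
    A: np.ndarray,
    sigma_g2: float = 1.0,
    sigma_e2: float = 1.0,
) -> tuple[float, float]:
    """Allele-substitution effect of one SNP as a fixed covariate.

    GLS of y on [snp, X] with V = W A W' sigma_g2 + I sigma_e2 (the
    polygenic animal effect absorbed into the covariance); returns the
    per-allele-copy effect and its SE.  The unit-variance case
    (sigma_g2 = sigma_e2 = 1) corresponds to a model with a ~ N(0, A)
    and e ~ N(0, I).
    """
    y = np.asarray(y, float)
    g = np.asarray(snp_column, float)
    if g.std() == 0:
        raise ValueError("SNP is monomorphic in the phenotyped set")
    Xf = np.column_stack([g, np.atleast_2d(X)])
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise ValueError("SNP column aliased with a fixed-effect column")
    idx = np.asarray(animal_index, int)
    n = len(y)
    WAW = A[np.ix_(idx, idx)]
    V = sigma_g2 * WAW + sigma_e2 * np.eye(n)
    Vi_X = np.linalg.solve(V, Xf)
    XtViX = Xf.T @ Vi_X
    cov = np.linalg.inv(XtViX)
    beta = cov @ (Vi_X.T @ y)
    return float(beta[0]), float(np.sqrt(cov[0, 0]))


class SingleStepGwas:
    """ssGBLUP GWAS model for one trait.

    Parameters
    ----------
    frame : single-trait ModelFrame (response + fixed-effect design).
    matrices : SingleStepMatrices from :func:`make_single_step`.
    sigma_g2, sigma_e2 : variance components for the trait (estimated
        beforehand, e.g. with the multi-trait animal model or a
        single-trait refit).
    sigma_p2 : phenotypic variance used for window-variance
        percentages; defaults to the sample variance of the response.
    """

    def __init__(
        self,
        frame: ModelFrame,
        matrices: SingleStepMatrices,
        sigma_g2: float,
        sigma_e2: float,
        sigma_p2: float | None = None,
    ):
        if frame.n_traits != 1:
            raise ValueError("SingleStepGwas takes a single-trait frame")
        self.frame = frame
        self.m = matrices
        self.sigma_g2 = float(sigma_g2)
        self.sigma_e2 = float(sigma_e2)
        self.sigma_p2 = (
            float(np.var(frame.Y[:, 0], ddof=1)) if sigma_p2 is None else float(sigma_p2)
        )

    def fit(self, fdr_significant: float = 0.10, fdr_suggestive: float = 0.30):
        m = self.m
        b_hat, g_hat, Cu2u2 = fit_ssgblup(
            self.frame, m.H, self.sigma_g2, self.sigma_e2, m.genotyped_ids
        )
        g2 = g_hat.loc[m.genotyped_ids].to_numpy()
        a_hat = backsolve_snp_effects(g2, m.Z, m.Ginv, m.k, m.b, m.alpha)
        sd, floored = snp_sampling_sd(
            m.Z, m.Ginv, m.G.values, Cu2u2, self.sigma_g2, m.k, m.b, m.alpha
        )
        p = snp_pvalues(a_hat, sd)
        q = fdr_adjust(p)
        table = m.snp_map.copy()
        table["effect"] = a_hat
        table["sd"] = sd
        table["p_value"] = p
        table["q_value"] = q
        with np.errstate(invalid="ignore"):
            table["significant"] = np.where(np.isfinite(q), q < fdr_significant, False)
            table["suggestive"] = np.where(np.isfinite(q), q < fdr_suggestive, False)
        table["var_floored"] = floored
        table["untestable"] = ~np.isfinite(p)
        wv = window_variance_explained(a_hat, m.Z, m.snp_map, self.sigma_p2)
        table["var_window_pct"] = wv
        return GwasResults(self, table, b_hat, g_hat, Cu2u2)


class GwasResults:
    """Per-SNP GWAS table plus QTL-region utilities."""

    def __init__(self, model: SingleStepGwas, table: pd.DataFrame, b_hat, g_hat, Cu2u2):
        self.model = model
        self.table = table
        self.b_hat = b_hat
        self.g_hat = g_hat
        self.Cu2u2 = Cu2u2

    def qtl_regions(
        self,
        distance_limit: float = 1_000_000,
        peak_fraction: float = 1.0 / 3.0,
    ) -> list[QtlRegion]:
        regions = group_qtl_regions(self.table, distance_limit, peak_fraction)
        sm = self.model.m.snp_map
        pos_of = {s: i for i, s in enumerate(sm["snp_id"].astype(str))}
        a_hat = self.table["effect"].to_numpy()
        Z = self.model.m.Z
        window = 20
        for reg in regions:
            union: set[int] = set()
            for s in reg.members:
                i = pos_of[s]
                for lead_i, cols in _window_slices(sm, window):
                    if lead_i == i:
                        union.update(cols.tolist())
                        break
            cols = np.array(sorted(union), dtype=int)
            score = Z[:, cols] @ a_hat[cols]
            reg.variance_pct = float(score.var() / self.model.sigma_p2 * 100.0)
        return regions

    def manhattan_data(self) -> pd.DataFrame:
        out = self.table[
            ["snp_id", "chromosome", "position", "p_value", "significant", "suggestive"]
        ].copy()
        out["mlogp"] = -np.log10(np.clip(out["p_value"].to_numpy(), 1e-300, None))
        return out

    def summary(self) -> str:
        t = self.table
        n_sig = int(t["significant"].sum())
        n_sug = int(t["suggestive"].sum())
        lines = [
            "Single-step GBLUP GWAS",
            f"  SNPs tested: {int((~t['untestable']).sum())} of {len(t)}",
            f"  significant (FDR<0.10): {n_sig}   suggestive (FDR<0.30): {n_sug}",
            f"  sigma_g2={self.model.sigma_g2:.4g}  sigma_e2={self.model.sigma_e2:.4g}",
        ]
        if n_sig:
            top = t[t["significant"]].nsmallest(5, "p_value")
            lines.append(top[["snp_id", "chromosome", "position", "effect", "p_value"]]
                         .to_string(index=False))
        return "\n".join(lines)
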