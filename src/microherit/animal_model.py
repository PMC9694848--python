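"""Multi-trait animal model: design frames, fitting, and summaries.

The animal model treats each trait (a CLR-transformed OTU abundance or
a dairy trait) as

    y_t = X_t b_t + a_t + e_t,

with per-animal additive genetic effects whose covariance across
animals is the relationship matrix A and across traits the genetic
covariance P.  Fitting is REML: an EM warm start (default 100 rounds)
followed by average-information refinement to a strict convergence
criterion (default 1e-10 on the relative parameter change).

Populations under directional selection bias single-trait estimates of
unselected traits; including the selection-criterion traits as the
first traits of a multi-trait frame restores (approximately) the
missing selection information, which is why frames here are built as
(selection trait 1, selection trait 2, focal trait[, second focal
trait]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr

from .relationship import Pedigree, RelationshipMatrix
from .reml import MultiTraitREML, VarianceComponents, solve_mme

__all__ = [
    "ModelFrame",
    "AnimalModel",
    "AnimalModelResults",
    "build_model_frame",
    "reml_em",
    "reml_ai",
    "heritability",
    "genetic_correlation",
]

# Default covariate plausibility ranges (days in milk spans the recording
# window of a dairy lactation study).
COVARIATE_RANGES: dict[str, tuple[float, float]] = {"dim": (28.0, 133.0)}


class DesignError(ValueError):
    pass


def _build_design(
    df: pd.DataFrame,
    factors: Sequence[str],
    covariates: Sequence[str],
    covariate_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Intercept + reference-coded dummies + covariates, full rank checked.

    Factor names may contain ':' to denote a nested/interaction factor
    built from the concatenated level labels of its components.
    """
    ranges = COVARIATE_RANGES if covariate_ranges is None else covariate_ranges
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]
    for f in factors:
        parts = [p.strip() for p in f.split(":")]
        for p in parts:
            if p not in df.columns:
                raise DesignError(f"fixed-effect column '{p}' not in phenotypes")
        if len(parts) == 1:
            lab = df[parts[0]].astype(str)
            dummies = pd.get_dummies(lab, prefix=f, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy())
                names.append(c)
        else:
            # 'a:b' = b nested within a: per level of the outer grouping,
            # dummies for the inner levels beyond a within-group reference
            # (these columns are orthogonal to the outer main effect, so
            # 'year' and 'year:lactation' can coexist in one design)
            outer = df[parts[0]].astype(str)
            for p in parts[1:-1]:
                outer = outer + "|" + df[p].astype(str)
            inner = df[parts[-1]].astype(str)
            for g in sorted(outer.unique()):
                in_g = (outer == g).to_numpy()
                levels = sorted(inner[in_g].unique())
                for lvl in levels[1:]:
                    cols.append((in_g & (inner == lvl).to_numpy()).astype(float))
                    names.append(f"{f}[{g}|{lvl}]")
    for c in covariates:
        if c not in df.columns:
            raise DesignError(f"covariate column '{c}' not in phenotypes")
        v = df[c].to_numpy(dtype=float)
        if c in ranges:
            lo, hi = ranges[c]
            if np.any(v < lo) or np.any(v > hi):
                warnings.warn(
                    f"covariate '{c}' outside expected range [{lo}, {hi}]",
                    stacklevel=3,
                )
        cols.append(v)
        names.append(c)
    X = np.column_stack(cols)
    # pivoted QR to name aliased columns on rank deficiency
    _, Rq, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rq))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[i] for i in piv[rank:]]
        raise DesignError(f"design rank-deficient; aliased columns: {aliased}")
    return X, names


@dataclass
class ModelFrame:
    """Responses, designs and animal mapping for one multi-trait model."""

    traits: list[str]
    Y: np.ndarray  # (n, T)
    Xs: list[np.ndarray]
    x_names: list[list[str]]
    animal_ids: list[str]

    def __post_init__(self):
        n = len(self.animal_ids)
        if self.Y.shape != (n, len(self.traits)):
            raise ValueError("Y shape mismatch")
        for X in self.Xs:
            if X.shape[0] != n:
                raise ValueError("design rows mismatch")

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def with_trait_values(self, trait: str | int, values: np.ndarray) -> "ModelFrame":
        t = trait if isinstance(trait, int) else self.traits.index(trait)
        Y = self.Y.copy()
        Y[:, t] = values
        return ModelFrame(list(self.traits), Y, self.Xs, self.x_names, list(self.animal_ids))


def build_model_frame(
    phenotypes: pd.DataFrame,
    traits: Sequence[str],
    fixed_effects: Mapping[str, Sequence[str]],
    covariates: Mapping[str, Sequence[str]] | None = None,
    pedigree: Pedigree | None = None,
    id_col: str = "animal",
    covariate_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> ModelFrame:
    """Assemble a multi-trait frame with complete-case restriction.

    Records missing any modelled trait or design column are dropped
    (the modelled subsets are assumed complete; partial records are not
    carried).  Every record must map to a pedigree animal when a
    pedigree is supplied.
    """
    covariates = covariates or {}
    used_cols = {id_col, *traits}
    for t in traits:
        for f in fixed_effects.get(t, []):
            used_cols.update(p.strip() for p in f.split(":"))
        used_cols.update(covariates.get(t, []))
    missing_cols = used_cols - set(phenotypes.columns)
    if missing_cols:
        raise DesignError(f"phenotype table lacks columns: {sorted(missing_cols)}")
    df = phenotypes[sorted(used_cols)].dropna().reset_index(drop=True)
    if df.empty:
        raise DesignError("no complete records for the requested traits")
    animals = df[id_col].astype(str).tolist()
    if pedigree is not None:
        known = set(pedigree.ids)
        orphan = [a for a in animals if a not in known]
        if orphan:
            raise DesignError(f"phenotyped animals absent from pedigree: {orphan[:5]}")
    Y = df[list(traits)].to_numpy(dtype=float)
    Xs, x_names = [], []
    for t in traits:
        X, names = _build_design(
            df, fixed_effects.get(t, []), covariates.get(t, []), covariate_ranges
        )
        Xs.append(X)
        x_names.append(names)
    return ModelFrame(list(traits), Y, Xs, x_names, animals)


class AnimalModel:
    """Multi-trait animal model bound to a frame and a relationship.

    Examples
    --------
    >>> model = AnimalModel(frame, A)            # doctest: +SKIP
    >>> res = model.fit()                        # doctest: +SKIP
    >>> res.heritability("OTU12")                # doctest: +SKIP
    """

    def __init__(self, frame: ModelFrame, relationship):
        self.frame = frame
        if isinstance(relationship, RelationshipMatrix):
            A_phi = relationship.submatrix(frame.animal_ids)
        elif isinstance(relationship, pd.DataFrame):
            A_phi = relationship.loc[frame.animal_ids, frame.animal_ids].to_numpy(float)
        else:
            A_phi = np.asarray(relationship, dtype=float)
            if A_phi.shape != (frame.n, frame.n):
                raise ValueError("relationship array must match frame records")
        self.A_phi = A_phi
        self._engine: MultiTraitREML | None = None

    @classmethod
    def from_dataframe(
        cls,
        phenotypes: pd.DataFrame,
        traits: Sequence[str],
        relationship,
        fixed_effects: Mapping[str, Sequence[str]],
        covariates: Mapping[str, Sequence[str]] | None = None,
        pedigree: Pedigree | None = None,
        id_col: str = "animal",
    ) -> "AnimalModel":
        frame = build_model_frame(
            phenotypes, traits, fixed_effects, covariates, pedigree, id_col
        )
        return cls(frame, relationship)

    @property
    def engine(self) -> MultiTraitREML:
        if self._engine is None:
            self._engine = MultiTraitREML(self.frame.Y, self.frame.Xs, A=self.A_phi)
        return self._engine

    def default_start(self) -> tuple[np.ndarray, np.ndarray]:
        """Diagonal start at 30% genetic / 70% residual of the OLS
        residual variance per trait."""
        T = self.frame.n_traits
        v = np.empty(T)
        for t in range(T):
            y, X = self.frame.Y[:, t], self.frame.Xs[t]
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            v[t] = max(resid.var(ddof=X.shape[1]), 1e-8)
        return np.diag(0.3 * v), np.diag(0.7 * v)

    def fit(
        self,
        start: tuple[np.ndarray, np.ndarray] | None = None,
        em_rounds: int = 100,
        tol: float = 1e-10,
        max_iter: int = 100,
    ) -> "AnimalModelResults":
        P0, R0 = start if start is not None else self.default_start()
        vc = self.engine.fit(P0, R0, em_rounds=em_rounds, tol=tol, max_iter=max_iter)
        return AnimalModelResults(self, vc)


class AnimalModelResults:
    """Variance components, heritabilities and genetic correlations."""

    def __init__(self, model: AnimalModel, components: VarianceComponents):
        self.model = model
        self.components = components

    # delegation conveniences -------------------------------------------
    @property
    def P(self) -> np.ndarray:
        return self.components.P

    @property
    def R(self) -> np.ndarray:
        return self.components.R

    @property
    def converged(self) -> bool:
        return self.components.converged

    @property
    def loglik(self) -> float:
        return self.components.loglik

    @property
    def traits(self) -> list[str]:
        return self.model.frame.traits

    def _trait_index(self, trait: str | int) -> int:
        return trait if isinstance(trait, int) else self.traits.index(trait)

    def heritability(self, trait: str | int) -> tuple[float, float]:
        return heritability(self.components, self._trait_index(trait))

    def genetic_correlation(self, t1: str | int, t2: str | int):
        return genetic_correlation(
            self.components, self._trait_index(t1), self._trait_index(t2)
        )

    def h2_table(self) -> pd.DataFrame:
        rows = []
        for t, name in enumerate(self.traits):
            h2, se = self.heritability(t)
            rows.append(
                {
                    "trait": name,
                    "sigma_g2": self.P[t, t],
                    "sigma_e2": self.R[t, t],
                    "h2": h2,
                    "se_h2": se,
                }
            )
        return pd.DataFrame(rows)

    def rg_table(self) -> pd.DataFrame:
        rows = []
        T = len(self.traits)
        for i in range(T):
            for j in range(i + 1, T):
                try:
                    rg, se, sig = self.genetic_correlation(i, j)
                except ValueError:
                    rg, se, sig = np.nan, np.nan, False
                rows.append(
                    {
                        "trait_1": self.traits[i],
                        "trait_2": self.traits[j],
                        "rg": rg,
                        "se_rg": se,
                        "significant": sig,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Multi-trait animal model (REML)"]
        lines.append(
            f"  n records: {self.model.frame.n}   traits: {len(self.traits)}   "
            f"converged: {self.converged}   iterations: {self.components.n_iterations}"
        )
        lines.append(f"  REML log-likelihood: {self.loglik:.4f}")
        if self.components.message:
            lines.append(f"  note: {self.components.message}")
        lines.append("")
        h2t = self.h2_table()
        lines.append(h2t.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        rgt = self.rg_table()
        if not rgt.empty:
            lines.append("")
            lines.append("Genetic correlations (significant if |rg| > 2 SE):")
            lines.append(
                rgt.to_string(index=False, float_format=lambda v: f"{v:.4f}")
            )
        return "\n".join(lines)

    def solve_mme(self, Kinv: np.ndarray, animal_index: np.ndarray):
        """BLUE/BLUP at the fitted components (dense Henderson system)."""
        return solve_mme(
            self.model.frame.Y,
            self.model.frame.Xs,
            animal_index,
            Kinv,
            self.P,
            self.R,
        )


# ---------------------------------------------------------------------------
# Spec-level operations
# ---------------------------------------------------------------------------


def reml_em(
    frame: ModelFrame, A, start=None, n_rounds: int = 100
) -> VarianceComponents:
    """EM-REML warm start: exactly ``n_rounds`` monotone updates."""
    model = AnimalModel(frame, A)
    P0, R0 = start if start is not None else model.default_start()
    P, R, path = model.engine.run_em(P0, R0, n_rounds)
    names = [f"{w}[{i},{j}]" for w, i, j in model.engine.basis]
    return VarianceComponents(
        P=P,
        R=R,
        cov_params=None,
        param_names=names,
        loglik=path[-1] if path else -np.inf,
        converged=False,
        n_iterations=n_rounds,
        message="EM warm start (not converged by design)",
        loglik_path=path,
    )


def reml_ai(
    frame: ModelFrame,
    A,
    warm_start: VarianceComponents | tuple,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> VarianceComponents:
    """AI-REML from a warm start; EM fallback when an AI step fails."""
    model = AnimalModel(frame, A)
    if isinstance(warm_start, VarianceComponents):
        P0, R0 = warm_start.P, warm_start.R
    else:
        P0, R0 = warm_start
    return model.engine.fit(P0, R0, em_rounds=0, tol=tol, max_iter=max_iter)


def _param_cov(vc: VarianceComponents, names: list[str]) -> np.ndarray:
    if vc.cov_params is None:
        return np.full((len(names), len(names)), np.nan)
    idx = [vc.param_index(n) for n in names]
    return vc.cov_params[np.ix_(idx, idx)]


def heritability(vc: VarianceComponents, trait: int) -> tuple[float, float]:
    """h2 = sigma_g2 / (sigma_g2 + sigma_e2) with a delta-method SE."""
    g, e = vc.P[trait, trait], vc.R[trait, trait]
    tot = g + e
    if tot <= 0:
        raise ValueError("zero total variance: heritability undefined")
    h2 = float(np.clip(g / tot, 0.0, 1.0))
    grad = np.array([e / tot**2, -g / tot**2])
    C = _param_cov(vc, [f"P[{trait},{trait}]", f"R[{trait},{trait}]"])
    var = float(grad @ C @ grad)
    se = float(np.sqrt(var)) if np.isfinite(var) and var >= 0 else np.nan
    return h2, se


def genetic_correlation(
    vc: VarianceComponents, i: int, j: int
) -> tuple[float, float, bool]:
    """rg = P_ij / sqrt(P_ii P_jj); significant when |rg| > 2 SE."""
    gii, gjj, gij = vc.P[i, i], vc.P[j, j], vc.P[i, j]
    if gii <= 0 or gjj <= 0:
        raise ValueError("zero genetic variance: correlation undefined")
    rg = gij / np.sqrt(gii * gjj)
    rg_c = float(np.clip(rg, -1.0, 1.0))
    lo, hi = (min(i, j), max(i, j))
    names = [f"P[{lo},{hi}]", f"P[{i},{i}]", f"P[{j},{j}]"]
    grad = np.array(
        [1.0 / np.sqrt(gii * gjj), -rg / (2.0 * gii), -rg / (2.0 * gjj)]
    )
    C = _param_cov(vc, names)
    var = float(grad @ C @ grad)
    se = float(np.sqrt(var)) if np.isfinite(var) and var >= 0 else np.nan
    significant = bool(np.isfinite(se) and abs(rg_c) > 2.0 * se)
    return rg_c, se, significant
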