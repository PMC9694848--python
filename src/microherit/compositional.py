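"""Compositional preprocessing of OTU count tables.

Microbiota counts are compositional: the sequencing depth imposes the
row total, so only ratios between parts are informative.  The pipeline
here is the standard log-ratio chain: abundance filtering, geometric
Bayesian-multiplicative (GBM) zero replacement, centred log-ratio (CLR)
transform, and per-OTU scaling to unit variance, in that fixed order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "ClrMatrix",
    "filter_low_abundance",
    "impute_zeros",
    "clr",
    "standardise_columns",
    "core_microbiome",
]

TAXONOMY_RANKS = [
    "domain", "phylum", "class", "order", "family", "genus", "species",
]


@dataclass
class OtuTable:
    """Non-negative integer counts (samples x OTU) with taxonomy.

    ``taxonomy`` maps otu_id -> taxonomic ranks; the genus may be
    ``"unknown"`` when assignment stops at a higher rank.
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.sample_ids),
            len(self.otu_ids),
        ):
            raise ValueError("counts shape must be (n_samples, n_otus)")
        if np.any(self.counts < 0):
            raise ValueError("negative counts are not allowed")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids not unique")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("otu ids not unique")
        if self.taxonomy is not None:
            missing = set(self.otu_ids) - set(self.taxonomy.index.astype(str))
            if missing:
                raise ValueError(
                    f"taxonomy missing for OTU: {sorted(missing)[:5]}"
                )

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def genus_of(self, otu_id: str) -> str:
        if self.taxonomy is None:
            return "unknown"
        return str(self.taxonomy.loc[str(otu_id), "genus"])


@dataclass
class ClrMatrix:
    """CLR-transformed values; rows sum to zero before standardisation."""

    values: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    standardised: bool = False
    scale: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not self.standardised:
            rowsums = np.abs(self.values.sum(axis=1))
            if rowsums.size and rowsums.max() > 1e-8:
                raise ValueError(
                    f"CLR rows must sum to 0 (max |row sum| = {rowsums.max():.2e})"
                )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)

    def column(self, otu_id: str) -> np.ndarray:
        return self.values[:, self.otu_ids.index(str(otu_id))]


def filter_low_abundance(table: OtuTable, threshold_fraction: float) -> OtuTable:
    """Drop OTU whose share of the grand total is below the threshold.

    The 0.005% cluster filter of amplicon pipelines corresponds to
    ``threshold_fraction = 5e-5``.
    """
    if not 0.0 <= threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in [0, 1)")
    if table.counts.size == 0:
        raise ValueError("empty OTU table")
    totals = table.counts.sum(axis=0).astype(float)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("OTU table has no counts")
    keep = totals / grand >= threshold_fraction
    if not keep.any():
        raise ValueError("threshold removes every OTU")
    otu_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    tax = table.taxonomy.loc[otu_ids] if table.taxonomy is not None else None
    return OtuTable(table.counts[:, keep], list(table.sample_ids), otu_ids, tax)


def impute_zeros(
    table: OtuTable, prior_strength: float | None = None
) -> np.ndarray:
    """Geometric Bayesian-multiplicative zero replacement.

    Zeros in row i are replaced by ``s/(n_i + s) * t_j`` where n_i is
    the row total, s the Dirichlet prior strength (default
    ``sqrt(n_parts)``) and t_j a prior composition proportional to the
    geometric mean of part j's closed proportions over the samples where
    it is observed (parts never observed fall back to the uniform prior
    weight before normalisation).  Observed parts are adjusted
    multiplicatively so each row remains a composition summing to one
    and pairwise ratios between observed parts are preserved.
    """
    X = np.asarray(table.counts, dtype=float)
    n, D = X.shape
    totals = X.sum(axis=1)
    zero_rows = np.where(totals == 0)[0]
    if zero_rows.size:
        raise ValueError(
            f"sample(s) with all-zero counts: {[table.sample_ids[i] for i in zero_rows[:5]]}"
        )
    s = math.sqrt(D) if prior_strength is None else float(prior_strength)
    closed = X / totals[:, None]
    with np.errstate(divide="ignore"):
        logc = np.where(closed > 0, np.log(closed), 0.0)
    obs = (closed > 0).sum(axis=0)
    t = np.full(D, 1.0 / D)
    seen = obs > 0
    t[seen] = np.exp(logc[:, seen].sum(axis=0) / obs[seen])
    t = t / t.sum()

    repl = (s / (totals[:, None] + s)) * t[None, :]
    zeros = closed == 0
    zsum = np.where(zeros, repl, 0.0).sum(axis=1)
    out = np.where(zeros, repl, closed * (1.0 - zsum)[:, None])
    if np.any(out <= 0):
        raise ValueError("imputation produced non-positive parts")
    return out


def clr(composition: np.ndarray | OtuTable, sample_ids=None, otu_ids=None) -> ClrMatrix:
    """Centred log-ratio transform: log(x) minus the row mean of log(x)."""
    if isinstance(composition, OtuTable):
        sample_ids = list(composition.sample_ids)
        otu_ids = list(composition.otu_ids)
        composition = composition.counts.astype(float)
    X = np.asarray(composition, dtype=float)
    if np.any(X <= 0):
        raise ValueError("CLR requires strictly positive input; impute zeros first")
    L = np.log(X)
    V = L - L.mean(axis=1, keepdims=True)
    n, D = V.shape
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    if otu_ids is None:
        otu_ids = [f"OTU{j}" for j in range(D)]
    return ClrMatrix(V, list(sample_ids), list(otu_ids), standardised=False)


def standardise_columns(clrm: ClrMatrix) -> ClrMatrix:
    """Scale each OTU column to unit sample variance (no recentering).

    The animal model's fixed effects absorb column means, so only the
    scale is adjusted.
    """
    V = clrm.values
    if V.shape[0] < 2:
        raise ValueError("need at least 2 samples to standardise")
    sd = V.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        bad = [o for o, z in zip(clrm.otu_ids, zero) if z]
        raise ValueError(f"zero-variance OTU columns: {bad[:5]}")
    return ClrMatrix(
        V / sd[None, :],
        list(clrm.sample_ids),
        list(clrm.otu_ids),
        standardised=True,
        scale=sd,
    )


def core_microbiome(table: OtuTable, occurrence: float = 0.90) -> set[str]:
    """OTU present (count > 0) in at least ``ceil(occurrence * n)`` samples."""
    if not 0.0 < occurrence <= 1.0:
        raise ValueError("occurrence must be in (0, 1]")
    need = math.ceil(occurrence * table.n_samples)
    present = (table.counts > 0).sum(axis=0)
    return {o for o, c in zip(table.otu_ids, present) if c >= need}
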