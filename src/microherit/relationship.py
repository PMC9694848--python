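"""Pedigree, genomic and joint relationship matrices.

Builds the numerator relationship matrix A from an ordered pedigree
(tabular method with inbreeding), the VanRaden genomic relationship
matrix G from centred allele counts, the blended G used in single-step
evaluations, and the joint pedigree-genomic matrix H that projects
genomic relationships onto non-genotyped ancestors.

All matrices are dense: the populations handled here are a few thousand
animals at most, where direct factorisation is exact and simple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

UNKNOWN_PARENT = "0"

__all__ = [
    "Pedigree",
    "GenotypeSet",
    "RelationshipMatrix",
    "ABlocks",
    "build_A",
    "partition_A",
    "extract_A22",
    "compute_G_raw",
    "blend_G",
    "build_H",
]


class PedigreeError(ValueError):
    pass


class Pedigree:
    """Ordered pedigree records (animal, sire, dam).

    Parents must precede their offspring; unknown parents are coded
    ``"0"``.  ``sort=True`` applies a topological sort (founders first)
    when the input is not already ordered.
    """

    def __init__(self, records: pd.DataFrame, sort: bool = False):
        required = {"animal", "sire", "dam"}
        if not required.issubset(records.columns):
            raise PedigreeError(f"pedigree needs columns {sorted(required)}")
        df = records[["animal", "sire", "dam"]].astype(str).reset_index(drop=True)
        if df["animal"].duplicated().any():
            dups = df.loc[df["animal"].duplicated(), "animal"].tolist()
            raise PedigreeError(f"duplicate animal ids: {dups[:5]}")
        known = set(df["animal"])
        for col in ("sire", "dam"):
            bad = set(df[col]) - known - {UNKNOWN_PARENT}
            if bad:
                raise PedigreeError(
                    f"{col} ids not in pedigree and not coded unknown: {sorted(bad)[:5]}"
                )
        if sort:
            df = self._toposort(df)
        self._check_order(df)
        self.records = df
        self._pos = {a: i for i, a in enumerate(df["animal"])}

    @staticmethod
    def _toposort(df: pd.DataFrame) -> pd.DataFrame:
        pos = {a: i for i, a in enumerate(df["animal"])}
        placed: dict[str, int] = {}
        order: list[int] = []
        remaining = list(range(len(df)))
        sires = df["sire"].tolist()
        dams = df["dam"].tolist()
        animals = df["animal"].tolist()
        while remaining:
            progressed = False
            still = []
            for i in remaining:
                ok = all(
                    p == UNKNOWN_PARENT or p in placed for p in (sires[i], dams[i])
                )
                if ok:
                    placed[animals[i]] = len(order)
                    order.append(i)
                    progressed = True
                else:
                    still.append(i)
            if not progressed:
                raise PedigreeError("pedigree contains a cycle")
            remaining = still
        del pos
        return df.iloc[order].reset_index(drop=True)

    @staticmethod
    def _check_order(df: pd.DataFrame) -> None:
        seen: set[str] = set()
        for animal, sire, dam in df.itertuples(index=False):
            for p in (sire, dam):
                if p != UNKNOWN_PARENT and p not in seen:
                    raise PedigreeError(
                        f"parent {p} of {animal} appears after its offspring; "
                        "construct with sort=True to reorder"
                    )
            seen.add(animal)

    @property
    def ids(self) -> list[str]:
        return self.records["animal"].tolist()

    def __len__(self) -> int:
        return len(self.records)

    def position(self, animal_id: str) -> int:
        return self._pos[str(animal_id)]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire and dam row indices (-1 for unknown)."""
        sidx = np.array(
            [self._pos.get(s, -1) if s != UNKNOWN_PARENT else -1 for s in self.records["sire"]],
            dtype=int,
        )
        didx = np.array(
            [self._pos.get(d, -1) if d != UNKNOWN_PARENT else -1 for d in self.records["dam"]],
            dtype=int,
        )
        return sidx, didx

    def relationship_matrix(self) -> "RelationshipMatrix":
        return build_A(self)


@dataclass
class GenotypeSet:
    """Individuals x SNPs allele counts (0/1/2, NaN = missing) plus map.

    ``allele_freqs`` may be supplied (e.g. true base-population
    frequencies from a simulation); otherwise frequencies of the counted
    allele are computed from the observed genotypes.
    """

    counts: np.ndarray
    ids: list[str]
    snp_map: pd.DataFrame  # columns: snp_id, chromosome, position
    allele_freqs: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.ids), len(self.snp_map)):
            raise ValueError("counts shape does not match ids x snp_map")
        for chrom, grp in self.snp_map.groupby("chromosome"):
            pos = grp["position"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not ascending on chromosome {chrom}")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def frequencies(self) -> np.ndarray:
        if self.allele_freqs is not None:
            return np.asarray(self.allele_freqs, dtype=float)
        return np.nanmean(self.counts, axis=0) / 2.0

    def centered(self, freqs: np.ndarray | None = None) -> np.ndarray:
        """Z = counts - 2p, with missing entries mean-imputed (to 0)."""
        p = self.frequencies() if freqs is None else np.asarray(freqs, float)
        Z = self.counts - 2.0 * p
        return np.where(np.isnan(Z), 0.0, Z)

    def subset(self, ids: Sequence[str]) -> "GenotypeSet":
        pos = {a: i for i, a in enumerate(self.ids)}
        rows = [pos[str(a)] for a in ids]
        return GenotypeSet(
            self.counts[rows], [str(a) for a in ids], self.snp_map, self.allele_freqs
        )


@dataclass
class RelationshipMatrix:
    values: np.ndarray
    ids: list[str]
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix must be square over ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.ids)}
        idx = np.array([pos[str(a)] for a in ids])
        return self.values[np.ix_(idx, idx)]


def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a(i,i) = 1 + F_i with F_i = a(sire,dam)/2; a(i,j) = (a(j,s)+a(j,d))/2.
    """
    n = len(pedigree)
    sidx, didx = pedigree.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sidx[i], didx[i]
        if s >= 0 and d >= 0:
            if i > 0:
                A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            if i > 0:
                A[i, :i] = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return RelationshipMatrix(A, pedigree.ids, kind="A")


class ABlocks(NamedTuple):
    A11: np.ndarray
    A12: np.ndarray
    A21: np.ndarray
    A22: np.ndarray
    nongenotyped: list[str]
    genotyped: list[str]


def partition_A(A: RelationshipMatrix, genotyped_ids: Sequence[str]) -> ABlocks:
    """Partition A into non-genotyped ("1") and genotyped ("2") blocks."""
    genotyped = [str(g) for g in genotyped_ids]
    pos = {a: i for i, a in enumerate(A.ids)}
    unknown = [g for g in genotyped if g not in pos]
    if unknown:
        raise KeyError(f"genotyped ids not in relationship matrix: {unknown[:5]}")
    gset = set(genotyped)
    nong = [a for a in A.ids if a not in gset]
    i1 = np.array([pos[a] for a in nong], dtype=int)
    i2 = np.array([pos[a] for a in genotyped], dtype=int)
    V = A.values
    return ABlocks(
        V[np.ix_(i1, i1)] if len(i1) else np.zeros((0, 0)),
        V[np.ix_(i1, i2)] if len(i1) else np.zeros((0, len(i2))),
        V[np.ix_(i2, i1)] if len(i1) else np.zeros((len(i2), 0)),
        V[np.ix_(i2, i2)],
        nong,
        genotyped,
    )


def extract_A22(A: RelationshipMatrix, genotyped_ids: Sequence[str]) -> RelationshipMatrix:
    blocks = partition_A(A, genotyped_ids)
    return RelationshipMatrix(blocks.A22, blocks.genotyped, kind="A22")


def compute_G_raw(
    genotypes: GenotypeSet, freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix G = ZZ' / 2*sum(p_i q_i)."""
    p = genotypes.frequencies() if freqs is None else np.asarray(freqs, float)
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        bad = genotypes.snp_map["snp_id"].to_numpy()[mono]
        raise ValueError(
            f"monomorphic SNPs (p in {{0,1}}): {list(bad[:5])}; run genotype QC first"
        )
    Z = genotypes.centered(p)
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = Z @ Z.T / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(
        G, genotypes.ids, kind="G_raw", meta={"denom": denom, "freqs": p}
    )


def blend_G(
    G_raw: RelationshipMatrix,
    A22: RelationshipMatrix,
    alpha: float = 0.05,
) -> RelationshipMatrix:
    """Tune and blend G with A22: (1-alpha)*(a + b*G_raw) + alpha*A22.

    The intercept a and slope b solve the 2x2 system equating mean
    diagonal (average inbreeding) and mean off-diagonal (average
    relationship) of the tuned G with those of A22.
    """
    if G_raw.values.shape != A22.values.shape:
        raise ValueError("G_raw and A22 are not conformable")
    n = G_raw.values.shape[0]
    offmask = ~np.eye(n, dtype=bool)
    mdiag_g = float(np.mean(np.diag(G_raw.values)))
    moff_g = float(np.mean(G_raw.values[offmask])) if n > 1 else 0.0
    mdiag_a = float(np.mean(np.diag(A22.values)))
    moff_a = float(np.mean(A22.values[offmask])) if n > 1 else 0.0
    M = np.array([[1.0, mdiag_g], [1.0, moff_g]])
    if abs(np.linalg.det(M)) < 1e-12:
        raise ValueError(
            "tuning system singular (G_raw has equal mean diagonal and "
            "off-diagonal); cannot solve for a, b"
        )
    a, b = np.linalg.solve(M, np.array([mdiag_a, moff_a]))
    G = (1.0 - alpha) * (a + b * G_raw.values) + alpha * A22.values
    G = 0.5 * (G + G.T)
    out = RelationshipMatrix(
        G,
        G_raw.ids,
        kind="G_blended",
        meta={**G_raw.meta, "a": float(a), "b": float(b), "alpha": float(alpha)},
    )
    if alpha > 0:
        w = np.linalg.eigvalsh(G)
        if w[0] <= 0:
            raise ValueError(
                f"blended G not positive definite (min eigenvalue {w[0]:.3e}); "
                "check A22 and alpha"
            )
    return out


def build_H(
    A: RelationshipMatrix,
    G_blended: RelationshipMatrix,
) -> RelationshipMatrix:
    """Joint pedigree-genomic relationship matrix.

    H's genotyped block equals G; genomic information is projected onto
    non-genotyped animals through A12 A22^-1.  The result is returned in
    the id order of A.
    """
    blocks = partition_A(A, G_blended.ids)
    G = G_blended.values
    if G.shape != blocks.A22.shape:
        raise ValueError("G dimension does not match genotyped block of A")
    n1 = len(blocks.nongenotyped)
    if n1 == 0:
        return RelationshipMatrix(G.copy(), list(G_blended.ids), kind="H",
                                  meta=dict(G_blended.meta))
    A22_inv = np.linalg.inv(blocks.A22)
    T = blocks.A12 @ A22_inv  # n1 x n2 projection
    H11 = blocks.A11 - T @ blocks.A21 + T @ G @ T.T
    H12 = T @ G
    order = blocks.nongenotyped + blocks.genotyped
    n = len(order)
    H = np.empty((n, n))
    H[:n1, :n1] = H11
    H[:n1, n1:] = H12
    H[n1:, :n1] = H12.T
    H[n1:, n1:] = G
    # permute back to A's original id order
    pos = {a: i for i, a in enumerate(order)}
    perm = np.array([pos[a] for a in A.ids])
    H = H[np.ix_(perm, perm)]
    H = 0.5 * (H + H.T)
    return RelationshipMatrix(H, list(A.ids), kind="H", meta=dict(G_blended.meta))
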