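"""Table readers/writers and genotype quality control.

Dialects (all plain text):
  pedigree      CSV  animal,sire,dam           unknown parents coded 0
  genotypes     TSV  FID IID snp1 ... snpm     entries 0/1/2, NA missing
  SNP map       TSV  chromosome snp_id position
  OTU counts    TSV  sample_id + one integer column per OTU
  taxonomy      TSV  otu_id + 7 rank columns (domain..species)
  phenotypes    CSV  animal + trait and environment columns
  truth         JSON summary of the simulated architecture
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .compositional import OtuTable, TAXONOMY_RANKS
from .relationship import GenotypeSet, Pedigree
from .simulate import SimulatedDataset

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_genotypes",
    "write_genotypes",
    "read_otu_table",
    "write_otu_table",
    "read_phenotypes",
    "write_phenotypes",
    "write_truth",
    "write_dataset",
    "qc_genotypes",
]


class FormatError(ValueError):
    pass


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, comment="#")
    missing = {"animal", "sire", "dam"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: pedigree lacks columns {sorted(missing)}")
    # offspring-before-parent input is legal; reorder automatically
    return Pedigree(df, sort=True)


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.records.to_csv(path, index=False)


def read_genotypes(raw_path, map_path) -> GenotypeSet:
    raw = pd.read_csv(raw_path, sep="\t", dtype={"FID": str, "IID": str}, comment="#")
    if "IID" not in raw.columns:
        raise FormatError(f"{raw_path}: genotype table needs an IID column")
    snp_cols = [c for c in raw.columns if c not in ("FID", "IID")]
    counts = raw[snp_cols].to_numpy(dtype=float)
    bad = ~(np.isnan(counts) | np.isin(counts, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{raw_path}: line {i + 2}, column {snp_cols[j]}: allele count "
            f"{counts[i, j]} not in {{0,1,2,NA}}"
        )
    smap = pd.read_csv(map_path, sep="\t", comment="#")
    need = {"chromosome", "snp_id", "position"}
    if not need.issubset(smap.columns):
        raise FormatError(f"{map_path}: SNP map lacks columns {sorted(need - set(smap.columns))}")
    if list(smap["snp_id"].astype(str)) != snp_cols:
        raise FormatError("SNP map order does not match genotype columns")
    ids = raw["IID"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise FormatError(f"{raw_path}: duplicate individual ids")
    return GenotypeSet(counts, ids, smap[["snp_id", "chromosome", "position"]])


def write_genotypes(genotypes: GenotypeSet, raw_path, map_path) -> None:
    df = pd.DataFrame(
        genotypes.counts,
        columns=genotypes.snp_map["snp_id"].astype(str),
    )
    # counts are small integers; keep them integral in the file
    df = df.astype("Int64")
    df.insert(0, "IID", genotypes.ids)
    df.insert(0, "FID", "F0")
    df.to_csv(raw_path, sep="\t", index=False, na_rep="NA")
    genotypes.snp_map[["chromosome", "snp_id", "position"]].to_csv(
        map_path, sep="\t", index=False
    )


def read_otu_table(counts_path, taxonomy_path=None) -> OtuTable:
    df = pd.read_csv(counts_path, sep="\t", comment="#")
    sample_col = df.columns[0]
    samples = df[sample_col].astype(str).tolist()
    counts = df.drop(columns=[sample_col]).to_numpy()
    if not np.issubdtype(counts.dtype, np.number) or np.any(counts != counts.astype(int)):
        raise FormatError(f"{counts_path}: OTU counts must be integers")
    tax = None
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str, comment="#")
        if "otu_id" not in tax.columns:
            raise FormatError(f"{taxonomy_path}: taxonomy needs an otu_id column")
        tax = tax.set_index("otu_id")
    return OtuTable(
        counts.astype(np.int64), samples, list(df.columns[1:]), tax
    )


def write_otu_table(table: OtuTable, counts_path, taxonomy_path=None) -> None:
    df = table.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(counts_path, sep="\t")
    if taxonomy_path is not None and table.taxonomy is not None:
        out = table.taxonomy.copy()
        out.index.name = "otu_id"
        out[TAXONOMY_RANKS].to_csv(taxonomy_path, sep="\t")


def read_phenotypes(path, pedigree: Pedigree | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "animal" not in df.columns:
        raise FormatError(f"{path}: phenotype table needs an 'animal' column")
    df["animal"] = df["animal"].astype(str)
    if pedigree is not None:
        orphans = set(df["animal"]) - set(pedigree.ids)
        if orphans:
            raise FormatError(
                f"{path}: phenotyped animals absent from pedigree: {sorted(orphans)[:5]}"
            )
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def write_truth(truth: dict, path) -> None:
    """JSON summary of simulation truth (large arrays elided)."""
    summary = {
        k: v
        for k, v in truth.items()
        if k in ("latent_names", "h2", "sigma_g2", "sigma_e2", "realized_h2",
                 "qtl", "genetic_correlations")
    }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1)


def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "genotypes": outdir / "genotypes.raw.tsv",
        "snp_map": outdir / "genotypes.map.tsv",
        "otu_counts": outdir / "otu_counts.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "phenotypes": outdir / "phenotypes.csv",
        "truth": outdir / "truth.json",
    }
    write_pedigree(dataset.pedigree, paths["pedigree"])
    write_genotypes(dataset.genotypes, paths["genotypes"], paths["snp_map"])
    write_otu_table(dataset.otu_counts, paths["otu_counts"], paths["taxonomy"])
    write_phenotypes(dataset.phenotypes, paths["phenotypes"])
    write_truth(dataset.truth, paths["truth"])
    return paths


def qc_genotypes(
    genotypes: GenotypeSet,
    snp_call_rate: float = 0.90,
    ind_call_rate: float = 0.95,
    maf_min: float = 0.05,
) -> tuple[GenotypeSet, dict]:
    """Genotype quality control in a fixed order.

    1. drop SNPs with call rate below ``snp_call_rate``;
    2. drop individuals with call rate below ``ind_call_rate``;
    3. drop SNPs with minor allele frequency below ``maf_min``
       (frequencies recomputed on the surviving data).
    Remaining missing entries stay NaN and are mean-imputed (2p) when a
    relationship matrix is built.
    """
    X = genotypes.counts
    n, m = X.shape
    called = ~np.isnan(X)
    keep_snp = called.mean(axis=0) >= snp_call_rate
    n_snp_cr = int((~keep_snp).sum())
    X1 = X[:, keep_snp]
    called1 = called[:, keep_snp]
    keep_ind = (
        called1.mean(axis=1) >= ind_call_rate
        if X1.shape[1]
        else np.ones(n, dtype=bool)
    )
    n_ind_cr = int((~keep_ind).sum())
    X2 = X1[keep_ind]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(X2, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep_maf = maf >= maf_min
    n_maf = int((~keep_maf).sum())
    X3 = X2[:, keep_maf]
    if X3.size == 0:
        raise ValueError("QC removed all SNPs or individuals")
    ids = [a for a, k in zip(genotypes.ids, keep_ind) if k]
    smap = genotypes.snp_map[keep_snp].reset_index(drop=True)[keep_maf].reset_index(
        drop=True
    )
    freqs = None
    if genotypes.allele_freqs is not None:
        freqs = np.asarray(genotypes.allele_freqs)[keep_snp][keep_maf]
    report = {
        "snps_in": m,
        "individuals_in": n,
        "removed_snp_call_rate": n_snp_cr,
        "removed_individual_call_rate": n_ind_cr,
        "removed_maf": n_maf,
        "snps_out": X3.shape[1],
        "individuals_out": X3.shape[0],
    }
    return GenotypeSet(X3, ids, smap, allele_freqs=freqs), report
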