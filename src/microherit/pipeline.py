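"""End-to-end pipeline: simulate -> QC -> CLR -> h2 -> permutation
threshold -> enrichment -> rg -> GWAS -> QTL regions.

Every stage is a thin orchestration over the library modules; all
randomness derives from the config seed, so a rerun with the same
config reproduces every numeric output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .animal_model import AnimalModel, build_model_frame
from .compositional import (
    clr,
    core_microbiome,
    filter_low_abundance,
    impute_zeros,
    standardise_columns,
)
from .gwas import SingleStepGwas, make_single_step
from .relationship import build_A
from .reml import MultiTraitREML
from .significance import empirical_threshold, genus_enrichment, permute_and_refit
from .simulate import DAIRY_TRAITS, SimulationConfig, simulate_dataset

__all__ = [
    "PipelineConfig",
    "RunLog",
    "run_pipeline",
    "rg_pair_table",
    "default_fixed_effects",
    "OTU_FIXED_EFFECTS",
]

# Environmental-effect structure of the animal models: which factors and
# covariates enter each trait's design (year-nested factors written with
# ':'), mirroring the effect-inclusion pattern of the study design the
# simulator emulates (see simulate.applied_factors).
OTU_FIXED_EFFECTS: tuple[list[str], list[str]] = (
    ["year", "year:lactation", "year:run", "total_seq_class", "year:time_order"],
    [],
)
_NESTED = {"lactation": "year:lactation", "run": "year:run",
           "time_order": "year:time_order"}


def default_fixed_effects(name: str) -> tuple[list[str], list[str]]:
    """(factors, covariates) for one trait or OTU column.

    Lactation, sequencing run and sampling order are modelled nested
    within year; the nested coding spans the additive effects the
    generator plants, so the frames remain correctly specified.
    """
    if name.startswith("OTU"):
        return OTU_FIXED_EFFECTS
    from .simulate import applied_factors

    factors, use_dim = applied_factors(name, is_otu=False)
    factors = [_NESTED.get(f, f) for f in factors]
    return factors, (["dim"] if use_dim else [])


def rg_pair_table(otu_ids, dairy_traits) -> pd.DataFrame:
    """One planned genetic-correlation row per (OTU, dairy trait) pair."""
    rows = [
        {"otu_id": str(o), "trait": str(t), "rg": np.nan, "se_rg": np.nan,
         "significant": False, "fitted": False}
        for o in otu_ids
        for t in dairy_traits
    ]
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    # genotype QC
    snp_call_rate: float = 0.90
    ind_call_rate: float = 0.95
    maf_min: float = 0.05
    # compositional
    abundance_threshold: float = 5e-5
    core_occurrence: float = 0.90
    # variance components
    em_rounds: int = 30
    reml_tol: float = 1e-8
    reml_max_iter: int = 60
    h2_max_otus: int | None = None
    # permutation threshold
    n_perm: int = 200
    error_rate: float = 0.05
    n_representative_otus: int = 2
    # genetic correlations
    rg_traits: list[str] = field(default_factory=lambda: list(DAIRY_TRAITS))
    rg_max_pairs: int | None = None
    # GWAS
    gwas_targets: list[str] = field(default_factory=list)
    blend_alpha: float = 0.05
    fdr_significant: float = 0.10
    fdr_suggestive: float = 0.30
    distance_limit: float = 1_000_000
    window: int = 20

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


class RunLog:
    """Timestamped stage records with record counts in/out."""

    def __init__(self):
        self.entries: list[str] = []

    def log(self, stage: str, message: str) -> None:
        stamp = time.strftime("%Y-%m-%d %H:%M:%S")
        self.entries.append(f"[{stamp}] {stage}: {message}")

    def write(self, path) -> None:
        Path(path).write_text("\n".join(self.entries) + "\n")


def _write_table(df: pd.DataFrame, path: Path, stage: str, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


_STAGES = [
    "simulate", "qc", "transform", "h2", "permtest", "enrich", "rg", "gwas",
]


def run_pipeline(
    config: PipelineConfig, outdir, stages: list[str] | None = None
) -> dict:
    """Run the pipeline up to (and including) the requested stages.

    Returns a dict of in-memory artefacts; tables and a run log are
    written under ``outdir``.  Stages are always executed in pipeline
    order, and later stages pull in their prerequisites.
    """
    wanted = set(stages or _STAGES)
    unknown = wanted - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    last = max(_STAGES.index(s) for s in wanted)
    todo = _STAGES[: last + 1]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    cfg_hash = config.hash()
    log.log("config", f"hash={cfg_hash}")
    art: dict = {"config": config}

    # -- simulate ------------------------------------------------------
    sim_cfg = SimulationConfig(seed=config.seed, **config.simulation)
    dataset = simulate_dataset(sim_cfg)
    art["dataset"] = dataset
    mio.write_dataset(dataset, outdir / "data")
    log.log(
        "simulate",
        f"{len(dataset.pedigree)} animals, {dataset.genotypes.n_snps} SNPs, "
        f"{dataset.otu_counts.n_otus} OTU, {len(dataset.phenotypes)} phenotyped",
    )
    A = build_A(dataset.pedigree)
    art["A"] = A
    if todo[-1] == "simulate":
        log.write(outdir / "run.log")
        return art

    # -- qc ------------------------------------------------------------
    genotypes, qc_report = mio.qc_genotypes(
        dataset.genotypes, config.snp_call_rate, config.ind_call_rate, config.maf_min
    )
    art["genotypes"] = genotypes
    art["qc_report"] = qc_report
    log.log("qc", json.dumps(qc_report))
    if todo[-1] == "qc":
        log.write(outdir / "run.log")
        return art

    # -- transform -----------------------------------------------------
    table = filter_low_abundance(dataset.otu_counts, config.abundance_threshold)
    log.log(
        "transform",
        f"abundance filter {config.abundance_threshold}: "
        f"{dataset.otu_counts.n_otus} -> {table.n_otus} OTU",
    )
    comp = impute_zeros(table)
    clrm = standardise_columns(
        clr(comp, sample_ids=table.sample_ids, otu_ids=table.otu_ids)
    )
    core = sorted(core_microbiome(table, config.core_occurrence))
    art["otu_table"] = table
    art["clr"] = clrm
    art["core"] = core
    _write_table(
        clrm.to_dataframe().reset_index(names="sample_id"),
        outdir / "otu_clr.tsv", "transform", cfg_hash,
    )
    _write_table(pd.DataFrame({"otu_id": core}), outdir / "core_microbiome.tsv",
                 "transform", cfg_hash)
    log.log("transform", f"core microbiome: {len(core)} OTU "
            f"({100 * len(core) / table.n_otus:.1f}%)")
    if todo[-1] == "transform":
        log.write(outdir / "run.log")
        return art

    # -- h2 ------------------------------------------------------------
    phen = dataset.phenotypes.copy()
    clr_df = clrm.to_dataframe()
    otu_ids = list(clr_df.columns)
    if config.h2_max_otus is not None:
        otu_ids = otu_ids[: config.h2_max_otus]
    fe = {t: default_fixed_effects(t)[0] for t in ("lscs", "cv_milk")}
    cov = {t: default_fixed_effects(t)[1] for t in ("lscs", "cv_milk")}

    def three_trait_frame(name: str, values: np.ndarray | None = None):
        df = phen.copy()
        if values is not None:
            df[name] = values
        f = dict(fe)
        c = dict(cov)
        f[name], c[name] = default_fixed_effects(name)
        return build_model_frame(
            df, ["lscs", "cv_milk", name], f, c, dataset.pedigree
        )

    animals = phen["animal"].astype(str).tolist()
    h2_rows = []
    frame0 = three_trait_frame(otu_ids[0], clr_df.loc[animals, otu_ids[0]].to_numpy())
    base_model = AnimalModel(frame0, A)
    engine = base_model.engine
    P0, R0 = base_model.default_start()
    for oid in otu_ids:
        engine.set_trait(2, clr_df.loc[animals, oid].to_numpy())
        vc = engine.fit(P0, R0, em_rounds=config.em_rounds, tol=config.reml_tol,
                        max_iter=config.reml_max_iter)
        tot = vc.P[2, 2] + vc.R[2, 2]
        h2_rows.append({
            "otu_id": oid,
            "h2": vc.P[2, 2] / tot if tot > 0 else np.nan,
            "sigma_g2": vc.P[2, 2],
            "sigma_e2": vc.R[2, 2],
            "converged": vc.converged,
        })
    h2_otu = pd.DataFrame(h2_rows)
    trait_rows = []
    for t in config.rg_traits:
        res = AnimalModel(three_trait_frame(t), A).fit(
            em_rounds=config.em_rounds, tol=config.reml_tol,
            max_iter=config.reml_max_iter,
        )
        h2, se = res.heritability(2)
        trait_rows.append({"trait": t, "h2": h2, "se_h2": se,
                           "converged": res.converged})
    h2_traits = pd.DataFrame(trait_rows)
    art["h2_otu"] = h2_otu
    art["h2_traits"] = h2_traits
    _write_table(h2_otu, outdir / "h2_otu.tsv", "h2", cfg_hash)
    _write_table(h2_traits, outdir / "h2_traits.tsv", "h2", cfg_hash)
    log.log("h2", f"{len(h2_otu)} OTU and {len(h2_traits)} dairy traits fitted")
    if todo[-1] == "h2":
        log.write(outdir / "run.log")
        return art

    # -- permutation threshold ----------------------------------------
    zeros = (table.counts == 0).mean(axis=0)
    in_scope = [i for i, o in enumerate(table.otu_ids) if o in set(otu_ids)]
    by_zero = sorted(in_scope, key=lambda i: zeros[i])
    picks = [by_zero[0], by_zero[-1]][: config.n_representative_otus]
    thresholds = []
    all_h2 = []
    per_rep = max(20, config.n_perm // max(1, len(picks)))
    for j, i_otu in enumerate(picks):
        oid = table.otu_ids[i_otu]
        values = clr_df.loc[animals, oid].to_numpy()
        res = permute_and_refit(
            values, frame0, A, per_rep, seed=config.seed + 1000 + j,
            error_rate=config.error_rate, em_rounds=min(config.em_rounds, 20),
            tol=config.reml_tol, max_iter=config.reml_max_iter,
        )
        thresholds.append(res.threshold)
        all_h2.append(res.h2_estimates)
    threshold = empirical_threshold(np.concatenate(all_h2), config.error_rate)
    art["perm_threshold"] = threshold
    _write_table(
        pd.DataFrame({"otu_id": [table.otu_ids[i] for i in picks],
                      "threshold": thresholds,
                      "combined_threshold": threshold}),
        outdir / "perm_threshold.tsv", "permtest", cfg_hash,
    )
    log.log("permtest", f"empirical h2 threshold = {threshold:.4f} "
            f"({config.n_perm} permutations over {len(picks)} OTU)")
    if todo[-1] == "permtest":
        log.write(outdir / "run.log")
        return art

    # -- enrichment ----------------------------------------------------
    heritable = h2_otu.loc[h2_otu["h2"] > threshold, "otu_id"].tolist()
    art["heritable_otus"] = heritable
    if table.taxonomy is not None and heritable:
        enrich = genus_enrichment(table.taxonomy, heritable, h2_otu["otu_id"])
        art["enrichment"] = enrich
        _write_table(enrich, outdir / "genus_enrichment.tsv", "enrich", cfg_hash)
        log.log("enrich", f"{len(heritable)} heritable OTU; "
                f"{int(enrich['significant'].sum())} genera at P<0.05")
    else:
        log.log("enrich", "skipped (no taxonomy or no heritable OTU)")
    if todo[-1] == "enrich":
        log.write(outdir / "run.log")
        return art

    # -- rg ------------------------------------------------------------
    pairs = rg_pair_table(heritable, config.rg_traits)
    n_fit = len(pairs) if config.rg_max_pairs is None else min(
        len(pairs), config.rg_max_pairs
    )
    for irow in range(n_fit):
        oid, trait = pairs.loc[irow, "otu_id"], pairs.loc[irow, "trait"]
        df = phen.copy()
        df[oid] = clr_df.loc[animals, oid].to_numpy()
        f = dict(fe)
        c = dict(cov)
        f[oid], c[oid] = default_fixed_effects(oid)
        f[trait], c[trait] = default_fixed_effects(trait)
        frame = build_model_frame(
            df, ["lscs", "cv_milk", oid, trait], f, c, dataset.pedigree
        )
        res = AnimalModel(frame, A).fit(
            em_rounds=config.em_rounds, tol=config.reml_tol,
            max_iter=config.reml_max_iter,
        )
        try:
            rg, se, sig = res.genetic_correlation(2, 3)
        except ValueError:
            rg, se, sig = np.nan, np.nan, False
        pairs.loc[irow, ["rg", "se_rg", "significant", "fitted"]] = (
            rg, se, sig, True
        )
    art["rg_table"] = pairs
    _write_table(pairs, outdir / "genetic_correlations.tsv", "rg", cfg_hash)
    log.log("rg", f"{len(pairs)} OTU x trait pairs emitted, {n_fit} fitted")
    if todo[-1] == "rg":
        log.write(outdir / "run.log")
        return art

    # -- gwas ----------------------------------------------------------
    targets = config.gwas_targets or (
        [config.rg_traits[0]] + heritable[:1]
    )
    ssm = make_single_step(A, genotypes, alpha=config.blend_alpha)
    gwas_tables = {}
    regions_rows = []
    for target in targets:
        df = phen.copy()
        if target.startswith("OTU"):
            if target not in clr_df.columns:
                log.log("gwas", f"{target}: not in CLR table, skipped")
                continue
            df[target] = clr_df.loc[animals, target].to_numpy()
        f_t, c_t = default_fixed_effects(target)
        frame = build_model_frame(df, [target], {target: f_t}, {target: c_t},
                                  dataset.pedigree)
        # per-trait variance components re-estimated under the
        # single-trait model with the joint relationship
        H_phi = ssm.H.submatrix(frame.animal_ids)
        eng = MultiTraitREML(frame.Y, frame.Xs, A=H_phi)
        vc = eng.fit(*AnimalModel(frame, H_phi).default_start(),
                     em_rounds=config.em_rounds, tol=config.reml_tol,
                     max_iter=config.reml_max_iter)
        model = SingleStepGwas(frame, ssm, vc.P[0, 0], vc.R[0, 0])
        res = model.fit(config.fdr_significant, config.fdr_suggestive)
        gwas_tables[target] = res
        _write_table(res.table, outdir / f"gwas_{target}.tsv", "gwas", cfg_hash)
        for reg in res.qtl_regions(config.distance_limit):
            regions_rows.append({
                "target": target, "lead_snp": reg.lead_snp,
                "chromosome": reg.chromosome, "start": reg.start,
                "end": reg.end, "n_snps": len(reg.members),
                "lead_mlogp": reg.lead_mlogp, "var_pct": reg.variance_pct,
            })
        log.log("gwas", f"{target}: {int(res.table['significant'].sum())} "
                "significant SNPs")
    regions = pd.DataFrame(regions_rows)
    art["gwas"] = gwas_tables
    art["qtl_regions"] = regions
    if not regions.empty:
        _write_table(regions, outdir / "qtl_regions.tsv", "gwas", cfg_hash)
    log.write(outdir / "run.log")
    return art
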