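"""Synthetic hologenome generator.

Emulates the data structure of a dairy-sheep rumen-microbiome study at
desk scale: a multi-generation pedigree of ewes (~800 phenotyped over
five founder generations by default), SNP genotypes produced by
Mendelian gene dropping, latent dairy traits and OTU log-abundances
with configurable heritabilities, genetic correlations and planted SNP
QTL, and an OTU count table rendered by multinomial sampling with a
calibrated zero fraction (default 37.5%).

Breeding values are generated by Mendelian descent alongside the
pedigree (founder BV ~ N(0, P); offspring BV = parent average plus a
Mendelian-sampling deviation scaled by parental inbreeding), which
yields exactly N(0, A (x) P) under random mating and remains coherent
when truncation selection on the first trait is switched on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compositional import OtuTable, TAXONOMY_RANKS
from .relationship import GenotypeSet, Pedigree

__all__ = [
    "TraitSpec",
    "Qtl",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_latent_traits",
    "render_otu_counts",
    "simulate_dataset",
    "DEFAULT_TRAIT_SPECS",
    "DAIRY_TRAITS",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TraitSpec:
    name: str
    h2: float
    mean: float
    variance: float


@dataclass(frozen=True)
class Qtl:
    """A planted QTL: a genotyped SNP given a fixed additive effect.

    The effect size is chosen so the locus explains ``variance_fraction``
    of the target latent variable's additive genetic variance; the
    polygenic variance is reduced accordingly so the total genetic
    variance matches the configured h2.
    """

    target: str
    variance_fraction: float
    snp_index: int | None = None
    chromosome: int | None = None
    position: int | None = None


# Descriptive statistics and heritabilities of the dairy traits of a
# Lacaune ewe population (daily-basis milk traits in g/100 mL, milk
# yield in mL; the two selection-criterion traits on a lactation basis).
DEFAULT_TRAIT_SPECS: list[TraitSpec] = [
    TraitSpec("lscs", 0.37, 3.29, 1.50**2),
    TraitSpec("cv_milk", 0.22, 53.93, 12.18**2),
    TraitSpec("milk_yield", 0.28, 1946.0, 589.0**2),
    TraitSpec("fat_content", 0.59, 7.37, 1.14**2),
    TraitSpec("protein_content", 0.57, 5.71, 0.52**2),
    TraitSpec("alpha_s1_casein", 0.54, 1.38, 0.15**2),
    TraitSpec("alpha_s2_casein", 0.68, 0.66, 0.26**2),
    TraitSpec("beta_casein", 0.41, 2.10, 0.23**2),
    TraitSpec("kappa_casein", 0.50, 0.45, 0.04**2),
    TraitSpec("alpha_lactalbumin", 0.36, 0.13, 0.01**2),
    TraitSpec("beta_lactoglobulin", 0.44, 0.46, 0.50**2),
    TraitSpec("c4_0", 0.50, 0.25, 0.03**2),
    TraitSpec("c6_0", 0.53, 0.21, 0.03**2),
    TraitSpec("c8_0", 0.55, 0.20, 0.03**2),
    TraitSpec("c10_0", 0.58, 0.73, 0.12**2),
    TraitSpec("c12_0", 0.60, 0.49, 0.08**2),
    TraitSpec("c16_0", 0.54, 1.96, 0.37**2),
    TraitSpec("c18_1", 0.44, 0.80, 0.31**2),
    TraitSpec("c18_2", 0.45, 0.04, 0.02**2),
    TraitSpec("c18_3", 0.38, 0.04, 0.01**2),
]

DAIRY_TRAITS: list[str] = [t.name for t in DEFAULT_TRAIT_SPECS[2:]]

DEFAULT_FIXED_LEVELS: dict[str, int] = {
    "year": 5,
    "lactation": 3,
    "litter_size": 2,
    "run": 6,
    "time_order": 8,
    "total_seq_class": 5,
    "test_day": 4,
}

# which simulated environmental factors act on which latent variable
# (per-trait inclusion pattern of the emulated study design; the
# analysis-side default frames mirror this map)
_LACTATION_BASIS = {"lscs", "cv_milk"}
_PROTEIN_LIKE = {
    "protein_content", "alpha_s1_casein", "alpha_s2_casein", "beta_casein",
    "kappa_casein", "alpha_lactalbumin", "beta_lactoglobulin",
}


def applied_factors(name: str, is_otu: bool) -> tuple[list[str], bool]:
    """(environmental factors, whether the DIM covariate acts) for one
    latent variable."""
    if is_otu or name.startswith("OTU"):
        return ["year", "lactation", "run", "total_seq_class", "time_order"], False
    if name == "lscs":
        return ["litter_size", "test_day"], False
    if name == "cv_milk":
        return ["year", "litter_size", "test_day"], False
    if name == "milk_yield":
        return ["year"], True
    if name == "fat_content":
        return ["year", "lactation"], True
    if name in _PROTEIN_LIKE:
        return ["year", "litter_size"], True
    # milk fatty acids and any other daily-basis trait
    return ["year", "lactation", "litter_size"], True


@dataclass
class SimulationConfig:
    seed: int = 0
    n_founders: int = 400
    n_generations: int = 5  # total generations, founders included
    n_offspring_per_mating: int = 2
    n_snps: int = 10_000
    n_chromosomes: int = 26
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_otus: int = 2_000
    target_zero_fraction: float = 0.375
    depth_range: tuple[int, int] = (5_000, 25_000)
    otu_h2_range: tuple[float, float] = (0.0, 0.3)
    otu_h2: np.ndarray | None = None
    otu_log_mean_sd: float = 0.8
    otu_latent_variance: float = 1.0
    trait_specs: list[TraitSpec] = field(default_factory=lambda: list(DEFAULT_TRAIT_SPECS))
    genetic_correlations: list[tuple[str, str, float]] = field(default_factory=list)
    qtl_list: list[Qtl] = field(default_factory=list)
    fixed_effect_levels: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_LEVELS)
    )
    fixed_effect_sd: float = 0.25  # effect SD per level, in trait-SD units
    dim_range: tuple[int, int] = (28, 133)
    dim_slope_sd: float = 0.1  # DIM slope SD in trait-SD units per 100 days
    sparsity_mask_fraction: float = 0.6
    divergent_selection: bool = False
    selection_fraction: float = 0.5
    n_genera: int = 40

    def __post_init__(self):
        if self.n_founders < 2 or self.n_generations < 1:
            raise ConfigError("need n_founders >= 2 and n_generations >= 1")
        if self.n_offspring_per_mating < 1:
            raise ConfigError("n_offspring_per_mating must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.target_zero_fraction < 1.0:
            raise ConfigError("target_zero_fraction must be in [0, 1)")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ConfigError("depth_range must be positive and ordered")
        lo, hi = self.otu_h2_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ConfigError("otu_h2_range must lie within [0, 1)")
        for q in self.qtl_list:
            if not 0.0 <= q.variance_fraction <= 1.0:
                raise ConfigError("QTL variance fractions must be in [0, 1]")
        for _, _, r in self.genetic_correlations:
            if not -1.0 <= r <= 1.0:
                raise ConfigError("genetic correlations must be in [-1, 1]")

    def streams(self) -> dict[str, np.random.Generator]:
        names = ["pedigree", "bv", "genotypes", "fixed", "noise", "otu", "taxonomy"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}

    def latent_names(self) -> list[str]:
        otus = [f"OTU{i + 1:04d}" for i in range(self.n_otus)]
        return [t.name for t in self.trait_specs] + otus


@dataclass
class SimulatedDataset:
    pedigree: Pedigree
    genotypes: GenotypeSet
    otu_counts: OtuTable
    phenotypes: pd.DataFrame
    truth: dict

    def __post_init__(self):
        ped_ids = set(self.pedigree.ids)
        orphans = set(self.phenotypes["animal"].astype(str)) - ped_ids
        if orphans:
            raise ValueError(f"phenotyped samples not in pedigree: {sorted(orphans)[:5]}")


# ---------------------------------------------------------------------------
# latent genetic architecture
# ---------------------------------------------------------------------------


class _LatentArchitecture:
    """Genetic variances, correlated-block Cholesky, QTL assignments."""

    def __init__(self, config: SimulationConfig, rng_bv: np.random.Generator):
        self.names = config.latent_names()
        self.index = {n: i for i, n in enumerate(self.names)}
        n_lat = len(self.names)
        h2 = np.empty(n_lat)
        var = np.empty(n_lat)
        mean = np.empty(n_lat)
        for i, spec in enumerate(config.trait_specs):
            h2[i], var[i], mean[i] = spec.h2, spec.variance, spec.mean
        n_tr = len(config.trait_specs)
        if config.otu_h2 is not None:
            oh2 = np.asarray(config.otu_h2, float)
            if oh2.shape != (config.n_otus,):
                raise ConfigError("otu_h2 must have length n_otus")
        else:
            oh2 = rng_bv.uniform(*config.otu_h2_range, size=config.n_otus)
        h2[n_tr:] = oh2
        var[n_tr:] = config.otu_latent_variance
        mean[n_tr:] = rng_bv.normal(0.0, config.otu_log_mean_sd, size=config.n_otus)
        self.h2, self.var, self.mean = h2, var, mean
        self.sigma_g2_total = h2 * var

        # QTL take a fraction of the genetic variance away from the
        # polygenic term
        self.qtl_fraction = np.zeros(n_lat)
        for q in config.qtl_list:
            if q.target not in self.index:
                raise ConfigError(f"QTL target '{q.target}' is not a latent variable")
            self.qtl_fraction[self.index[q.target]] += q.variance_fraction
        if np.any(self.qtl_fraction > 1.0):
            raise ConfigError("QTL variance fractions exceed 1 for some target")
        self.sigma_g2_poly = self.sigma_g2_total * (1.0 - self.qtl_fraction)
        self.sigma_e2 = var * (1.0 - h2)

        # correlated polygenic block
        corr_ids = sorted(
            {a for a, _, _ in config.genetic_correlations}
            | {b for _, b, _ in config.genetic_correlations}
        )
        for name in corr_ids:
            if name not in self.index:
                raise ConfigError(f"correlated latent '{name}' unknown")
        self.block = np.array([self.index[n] for n in corr_ids], dtype=int)
        if len(self.block):
            k = len(self.block)
            C = np.eye(k)
            pos = {self.index[n]: i for i, n in enumerate(corr_ids)}
            for a, b, r in config.genetic_correlations:
                ia, ib = pos[self.index[a]], pos[self.index[b]]
                C[ia, ib] = C[ib, ia] = r
            sd = np.sqrt(self.sigma_g2_poly[self.block])
            cov = C * np.outer(sd, sd)
            w = np.linalg.eigvalsh(C)
            if w[0] < -1e-10:
                raise ConfigError(
                    "requested genetic correlation matrix is not positive "
                    f"semi-definite (min eigenvalue {w[0]:.3e})"
                )
            wC = np.linalg.eigvalsh(cov)
            if wC[0] < 0:
                cov += np.eye(k) * (1e-12 - wC[0])
            self.block_chol = np.linalg.cholesky(cov)
        else:
            self.block_chol = None
        self.indep_sd = np.sqrt(self.sigma_g2_poly)
        if len(self.block):
            self.indep_sd[self.block] = 0.0

    def sample_bv_deviation(
        self, rng: np.random.Generator, scale: float, size: int = 1
    ) -> np.ndarray:
        """Draw ``size`` latent BV deviations ~ N(0, scale * P_poly)."""
        n_lat = len(self.names)
        eps = rng.standard_normal((size, n_lat))
        out = eps * self.indep_sd[None, :]
        if self.block_chol is not None:
            out[:, self.block] = eps[:, self.block] @ self.block_chol.T
        return math.sqrt(scale) * out


# ---------------------------------------------------------------------------
# pedigree + breeding values
# ---------------------------------------------------------------------------


def _generate_population(config: SimulationConfig):
    """Pedigree, sexes, generations, inbreeding, and latent BVs.

    Returns (records list, sex array, generation array, bv matrix,
    architecture).  Mating is random non-selfing within generation;
    with ``divergent_selection`` parents are the top
    ``selection_fraction`` of their sex on the first trait's phenotype.
    """
    streams = config.streams()
    rng_ped, rng_bv = streams["pedigree"], streams["bv"]
    arch = _LatentArchitecture(config, rng_bv)
    sel_e_sd = math.sqrt(max(arch.sigma_e2[0], 0.0))

    records: list[tuple[str, str, str]] = []
    sex: list[int] = []  # 0 = female, 1 = male
    gen: list[int] = []
    bv_rows: list[np.ndarray] = []
    sel_pheno: list[float] = []
    F: list[float] = []
    # relationships are tracked with a preallocated dense tabular A so
    # inbreeding (hence Mendelian-sampling variance) is exact
    per_gen = max(1, config.n_founders // config.n_offspring_per_mating) * (
        config.n_offspring_per_mating
    )
    n_total = config.n_founders + (config.n_generations - 1) * per_gen
    A = np.zeros((n_total, n_total))
    n_lat = len(arch.names)

    def add(aid, sire_i, dam_i, generation, sx):
        i = len(records)
        if i >= A.shape[0]:
            raise ConfigError("population grew beyond the preallocated bound")
        if sire_i is not None and dam_i is not None:
            A[i, :i] = 0.5 * (A[sire_i, :i] + A[dam_i, :i])
            f = 0.5 * A[sire_i, dam_i]
            msv = 0.5 - 0.25 * (F[sire_i] + F[dam_i])
            pm = 0.5 * (bv_rows[sire_i] + bv_rows[dam_i])
        elif sire_i is not None or dam_i is not None:
            p = sire_i if sire_i is not None else dam_i
            A[i, :i] = 0.5 * A[p, :i]
            f, msv, pm = 0.0, 0.75 - 0.25 * F[p], 0.5 * bv_rows[p]
        else:
            f, msv, pm = 0.0, 1.0, np.zeros(n_lat)
        A[i, i] = 1.0 + f
        A[:i, i] = A[i, :i]
        records.append(
            (
                aid,
                records[sire_i][0] if sire_i is not None else "0",
                records[dam_i][0] if dam_i is not None else "0",
            )
        )
        sex.append(sx)
        gen.append(generation)
        F.append(f)
        bv_rows.append(pm + arch.sample_bv_deviation(rng_bv, msv)[0])
        sel_pheno.append(bv_rows[-1][0] + rng_bv.normal(0.0, sel_e_sd))
        return i

    width = len(str(config.n_founders * (config.n_generations + 1))) + 1
    counter = 0

    def next_id():
        nonlocal counter
        counter += 1
        return f"A{counter:0{width}d}"

    current = []
    for k in range(config.n_founders):
        current.append(add(next_id(), None, None, 0, k % 2))

    per_gen = config.n_founders
    for g in range(1, config.n_generations):
        females = [i for i in current if sex[i] == 0]
        males = [i for i in current if sex[i] == 1]
        if not females or not males:
            raise ConfigError("a generation lacks one sex; increase n_founders")
        if config.divergent_selection:
            k_f = max(1, int(round(config.selection_fraction * len(females))))
            k_m = max(1, int(round(config.selection_fraction * len(males))))
            females = sorted(females, key=lambda i: -sel_pheno[i])[:k_f]
            males = sorted(males, key=lambda i: -sel_pheno[i])[:k_m]
        n_matings = max(1, per_gen // config.n_offspring_per_mating)
        dams = rng_ped.choice(females, size=n_matings, replace=len(females) < n_matings)
        sires = rng_ped.choice(males, size=n_matings)
        nxt = []
        for dam_i, sire_i in zip(dams, sires):
            for _ in range(config.n_offspring_per_mating):
                sx = int(rng_ped.random() < 0.5)
                nxt.append(add(next_id(), int(sire_i), int(dam_i), g, sx))
        current = nxt

    df = pd.DataFrame(records, columns=["animal", "sire", "dam"])
    ped = Pedigree(df)
    n = len(records)
    ped.generation = np.array(gen)  # type: ignore[attr-defined]
    ped.sex = np.array(sex)  # type: ignore[attr-defined]
    ped._bv = np.array(bv_rows)  # type: ignore[attr-defined]
    ped._arch = arch  # type: ignore[attr-defined]
    ped._A = A[:n, :n].copy()  # type: ignore[attr-defined]
    return ped, arch


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Random-mating (optionally divergently selected) pedigree.

    Founders form generation 0 and ``n_generations`` counts all
    generations including them (``n_generations=1`` is founders only).
    Each later generation has roughly ``n_founders`` animals produced
    by random dam-sire pairings with ``n_offspring_per_mating``
    offspring each; with the defaults (400 founders, 5 generations)
    the sampled cohort of non-founder females is ~800 ewes.
    """
    ped, _ = _generate_population(config)
    return ped


def simulate_genotypes(pedigree: Pedigree, config: SimulationConfig) -> GenotypeSet:
    """Gene-drop SNP genotypes down the pedigree.

    Founder allele counts are Binomial(2, p) with p ~ Uniform(maf_range)
    per SNP; each offspring receives one allele per parent, drawn
    Bernoulli(parent count / 2) independently per SNP (unlinked
    transmission).  True founder frequencies are stored on the
    resulting GenotypeSet.
    """
    rng = config.streams()["genotypes"]
    m = config.n_snps
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    sidx, didx = pedigree.parent_indices()
    n = len(pedigree)
    counts = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        s, d = sidx[i], didx[i]
        if s < 0 and d < 0:
            counts[i] = rng.binomial(2, p)
        else:
            pat = (
                rng.random(m) < counts[s] / 2.0
                if s >= 0
                else rng.random(m) < p
            )
            mat = (
                rng.random(m) < counts[d] / 2.0
                if d >= 0
                else rng.random(m) < p
            )
            counts[i] = pat.astype(np.int8) + mat.astype(np.int8)
    # SNP map: contiguous chromosome blocks, ascending positions
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    chroms = np.repeat(np.arange(1, config.n_chromosomes + 1), per_chrom)
    positions = np.empty(m, dtype=np.int64)
    start = 0
    for c, k in enumerate(per_chrom):
        pos = np.sort(rng.integers(1, 100_000_001, size=k))
        # nudge the (rare) duplicate draws apart so positions are strict
        for _ in range(3):
            dup = np.flatnonzero(np.diff(pos) == 0)
            if dup.size == 0:
                break
            pos[dup + 1] += 1
            pos = np.sort(pos)
        positions[start : start + k] = pos
        start += k
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1:06d}" for i in range(m)],
            "chromosome": chroms,
            "position": positions,
        }
    )
    return GenotypeSet(
        counts.astype(float), pedigree.ids, snp_map, allele_freqs=p
    )


def _resolve_qtl_snp(q: Qtl, genotypes: GenotypeSet) -> int:
    if q.snp_index is not None:
        return int(q.snp_index)
    if q.chromosome is None or q.position is None:
        raise ConfigError("QTL needs snp_index or (chromosome, position)")
    sm = genotypes.snp_map
    on = sm[sm["chromosome"] == q.chromosome]
    if on.empty:
        raise ConfigError(f"no SNPs on chromosome {q.chromosome}")
    j = (on["position"] - q.position).abs().idxmin()
    return int(sm.index.get_loc(j))


def _phenotyped_rows(pedigree: Pedigree) -> np.ndarray:
    """Default sampled cohort: non-founder females (the ewes)."""
    gen = getattr(pedigree, "generation", None)
    sex = getattr(pedigree, "sex", None)
    if gen is None or sex is None:
        return np.arange(len(pedigree))
    rows = np.where((gen > 0) & (sex == 0))[0]
    return rows if rows.size else np.arange(len(pedigree))


def simulate_latent_traits(
    genotypes: GenotypeSet,
    pedigree: Pedigree,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict]:
    """Latent values (traits + OTU log-abundances) for the sampled ewes.

    value = mean + fixed effects + QTL term + polygenic BV + residual.
    The returned truth record carries the breeding values, per-latent
    variance components, fixed-effect assignments and planted QTL.
    """
    arch: _LatentArchitecture = getattr(pedigree, "_arch", None)
    bv = getattr(pedigree, "_bv", None)
    streams = config.streams()
    if arch is None or bv is None:
        arch = _LatentArchitecture(config, streams["bv"])
        A = pedigree.relationship_matrix().values
        L = np.linalg.cholesky(A + 1e-10 * np.eye(len(A)))
        dev = arch.sample_bv_deviation(streams["bv"], 1.0, size=len(A))
        bv = L @ dev
    if bv.shape != (len(pedigree), len(arch.names)):
        raise ValueError("breeding-value matrix does not match pedigree")

    rng_fixed, rng_noise = streams["fixed"], streams["noise"]
    rows = _phenotyped_rows(pedigree)
    n = len(rows)
    n_lat = len(arch.names)
    n_tr = len(config.trait_specs)

    # environment: level assignment per animal, effect sizes per level
    levels = {
        f: rng_fixed.integers(0, k, size=n)
        for f, k in config.fixed_effect_levels.items()
    }
    dim = rng_fixed.integers(config.dim_range[0], config.dim_range[1] + 1, size=n)
    sd_lat = np.sqrt(arch.var)
    factor_effects: dict[str, np.ndarray] = {}
    applies = np.zeros((len(config.fixed_effect_levels), n_lat), dtype=bool)
    fnames = list(config.fixed_effect_levels)
    for fi, f in enumerate(fnames):
        k = config.fixed_effect_levels[f]
        eff = rng_fixed.normal(0.0, config.fixed_effect_sd, size=(k, n_lat)) * sd_lat
        factor_effects[f] = eff
        for li, name in enumerate(arch.names):
            applies[fi, li] = f in applied_factors(name, li >= n_tr)[0]
    dim_slope = rng_fixed.normal(0.0, config.dim_slope_sd, size=n_lat) * sd_lat / 100.0
    dim_applies = np.array(
        [applied_factors(name, li >= n_tr)[1] for li, name in enumerate(arch.names)]
    )

    values = np.tile(arch.mean, (n, 1))
    for fi, f in enumerate(fnames):
        contrib = factor_effects[f][levels[f]]  # (n, n_lat)
        values += np.where(applies[fi][None, :], contrib, 0.0)
    values += np.where(
        dim_applies[None, :], (dim[:, None] - np.mean(config.dim_range)) * dim_slope, 0.0
    )

    qtl_truth = []
    for q in config.qtl_list:
        j = _resolve_qtl_snp(q, genotypes)
        li = arch.index[q.target]
        p = genotypes.frequencies()[j]
        denom = 2.0 * p * (1.0 - p)
        sg2 = arch.sigma_g2_total[li]
        beta = math.sqrt(q.variance_fraction * sg2 / denom) if denom > 0 else 0.0
        z = genotypes.counts[rows, j]
        values[:, li] += beta * (z - 2.0 * p)
        qtl_truth.append(
            {
                "target": q.target,
                "snp_index": j,
                "snp_id": genotypes.snp_map["snp_id"].iloc[j],
                "chromosome": int(genotypes.snp_map["chromosome"].iloc[j]),
                "position": int(genotypes.snp_map["position"].iloc[j]),
                "beta": beta,
                "variance_fraction": q.variance_fraction,
            }
        )

    values += bv[rows]
    resid = rng_noise.standard_normal((n, n_lat)) * np.sqrt(arch.sigma_e2)[None, :]
    values += resid

    ids = [pedigree.ids[i] for i in rows]
    latent = pd.DataFrame(values, index=ids, columns=arch.names)
    env = pd.DataFrame({f: levels[f] for f in fnames}, index=ids)
    env["dim"] = dim
    realized_h2 = {}
    for li, name in enumerate(arch.names):
        vt = values[:, li].var()
        gpart = bv[rows, li]
        for qt in qtl_truth:
            if qt["target"] == name:
                j = qt["snp_index"]
                gpart = gpart + qt["beta"] * genotypes.counts[rows, j]
        realized_h2[name] = float(np.var(gpart) / vt) if vt > 0 else 0.0
    truth = {
        "latent_names": arch.names,
        "h2": {n_: float(h) for n_, h in zip(arch.names, arch.h2)},
        "sigma_g2": {n_: float(v) for n_, v in zip(arch.names, arch.sigma_g2_total)},
        "sigma_e2": {n_: float(v) for n_, v in zip(arch.names, arch.sigma_e2)},
        "realized_h2": realized_h2,
        "qtl": qtl_truth,
        "bv": bv,
        "phenotyped_rows": rows,
        "environment": env,
        "genetic_correlations": list(config.genetic_correlations),
    }
    return latent, truth


def render_otu_counts(
    latent_otu: pd.DataFrame, config: SimulationConfig
) -> OtuTable:
    """Render multinomial OTU counts from latent log-abundances.

    Per sample the composition is softmax(latent); a calibrated
    constant is subtracted from a random subset of latent cells
    (fraction ``sparsity_mask_fraction``) so the expected zero fraction
    of the count table matches ``target_zero_fraction``; counts are
    multinomial at a depth drawn uniformly from ``depth_range``.
    """
    if not np.all(np.isfinite(latent_otu.to_numpy())):
        raise ValueError("latent log-abundances must be finite")
    lo, hi = config.depth_range
    if lo <= 0:
        raise ValueError("depth must be positive")
    rng = config.streams()["otu"]
    L = latent_otu.to_numpy(dtype=float)
    n, D = L.shape
    depths = rng.integers(lo, hi + 1, size=n)
    mask = rng.random((n, D)) < config.sparsity_mask_fraction

    def zero_fraction(offset: float) -> float:
        La = L - offset * mask
        La = La - La.max(axis=1, keepdims=True)
        E = np.exp(La)
        pi = E / E.sum(axis=1, keepdims=True)
        return float(np.mean(np.exp(np.log1p(-np.clip(pi, 0, 1 - 1e-12)) * depths[:, None])))

    # the offset only ever pushes masked cells towards zero, so the
    # calibration works on the non-negative branch where the expected
    # zero fraction is monotone increasing in the offset
    target = config.target_zero_fraction
    lo_c, hi_c = 0.0, 60.0
    f_lo, f_hi = zero_fraction(lo_c), zero_fraction(hi_c)
    if not (f_lo <= target <= f_hi):
        raise ValueError(
            f"target zero fraction {target} unreachable (range [{f_lo:.3f}, {f_hi:.3f}]); "
            "adjust sparsity_mask_fraction or otu_log_mean_sd"
        )
    for _ in range(60):
        mid = 0.5 * (lo_c + hi_c)
        if zero_fraction(mid) < target:
            lo_c = mid
        else:
            hi_c = mid
    offset = 0.5 * (lo_c + hi_c)
    La = L - offset * mask
    La = La - La.max(axis=1, keepdims=True)
    E = np.exp(La)
    pi = E / E.sum(axis=1, keepdims=True)
    counts = np.empty((n, D), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(depths[i], pi[i])
    taxonomy = _synthetic_taxonomy(list(latent_otu.columns), config)
    return OtuTable(counts, list(latent_otu.index.astype(str)), list(latent_otu.columns), taxonomy)


def _synthetic_taxonomy(otu_ids: list[str], config: SimulationConfig) -> pd.DataFrame:
    """Skewed genus assignment (a few dominant genera, a long tail)."""
    rng = config.streams()["taxonomy"]
    k = config.n_genera
    w = 1.0 / np.arange(1, k + 1) ** 1.2
    w /= w.sum()
    genus_idx = rng.choice(k, size=len(otu_ids), p=w)
    n_fam = max(3, k // 3)
    fam_of_genus = rng.integers(0, n_fam, size=k)
    rows = []
    for oid, g in zip(otu_ids, genus_idx):
        genus = f"Genus_{g + 1:03d}" if rng.random() > 0.05 else "unknown"
        rows.append(
            {
                "otu_id": oid,
                "domain": "Bacteria",
                "phylum": f"Phylum_{fam_of_genus[g] % 4 + 1}",
                "class": f"Class_{fam_of_genus[g] % 8 + 1}",
                "order": f"Order_{fam_of_genus[g] % 12 + 1}",
                "family": f"Family_{fam_of_genus[g] + 1:02d}",
                "genus": genus,
                "species": "unknown",
            }
        )
    df = pd.DataFrame(rows).set_index("otu_id")
    return df[TAXONOMY_RANKS]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full synthetic dataset: pedigree, genotypes, OTU counts, phenotypes."""
    ped, _ = _generate_population(config)
    genotypes = simulate_genotypes(ped, config)
    latent, truth = simulate_latent_traits(genotypes, ped, config)
    trait_names = [t.name for t in config.trait_specs]
    otu_names = [c for c in latent.columns if c not in trait_names]
    otu_table = render_otu_counts(latent[otu_names], config)
    env: pd.DataFrame = truth["environment"]
    phen = pd.concat([latent[trait_names], env], axis=1)
    phen.insert(0, "animal", latent.index)
    phen = phen.reset_index(drop=True)
    truth["latent_otu"] = latent[otu_names]
    return SimulatedDataset(
        pedigree=ped,
        genotypes=genotypes,
        otu_counts=otu_table,
        phenotypes=phen,
        truth=truth,
    )
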