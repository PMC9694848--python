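# microherit

Quantitative-genetic analysis of host control over the rumen
microbiota in dairy sheep, at desk scale.

Rumen bacteria ferment feed into the fatty acids and microbial protein
that shape milk composition, and the abundance of individual taxa is
itself partly heritable.  `microherit` implements the full analysis
chain needed to quantify that host-genetic control and its link with
dairy traits from three data sources — a pedigree, SNP genotypes and a
16S OTU count table — together with a synthetic hologenome generator
so that every stage can be exercised and validated without any
external data.

The pipeline:

1. **Compositional preprocessing** — abundance filtering, geometric
   Bayesian-multiplicative zero replacement, centred log-ratio (CLR)
   transform, per-OTU scaling to unit variance, core-microbiome
   detection.
2. **Multi-trait animal model (REML)** — for each OTU or dairy trait
   `y_t = X_t b_t + a_t + e_t` with `a ~ N(0, A ⊗ P)` and
   `e ~ N(0, I ⊗ R)`; EM-REML warm start, average-information (AI)
   refinement, heritabilities `h² = σ²g/(σ²g+σ²e)` and genetic
   correlations `r_g = P_ij/√(P_ii P_jj)` with delta-method SEs.  The
   selection-criterion traits of the population enter as the first
   traits of every frame to absorb selection bias.
3. **Permutation significance** — the empirical null of ĥ² from
   shuffling OTU abundances across ewes; the threshold is the lower
   bound of the upper 5% tail.
4. **Genus enrichment** — two-sided Fisher's exact test per genus on
   (significantly heritable vs not) × (genus vs other).
5. **Single-step GBLUP GWAS** — `y = Xb + Wg + e` with
   `g ~ N(0, H σ²g)`, where H combines the pedigree relationship A
   with the VanRaden genomic matrix `G = ZZ'/2Σp_i q_i` (tuned and
   blended with A₂₂, α = 0.05); SNP effects are back-solved from the
   breeding values, `â = (1−α) b Z'G⁻¹ ĝ₂ / 2Σp_i q_i`, with sampling
   variances from the prediction-error covariance, two-sided normal
   p-values, Benjamini–Hochberg FDR (0.10 genome-wide / 0.30
   suggestive), QTL-region grouping around lead SNPs, LD r², 20-SNP
   window variances, and a fixed-SNP allele-substitution model.

## Worked example

```python
import numpy as np
from microherit import (
    AnimalModel, SimulationConfig, TraitSpec, build_A,
    build_model_frame, simulate_dataset,
)
from microherit.pipeline import default_fixed_effects

cfg = SimulationConfig(
    seed=11, n_founders=120, n_generations=4, n_snps=200, n_otus=30,
    depth_range=(2000, 5000),
    trait_specs=[TraitSpec("lscs", 0.37, 3.29, 2.25),
                 TraitSpec("cv_milk", 0.22, 53.9, 148.0),
                 TraitSpec("fat_content", 0.50, 7.4, 1.3)],
)
ds = simulate_dataset(cfg)          # pedigree, genotypes, OTU counts, phenotypes
A = build_A(ds.pedigree)

traits = ["lscs", "cv_milk", "fat_content"]
fe = {t: default_fixed_effects(t)[0] for t in traits}
cov = {t: default_fixed_effects(t)[1] for t in traits}
frame = build_model_frame(ds.phenotypes, traits, fe, cov, ds.pedigree)
res = AnimalModel(frame, A).fit(em_rounds=100)
print(res.summary())
```

prints (seed 11):

```
Multi-trait animal model (REML)
  n records: 173   traits: 3   converged: True   iterations: 13
  REML log-likelihood: -799.4904

      trait  sigma_g2  sigma_e2     h2  se_h2
       lscs    1.6620    0.9438 0.6378 0.1552
    cv_milk   55.8557  147.9118 0.2741 0.1540
fat_content    0.9236    0.3652 0.7166 0.1565

Genetic correlations (significant if |rg| > 2 SE):
trait_1     trait_2     rg  se_rg  significant
   lscs     cv_milk 0.6869 0.3089         True
   lscs fat_content 0.3844 0.2208        False
cv_milk fat_content 0.1417 0.3133        False
```

Each row is one trait's estimated additive-genetic and residual
variance and the heritability with its standard error.  The traits
were simulated with h² = 0.37, 0.22 and 0.50: at this demo size
(173 ewes) individual estimates scatter within roughly ±2 SE of those
values; the validation studies below run the same machinery at ~2,000
ewes, where a true h² of 0.30 is recovered to within a few
hundredths.  The genetic-correlation block flags `|r_g| > 2·SE` as
significant (here the simulator planted no correlations, and one of
three estimates strays past the loose 2·SE line — the permutation
threshold stage exists precisely because such small-sample estimates
are noisy).

The same dataset flows through the rest of the pipeline with
`microherit.pipeline.run_pipeline` or the CLI:

```bash
microherit run-all --config examples/demo.yaml --out results/demo
```

(stage subcommands `simulate`, `qc`, `transform`, `h2`, `permtest`,
`enrich`, `rg`, `gwas`, `regions` run the pipeline up to that stage).

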