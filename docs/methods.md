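# Methods

This note documents the models implemented in `microherit`, the
assumptions behind them, the synthetic data generator used to validate
them, and the numerical choices a user should know about.

## The statistical setting

The package analyses a population of dairy ewes in which both
quantitative milk traits and the abundances of individual rumen
bacterial taxa (OTU) are treated as phenotypes of the host.  Three
questions drive the design: how heritable is each OTU's abundance,
how strongly is it genetically correlated with milk traits, and which
genomic regions (QTL) underlie either.  The population is assumed to
be under known directional selection on two traits (somatic cell
score and milk-yield persistency); those selection-criterion traits
are carried as the first traits of every variance-component model so
the selection information is represented in the likelihood, which is
the standard remedy for selection bias in animal-model REML.

## Compositional preprocessing

Sequencing fixes each sample's total count, so OTU counts are
compositional: only ratios carry information.  The chain is fixed as
filter → impute → CLR → scale:

* **Abundance filter**: OTU below a fraction of the grand total
  (default 0.005%) are removed.
* **Zero replacement**: geometric Bayesian-multiplicative.  For a
  sample with total n, a zero part j is replaced by
  `s·t_j/(n+s)` where the prior composition t is proportional to the
  geometric mean of each part's observed closed proportions across
  samples (uniform weight for parts never observed) and the Dirichlet
  prior strength is `s = √D` for D parts (exposed as
  `prior_strength`).  Observed parts are adjusted multiplicatively, so
  their pairwise ratios are untouched and rows remain compositions.
* **CLR**: `log x − mean(log x)` per sample; rows sum to zero and the
  transform is invariant to sample-wise rescaling.
* **Scaling**: each OTU column is divided by its sample SD (no
  recentering — the animal model's fixed effects absorb means).

The **core microbiome** is the set of OTU present in at least
`ceil(occurrence · n_samples)` samples (default 90%); the ceiling rule
is stated explicitly because "90% of 10 samples" must mean 9.

## Relationship matrices

* **A** is built by the tabular method with inbreeding
  (`a_ii = 1 + F_i`); populations here are a few thousand animals, so
  the dense recursion is exact and cheap.
* **G** is VanRaden's `ZZ'/2Σp_i q_i` with Z the allele counts centred
  by `2p_i`.  Frequencies default to the observed genotyped set and
  can be overridden (e.g. with base-population frequencies from a
  simulation).  Missing genotypes are mean-imputed at `2p_i`.
* **Blending**: `G* = (1−α)(a + b·G) + α·A₂₂` with `(a, b)` solving
  the 2×2 system that equates mean diagonal and mean off-diagonal of
  the tuned G with those of A₂₂, and α = 0.05; this makes G*
  invertible and on the pedigree scale.
* **H** joins pedigree and genomic information by projecting G onto
  non-genotyped relatives through `A₁₂A₂₂⁻¹`; its genotyped block is
  exactly G*.  H is assembled densely; the classical inverse identity
  `H⁻¹ = A⁻¹ + block(G⁻¹ − A₂₂⁻¹)` serves as an independent check in
  the tests, not as the construction.

## Multi-trait REML

The animal model for T traits with one record per trait per ewe is

    y_t = X_t b_t + a_t + e_t,   a ~ N(0, A ⊗ P),  e ~ N(0, I ⊗ R).

Because each phenotyped animal carries exactly one record per trait,
the REML likelihood for (P, R) depends on A only through its
phenotyped block.  One symmetric eigendecomposition A = U D U' turns
the system into n independent T×T blocks with covariance
`d_m P + R`; every EM and AI quantity then costs O(n·T³) per
iteration.  This is the package's central performance choice: it makes
10,000-permutation nulls and per-OTU scans affordable, and lets one
decomposition be shared across all refits on the same animal set
(the engine's `set_trait` swaps a response without refactorising).
Records missing any trait of a frame are dropped (complete-case); the
modelled subsets are assumed complete.

Fitting is EM warm start (default 100 rounds; the conditional-
expectation updates are monotone in the REML log-likelihood, checked
at every step) followed by AI (Newton-type) iterations with
step-halving.  Convergence is declared when the relative change of
the stacked parameter vector (vech P, vech R) falls below the
tolerance (default 1e-10).  Numerical guards:

* P and R are projected to the PSD cone (eigenvalue floor
  1e-8 × trace) after every AI step.
* AI trajectories can oscillate at boundary optima (singular P, e.g.
  a null OTU under permutation).  After three rejected or halved AI
  steps the fit restarts from the best state seen and finishes with
  monotone EM at a tolerance of max(tol, 1e-7); fits that still fail
  are flagged `converged=False` and reported, never silently used.
* Non-identifiable models (e.g. A = I with one record per animal)
  are detected through the conditioning of the diagonally-rescaled AI
  matrix and flagged unconverged.

Standard errors come from the inverse AI matrix; h² and r_g SEs by the
delta method.  A genetic correlation is called different from zero
when |r_g| > 2·SE.

`solve_mme` provides the dense Henderson mixed-model equations
(returning the full inverse coefficient matrix) for the cases that
need prediction-error covariances — ssGBLUP GWAS — and as an
independent cross-check of the eigendecomposition path.

## Permutation significance and enrichment

The null distribution of ĥ² for an OTU is estimated by shuffling its
abundances across ewes and refitting the three-trait model; the
threshold is the smallest member of the top `error_rate` fraction of
the sorted estimates (rank `n − floor(error_rate·n) + 1`), i.e. "the
lower value of the upper 5%".  The reference analysis estimated this
null from two representative OTU (one zero-rich, one zero-poor) with
10,000 shuffles; the implementation generalises the OTU subset and
permutation count, and the default validation study uses 200
permutations at reduced n so it runs in minutes.

Genus enrichment among significantly heritable OTU uses a two-sided
Fisher's exact test per genus on the 2×2 table
(significant vs not) × (genus vs other), with the conventional
two-sided definition (sum of hypergeometric probabilities of tables no
more probable than observed).

## Single-step GBLUP GWAS

With variance components estimated beforehand (re-estimated per trait
under the single-trait model with H, or supplied), the MME with H⁻¹
yield breeding values ĝ and the prediction-error covariance block
C^{u2u2} of the genotyped animals.  SNP effects and their sampling
variances are

    â       = (1−α) b k Z' G⁻¹ ĝ₂,          k = 1/(2Σp_i q_i)
    Var(â_i) = k²(1−α)²b² z_i' G⁻¹ (G σ²g − C^{u2u2}) G⁻¹ z_i,

with two-sided normal p-values `2(1−Φ(|â_i|/sd(â_i)))` and per-trait
Benjamini–Hochberg FDR at 0.10 (genome-wide) and 0.30 (suggestive).
Negative computed variances (possible with a blended G) are floored at
zero and the SNP flagged untestable, as are SNPs monomorphic after
centring.

**QTL regions**: per chromosome, the most significant remaining SNP
is a lead; significant SNPs within the distance limit whose −log₁₀ p
reaches the upper third of the peak (≥ ⅔ of the lead's value) join its
region; the rest seed further regions; singletons allowed.  The
distance limit defaults to 1 Mbp: the reference text prints
"1000 Mbp", which exceeds any ovine chromosome and is read as a
typographical slip — this is the package's single deliberate deviation
from the printed rule, and the limit is configurable.  The
"upper third of the peak" is interpreted on the −log₁₀ p scale
(configurable), since the printed rule does not define the scale.

**Window variance**: for each SNP, the variance across individuals of
the genomic score `Z_w â_w` of the 20 adjacent SNPs centred on it
(edge-truncated, within chromosome, centred allele counts), divided by
the phenotypic variance.  Region variance uses the union of member
windows.

**Allele substitution**: a significant SNP re-entered as a fixed 0/1/2
covariate with a polygenic background, estimated by GLS with
`V = W A W' σ²g + I σ²e`; the printed model's unit-variance form
(`a ~ N(0, A)`, `e ~ N(0, I)`) is the default special case.

## The synthetic hologenome generator

The generator emulates the structure the models assume, at the scale
of the emulated study: ~800 phenotyped/genotyped ewes from 5
generations (400 founders, random non-selfing mating, constant
generation size), 2,000 OTU with a 37.5% zero fraction, dairy traits
with the means, SDs and heritabilities of the published Lacaune
descriptive table, OTU latent heritabilities uniform on [0, 0.3], and
a medium-density SNP panel (default 10,000 markers on 26 autosomes —
kept below a real chip's 35k–54k so that default desk runs stay light;
the count is configurable).

* **Breeding values** are generated by Mendelian descent during
  pedigree construction: founders draw N(0, P), offspring get the
  parent average plus a deviation with variance
  `(0.5 − 0.25(F_s + F_d))·P`, with inbreeding tracked exactly by an
  incremental tabular A.  Under random mating this yields exactly
  N(0, A ⊗ P); under the optional truncation-selection flag
  (divergent-selection emulation) it remains a coherent generative
  process, which a post-hoc N(0, A ⊗ P) draw would not be.
* **Genotypes** by per-SNP gene dropping (founders Binomial(2, p),
  p ~ U(maf_range); transmission Bernoulli(count/2) per parent).
  Markers are unlinked, so planted QTL are detected through the causal
  SNP itself rather than through LD — real-chip LD structure is
  explicitly out of scope, and GWAS localisation results on synthetic
  data speak to the causal-marker-genotyped case only.
* **Latent values** = trait mean + environmental effects (year,
  lactation, litter size, sequencing run, total-sequence class,
  sampling order, DIM covariate — per-trait inclusion mirroring the
  emulated design; effect sizes N(0, 0.25 SD) per level, drawn once)
  + QTL term (effect sized to the requested fraction of genetic
  variance, polygenic variance reduced to match) + polygenic BV +
  residual.
* **Counts**: per-sample softmax of OTU latents → multinomial at a
  depth ~ U(5,000, 25,000).  Zero inflation subtracts a calibrated
  constant from a random 60% of latent cells; the constant is found by
  bisection on the analytic expected zero fraction (monotone on the
  non-negative branch), hitting the 37.5% target without hurdle
  models.  OTU base log-abundances are N(0, 0.8²), chosen to give a
  realistically skewed abundance distribution while leaving the
  calibration headroom below the target.

What the generator does **not** emulate: linkage disequilibrium,
sequencing error and chimeras, amplicon bias, overdispersion beyond
multinomial sampling, maternal or permanent-environment effects, and
real taxonomic structure (the synthetic taxonomy is a skewed random
genus assignment).  Passing tests therefore demonstrate the
correctness and calibration of the estimators under the stated model,
not robustness to those real-data features.

## Validation studies and problem sizes

`microherit.validation` holds the reproducible studies used by the
test suite and the acceptance script; sizes were chosen so each study
runs in minutes on one CPU while retaining enough information for its
target:

* GBLUP↔SNP-BLUP equivalence: 300 animals × 2,000 SNPs, α=0, a=0,
  b=1, true-frequency centring (observed-frequency centring makes ZZ'
  singular because centred columns sum to zero).
* h² recovery: 20 replicates at ~2,000 phenotyped ewes, true h²=0.30.
* r_g recovery: 20 replicates of the 4-trait frame at ~2,000 ewes,
  true r_g = 0.6 planted between one OTU's latent abundance and a
  milk trait; the OTU enters on its latent scale, which is the scale
  the correlation is defined on (CLR of counts adds multinomial noise
  and closure leakage that attenuate the estimate — a property of the
  measurement, not of the estimator under test).
* Permutation type-I error: 100 null OTU at ~130 ewes, threshold from
  200 shuffles of two representative OTU; the study uses fewer
  environmental levels than the full design so the OTU model's fixed
  effects stay commensurate with n.
* GWAS: 10 replicates at ~800 genotyped ewes × 5,000 SNPs, one QTL at
  10% of genetic variance, h²=0.25.  The null-calibration check uses
  the mean p<0.05 fraction over replicates with its empirical-SD
  t-interval: back-solved z-scores are correlated across SNPs (they
  live in the span of n breeding values), so a pooled binomial CI
  would understate the sampling variance.
* SNP-variance Monte Carlo: 120 animals × 300 SNPs × 2,000 phenotype
  replicates at fixed genotypes, reusing one factorisation.

## Known limitations

* Residual covariances across traits assume records taken on the same
  animal at effectively the same time; records missing one trait are
  dropped rather than modelled.
* The permutation threshold at strongly reduced n is much higher than
  a full-scale study would give (null ĥ² spreads widely when the
  effective degrees of freedom are small); the calibration property —
  5% of null OTU exceed it — is what the studies verify.
* Boundary fits (true h² = 0) are flagged non-converged by the strict
  parameter-change criterion more often than interior fits; their
  estimates remain usable and the counts are always reported.
* Dense linear algebra throughout: intended for up to a few thousand
  animals, not national evaluations.
* GWAS detection power at the emulated scale is modest: with ~800
  genotyped ewes, a QTL explaining 10% of the genetic variance of a
  h² = 0.25 trait (2.5% of phenotypic variance) yields a mean
  back-solved z of ≈ 3.5, so genome-wide FDR-0.10 detection succeeds
  in a minority of replicates — the fixed-SNP GLS ceiling
  z ≈ √(n·2pq·β²/σ²e), further reduced by the family-structured
  effective sample size, limits any method at this n.  Reliable
  localisation of effects this small needs a few thousand animals;
  the validation studies report the measured power rather than
  assuming it.
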