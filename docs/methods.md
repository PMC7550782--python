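# Methods

`ftirblup` models the two-tier phenotyping strategy used in dairy cattle
breeding for difficult-to-measure milk traits: a small reference ("LAB")
cohort of cows with gold-standard wet-lab measurements (milk coagulation
properties, cheese yields, protein fractions) and a large routine
("FIELD") cohort whose test-day milk samples carry FTIR absorbance spectra
but no wet-lab values. Calibration equations trained on the LAB cohort
turn FIELD spectra into predicted phenotypes; treating the measurement and
its spectral prediction as two genetically correlated traits then lets the
FIELD tier contribute to genetic evaluation of the LAB trait.

## Synthetic data

All analyses run on simulated data, because reference datasets of this
kind are proprietary. The generator (`ftirblup.simulate`) produces:

- **Pedigree.** Founders plus discrete generations. A configurable male
  founder fraction (default 0.25) controls how strongly later sires
  cluster into (half-)sib families — dairy bull pedigrees are heavily
  clustered, and the strength of the genomic/pedigree bridge between
  training and validation sires depends on it. Intermediate generations
  keep the population near founder size; the final generation expands into
  the phenotyped cohorts, with every final-generation sire having
  daughters in *both* cohorts (this connection identifies the LAB–FIELD
  genetic correlation). Intermediate-generation females are themselves
  routine-recorded FIELD cows by default — real FIELD tiers span many
  generations, and this is what gives later cows *recorded dams*, a major
  information channel in the evaluation. Default cohort sizes (25 sires,
  4 LAB and 12 FIELD daughters each) mirror the reference design's
  roughly 4 LAB daughters per sire and its much larger FIELD tier, at
  desk scale.
- **Genotypes.** Unlinked biallelic markers; founder allele frequencies
  Uniform(0.05, 0.5); Mendelian gene dropping through the pedigree.
  Genotyped animals: all sires, all LAB cows, and a configurable fraction
  of FIELD cows (default 0.48, preserving the ≈1:1.45 LAB:FIELD ratio of
  genotyped cows of the reference design at the default cohort sizes).
- **Breeding values.** Bivariate infinitesimal model: founders draw
  (LAB, FIELD) breeding-value pairs from N(0, G0) with
  G0 = [[σ²a1, r_a σa1 σa2], [·, σ²a2]]; descendants get the parent
  average plus a Mendelian term with covariance ½(1 − (F_s + F_d)/2) G0,
  using exact parental inbreeding coefficients so relationship-matrix
  recovery tests are exact. Defaults are the rennet-coagulation-time
  scale: σ²a = 7.155, σ²e = 14.967 (LAB); σ²a = 5.911, σ²pe = 2.091,
  σ²e = 8.901 (FIELD); r_a = 0.9.
- **Records.** LAB cows: one record y = μ + herd-test-day + DIM-class +
  a + e. FIELD cows: repeated test-day records y = μ + herd-year-season +
  stage + a + pe + e. Herd/season/stage effects are drawn from normal
  distributions with configurable variances (defaults 1–2 trait units²)
  rather than from real calendars — enough structure to exercise
  fixed-effect estimation, nothing more.
- **Spectra.** One 1,060-point spectrum per milk sample. The standardized
  record value loads onto a small set of active wavelengths (default 20)
  with total loading norm √(r²/(1−r²)), plus unit-variance independent
  wavelength noise, so the best linear spectral predictor of the record
  has R² = `calibration_signal_r2` (default 0.736, i.e. a calibration
  correlation of ≈0.86, the middle of the published 0.57–0.95 range).

What the generator does **not** emulate: linkage and LD between markers
(so genomic-prediction accuracies here are optimistic per marker),
lactation-curve shapes, selection across generations,
genotype-by-environment interaction, instrument drift or water-absorption
artefacts in spectra, and real calendar structure in herd-test-day
effects. Passing tests therefore validate the *algorithms* under the
stated generative model, not field performance on real milk recordings.

## Spectral editing

Standardization is to zero mean and unit sample variance (ddof = 1) per
wavelength within year-period groups. Outlier screening computes principal
components of the standardized spectra (SVD), the squared Mahalanobis
distance of each sample's first five scores from the score centroid using
the score covariance, and an upper-tail chi-square(5) p-value; samples
with p < 0.01 are removed. The screen is one pass — the covariance is
estimated from all samples including candidates, and removal is not
iterated. Record filters drop FIELD records of cows that also have LAB
records (the cohorts must connect only through the additive effect) and
records missing parity, calving date, id, or a pedigree link. Phenotype
screening removes values beyond 3 SD: raw deviations for single-record LAB
traits, repeatability-model residuals for FIELD traits.

## BayesB calibration

Spike-and-slab Gibbs sampler: each wavelength effect is zero with
probability π (prior 0.95, Beta-updated with prior weight 10) or normal
with a wavelength-specific variance under a scaled-inverse-chi-square slab
(5 df; scale set so the prior explains R² = 0.5 of phenotypic variance —
the convention of the standard Bayesian whole-genome regression software
family). The inclusion indicator is sampled from the collapsed
(effect-integrated) conditional, which mixes well with 1,060 correlated
predictors. Residual variance has a scaled-inverse-chi-square prior
(5 df, scale matching 1 − R²). Production profile: 100,000 iterations,
20,000 burn-in, thinning 10. Desk/test profile: 2,000 iterations, 500
burn-in — posterior-mean calibrations are already stable there for the
synthetic signals used. Chains are exactly reproducible under a fixed
seed. The reported `r_C_LAB` is the in-sample Pearson correlation between
measured and fitted values (matching the published tables' convention); a
k-fold cross-validated variant is also available.

## Relationship matrices

A by the tabular method with inbreeding; A⁻¹ by Henderson's rules with
Meuwissen–Luo inbreeding coefficients (exact inverse of the tabular A);
G by VanRaden's first method, Z centered at twice the observed allele
frequencies and denominator 2Σp(1−p), after marker QC (call rate ≥ 0.95,
MAF ≥ 0.05, one-df Hardy–Weinberg chi-square p ≥ 1e-6, autosomal
known-position markers only) and mean imputation of missing dosages.
H⁻¹ = A⁻¹ plus the genotyped-block correction G*⁻¹ − A22⁻¹, with
G* = 0.95 G + 0.05 A22 blended first and then linearly tuned so its mean
diagonal and overall mean match A22 (defaults of the standard single-step
tool chain; the correction block is unscaled, τ = ω = 1). Blending,
tuning constants and the allele-frequency source are conventions of that
tool chain, adopted here as defaults.

## Mixed models and REML

Henderson's MME are assembled sparse, with fixed effects coded as
intercept plus reference-level dummies; aliased columns (confounded
factor levels, common in small subsets with many classes) are dropped by
rank-revealing QR, equivalent to a generalized-inverse solve, and
fixed-effect estimates are reported sum-to-zero within factor (EBV
contrasts are invariant to this choice). Bivariate systems couple the
additive equations through G0⁻¹ ⊗ K⁻¹ (trait-major ordering) with
trait-diagonal residuals; LAB and FIELD residuals are structurally
uncorrelated because no cow has records in both cohorts after editing.
Direct solves use sparse LU with minimum-degree ordering on C + Cᵀ (the
default column ordering is catastrophic for MME because of the dense
intercept row); a diagonally preconditioned conjugate-gradient solver is
available for large systems.

Variance components: EM-REML is the reference algorithm, accelerated by
average-information (AI) steps. Every AI proposal is damped (initial
damping caps the largest relative parameter change at 2×), projected back
into the parameter space (variance floors at 1e-8 of the data variance;
additive correlation bounded at |r_a| ≤ 0.999, the standard resolution
for boundary estimates — at |r_a| = 1 the additive covariance matrix is
singular and EM creeps indefinitely), and accepted only if it does not
decrease the REML log-likelihood; otherwise the EM update is taken. While
the correlation bound is active and the gradient still points outward,
Newton steps act in the reduced space through the chain-rule Jacobian of
cov = ±0.999·σa1·σa2 (without the chain term, reduced steps point
downhill). Convergence: summed squared relative parameter change below
1e-10; parameters pinned at a floor or bound
are excluded. `ConvergenceError` carries the last estimates.

The EM E-step traces — tr(K⁻¹ C^{a_k a_l}), tr(C^{pe,pe}),
tr(W_t C⁻¹ W_tᵀ) — are exact in both regimes: dense inversion of the
coefficient matrix for systems up to 900 equations, and, beyond that, a
sparse LDLᵀ factorization (up-looking, elimination-tree based) with the
Takahashi selected inverse, which yields all inverse entries on the
Cholesky pattern at roughly factorization cost. The fill-reducing
permutation is the symmetric minimum-degree order; the assembled additive
block always keeps the full 2×2 trait-block pattern (explicit zeros when
G0⁻¹ has a zero entry) so the symbolic factorization is stable across
rounds. Standard errors come from the inverse AI matrix at convergence.

Heritabilities: h² = σ²a/(σ²a + σ²e) for single-record traits,
h² = σ²a/(σ²a + σ²pe + σ²e) for repeated-record traits. Genetic
correlation: r_a = σ_a12/(σa1 σa2), clamped to ±1 only within 1e-8 of the
boundary.

## Cross-validation over phenotyping scenarios

Sires with daughters in both cohorts are split into four folds balanced on
LAB-daughter counts (seeded shuffle, stable sort by descending count,
greedy assignment to the lightest fold). Five scenarios control which
phenotypes enter training: LAB.t, FIELD.t, LAB.t+FIELD.t, FIELD.t+FIELD.v,
LAB.t+FIELD.t+FIELD.v, where ".t" means records of training-sires'
daughters and "FIELD.v" adds FIELD records of validation-sires' daughters.
LAB records of validation daughters are always masked; a structural guard
raises `LeakageError` if any masked record would enter a training system,
and a scenario requesting "LAB.v" is rejected outright. Variance
components are fixed single-trait estimates; only the additive covariance
varies over the assumed-correlation grid (0.1–1.0 in 0.1 steps, r = 1
nudged to 1 − 1e-6 for positive definiteness), and they are not
re-estimated inside folds. The single-trait LAB.t scenario bypasses the
grid. Accuracy is the Pearson correlation between raw masked LAB records
and the validation daughters' LAB-trait (G)EBVs from the bivariate
single-step system (H⁻¹ over all pedigree animals, all genotyped animals
included regardless of masking); an adjusted-phenotype validation target
is deliberately not the default, matching the published accuracy formula,
and accuracy is undefined below 3 validation records.

## Problem sizes used in tests and the acceptance script

- Univariate REML recovery: 100 sires × 20 LAB daughters (2,000 cows),
  generating values σ²a = 7.155, σ²e = 14.967; 20 replicates in the test
  suite, 10 in the acceptance script.
- Bivariate r_a recovery: 50 shared sires, 6 LAB + 30 FIELD daughters
  each (300 LAB cows, 1,500 FIELD cows × 2 records), r_a = 0.9, male
  founder fraction 0.15; 10 replicates (6 in the acceptance script).
  Replicates whose likelihood peaks at the correlation boundary report
  the bounded value 0.999; they are genuine features of small two-cohort
  designs and are averaged as-is.
- Scenario cross-validation: 32 shared sires (male founder pool 32 of
  240), 16 LAB + 80 FIELD daughters per sire plus intermediate-generation
  FIELD dams, 2 records per FIELD cow, 1,500 markers, 30% of FIELD cows
  genotyped, assumed grid value 0.9. These sizes keep per-replicate fold
  accuracies informative while the whole suite stays desk-scale; the
  absolute accuracies are smaller than published ones (the FIELD tier
  here is ~100× smaller) but the scenario ordering
  LAB.t < LAB.t+FIELD.t < (+FIELD.v) reproduces.

## Known limitations

- Unlinked markers mean G carries no LD structure; single-step gains are
  driven purely by realized-relationship precision.
- Two traits maximum; no maternal effects, random regression, or
  test-day covariance functions.
- The correlation bound (0.999) means boundary replicates report a
  bounded, not an unconstrained, maximum-likelihood estimate.
- Standard errors are asymptotic (inverse AI matrix) and omitted when a
  run converges through EM steps alone.
- The tabular A (and A22) is dense; pedigrees beyond ~20,000 animals
  would need an indirect A22 algorithm that is not implemented.
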