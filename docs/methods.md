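# Methods

This note documents the statistical models, simulator assumptions,
default parameters and numerical choices behind `crossprs`. It is the
reference for what each stage computes and for what the synthetic-data
tests do — and do not — demonstrate about real data.

## Synthetic two-population genotypes

Genotypes are simulated per LD block from a first-order autoregressive
latent Gaussian: variants *i* and *j* of a block have latent correlation
`ρ^{|i−j|}` (default ρ = 0.9), blocks are independent, and a haplotype
carries the counted allele when its latent value falls below `Φ⁻¹(p)` for
the variant's population frequency *p*. A diploid dosage is the sum of
two independent haplotypes. Population divergence follows Balding–Nichols:
each variant's ancestral frequency is drawn uniformly from a configurable
interval (default (0.1, 0.9)) and each population's frequency from
`Beta(p(1−Fst)/Fst, (1−p)(1−Fst)/Fst)` (draws clipped to
[10⁻⁴, 1−10⁻⁴] so no variant is structurally monomorphic). A
Hudson-estimator check on generated data recovers Fst within the
simulation's sampling error.

Two seeds control reproducibility. The *frequency seed* pins the
ancestral draws, the per-population Balding–Nichols draws and the allele
labels — everything that defines a population; the ordinary seed draws
individuals. Panels generated with the same frequency seed and different
seeds are independent samples from the same pair of populations, which is
what a study needs when it simulates a reference panel, a discovery
cohort and target cohorts that must share LD structure. At Fst = 0 the
two populations have identical frequencies by construction.

Variant positions are evenly spaced within each block's span; blocks are
assigned round-robin to chromosomes 1–22, and the first chromosome-6
block is pinned to start at 25 Mb so that the MHC region modes always
have variants to act on.

What the generator deliberately does not emulate: recombination maps and
realistic LD decay, demographic history, imputation-quality structure,
allele-frequency-dependent genotyping error, or covariate–disease
confounding (age and sex are generated independent of case status; the
analysis adjusts for them, it does not model their effect). Passing tests
therefore show the pipeline's *statistical machinery* is correct under
the stated model, not that any particular real-data R² will be attained.

## Disease model

Liability is the standardized-genotype weighted sum of causal effects
plus `Normal(0, 1−h²)` noise; an individual is a case when liability
exceeds `Φ⁻¹(1−K)`. Causal variants are a random subset (default 30% of
variants); raw effects are drawn standard normal and rescaled so the
genetic component's *realized* variance is exactly h² in the cohort —
this keeps the prevalence calibration exact (the realized case fraction
of a large cohort converges to K) at the cost of a per-cohort rescaling
factor on the stored true effects. A disease architecture can be shared
across several cohorts (discovery, matched target, diverged target) by
passing a common architecture seed; environmental noise and covariates
remain cohort-specific.

The default prevalence for pipeline-scale simulations is K = 0.02, so
cohorts of a few thousand to twenty thousand individuals carry enough
cases for stable logistic fits; the rare-disease value K = 0.002 is used
where only the liability arithmetic or the power simulation is involved,
which need no simulated genotypes. The cross-ancestry attenuation study
(below) uses K = 0.1 for the same reason at its smaller cohort sizes.

## Discovery summary statistics

Per-variant effects come from the logistic score test against the
intercept-only null: with case indicator *y*, mean *ȳ* and dosage *g*,

    U = Σ (y−ȳ) g,   V = ȳ(1−ȳ) Σ (g−ḡ)²,
    β̂ = U/V,  se = 1/√V,  p from U²/V ~ χ²₁ .

The one-step estimator is the standard fast approximation to the
per-variant logistic Wald fit and is well behaved at low case counts.
Monomorphic variants are flagged and withheld. A *tag-only* switch
removes the truly causal variants from the output, forcing downstream
scores to work through LD tags — the mechanism behind cross-ancestry
attenuation. Configurable fractions of emitted variants are rewritten
with palindromic (A/T, C/G) allele codings or strand-complemented
alleles (defaults 5% each) so harmonization is exercised; affected
variant ids are recorded.

## Quality control

Variant filters are applied in a fixed order — call rate, imputation
INFO, minor allele frequency, Hardy–Weinberg equilibrium, missingness,
non-autosomal — with defaults call rate > 0.90, INFO > 0.7, MAF > 0.01,
HWE p ≥ 10⁻¹⁰, missingness < 0.10. A variant is counted once under the
first filter it fails, so the exclusion report always reconciles. A zero
threshold disables its (strict) filter, giving an exact pass-everything
mode. Variants without an INFO value pass the INFO filter by convention.
Call rate and missingness are redundant at their defaults; both are kept
as independent knobs. HWE uses the two-sided exact conditional test
(probabilities summed over heterozygote counts no more probable than the
observed one), computed by the standard two-directional recurrence on all
retained individuals; it is verified against an exact-fraction
enumeration oracle for every genotype table up to 50 individuals.

Individual-level QC removes, in order: PCA outliers (any of the first 4
PC scores more than 4 SD from that PC's mean, single pass), individuals
with > 10% missing genotypes, then individuals without complete
phenotype/covariate records — each counted once under its first
applicable reason. Note that flagging a *single* diverged individual
requires its PC displacement to rise above the Marchenko–Pastur bulk of
the genotype matrix, which at Fst ≈ 0.2 takes a few thousand informative
variants. Kinship-based relatedness pruning is a deliberate no-op hook:
it belongs to biobank-scale replication cohorts outside this pipeline's
scope.

## Harmonization

Summary-statistic variants are matched to the target on chromosome +
position (variant IDs differ across imputation panels and are not used).
Palindromic pairs are excluded unconditionally — allele labels cannot
resolve their strand, whatever the frequency. If the target alleles match
in order the action is `match`; reversed order is `flip_effect`;
otherwise the strand complement is tried before declaring a mismatch.
Target positions with more than one allele pair are excluded as
multiallelic; duplicated identical variants are an input error. The six
actions partition the input exactly.

A `flip_effect` variant is scored on its effect-allele dosage `2−g`
rather than by negating β: both conventions give scores identical up to a
constant shared by every individual (irrelevant after standardization),
but the dosage convention makes two invariants exact — reversing every
target allele pair changes no score value, and the MHC-only and
without-MHC scores of a partition sum to the with-MHC score.

## Clumping and thresholding

Clumping is greedy: visit variants by ascending p (ties broken by
chromosome, position, then alleles — determinism under input
permutation); each unassigned visited variant becomes an index and
removes unassigned variants within ±250 kb (default window; the c+t
convention) whose reference-panel dosage r² with it exceeds the
threshold. r² is composite LD on mean-imputed dosages, not phased
haplotypes. Variants absent from the reference cannot be clumped and are
retained with a warning count. Clumping runs once per (region mode, r²)
on the full harmonized set and is reused across p-thresholds
(clump-then-threshold, the convention of standard c+t tools); region
filtering precedes clumping so each score's clumps are internally
consistent. The standard grid — r² ∈ {0.001, 0.01, 0.05, 0.1, 0.2, 0.4,
0.6}, 16 p-thresholds from 10⁻⁸ to 0.5, three MHC modes — enumerates 336
configurations. A configuration with no surviving variants yields an
all-zero, flagged score.

## Evaluation

Logistic models are fitted by Newton/IRLS (statsmodels) with tolerance
10⁻⁸ and at most 100 iterations; single-class responses and
rank-deficient designs are errors (naming the dependent columns), and
quasi-separated fits are flagged rather than silently returned. The
model-fit p-value is the likelihood-ratio test of full (covariates +
standardized PRS) vs null (covariates only) — the natural choice when the
null model is explicitly constructed. Nagelkerke's R² likewise contrasts
full vs covariate-only, so it isolates the PRS increment rather than
conflating covariate effects.

The liability conversion multiplies the observed R² by
`C = K(1−K)/z² · K(1−K)/(P(1−P)) · e` and divides by `1 + C·θ·R²`, with
`e = 1 − P^{2P}(1−P)^{2(1−P)}` mapping Nagelkerke's rescaled statistic
back to the observed (Cox–Snell) scale before the ascertainment
correction — omitting `e` inflates "liability" R² several-fold and can
push it above h². With an unascertained sample (P = K) the formula
reduces to `C·R²` exactly, and θ = 0.

AUCs are rank-based (midranks for ties) for the full model, the null
model and the raw score, and equal trapezoidal integration of the
empirical ROC. Quartiles are cut at ranks n/4, 2n/4, 3n/4 after a stable
sort (tied scores keep input order). Quartile odds ratios (Q2–Q4 vs Q1)
come from one covariate-adjusted logistic fit with Wald 95% intervals
`exp(b ± 1.96·se)`; a contrast whose quartile (or the reference) has no
cases is reported as undefined rather than as a diverging estimate.
Optimal-score selection takes the minimal fit p, breaking ties toward
larger liability R², then fewer variants, then input order. A constant
score short-circuits to fit p = 1 and R² = 0.

## Cross-cohort comparison and power

Sub-sampling draws cases and controls without replacement within an
iteration, independently across iterations, from a single seeded
generator. By default the best p-threshold is re-selected inside every
sub-sample (mirroring optimal-score selection in the comparator cohort);
a flag fixes the configuration instead. Degenerate fits still yield an R²
and are retained, matching the add-one-smoothed empirical p-value
`(N_below+1)/(N_iter+1)`, which is never 0 and never below
`1/(N_iter+1)`. The power simulation generates fresh data each iteration
— controls `Normal(0,1)`, cases `Normal(δ,1)` — and uses the Wald z-test
of the score coefficient from a logistic fit, the natural reading of a
"Wald test" in a case/control pipeline (a two-sample z approximation
gives nearly identical results but is not the default). At the
42-case / 40,490-control design the analytic power at δ = 0.5 is ≈ 0.90,
and the simulation reproduces it.

## The attenuation study

The acceptance-level demonstration of cross-ancestry attenuation uses: 60
blocks × 10 SNPs, ρ = 0.9, Fst = 0.3 between discovery and diverged
populations, ancestral frequencies U(0.2, 0.8); 10% causal variants,
h² = 0.25 — chosen so the matched-ancestry target's liability R² lands
near 0.05 — and K = 0.1 so cohorts of 6,000–16,000 carry hundreds of
cases (the precision the resampling comparison needs). Discovery
(n = 8,000) sumstats are estimated tag-only; scores use clumping r² 0.1
with p-thresholds {0.01, 0.05, 0.5}. The matched-ancestry target
out-performs the diverged target in ≫ 80% of replicates, and
sub-sampling the matched cohort to the diverged cohort's case/control
counts flags the deficit (empirical p < 0.05) in ≫ 80% of outer
replicates at 99 iterations each. These problem sizes were fixed from
pilot runs of the generator before the assertions were frozen.

## Known limitations

- The AR(1)-within-block LD model creates tag/causal divergence through
  allele-frequency perturbation only; the latent correlation structure is
  shared between populations, which understates how strongly real LD
  patterns differ. Attenuation magnitudes are therefore qualitative.
- Liability-scale conversion is the Lee-style first-order approximation;
  at very large R² or extreme ascertainment it is approximate.
- The per-variant score test slightly underestimates very large effects
  relative to a full logistic fit (one-step estimator).
- PRS evaluation fits and evaluates on the same cohort when used that
  way; nothing in the pipeline corrects for the resulting optimism —
  cross-cohort application is the intended use.
- Wald quartile CIs and the single-pass PCA outlier rule are simple
  defaults, not robust alternatives (profile likelihood, iterative
  outlier removal).
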