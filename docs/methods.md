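# Methods

## Scope and model

`mr2step` implements summary-data two-sample Mendelian randomization under
the linear instrumental-variable model Γⱼ = β γⱼ + αⱼ, where γⱼ is SNP *j*'s
effect on the exposure, Γⱼ its effect on the outcome, β the causal effect of
interest, and αⱼ a horizontal-pleiotropy effect. Estimation uses only
per-SNP association statistics (beta, SE, p, allele frequencies) from two
non-overlapping GWAS; individual-level data never enter.

## Instrument selection

Three filters, all strict inequalities: association p < 5×10⁻⁸; single-SNP
strength F = (β/SE)² > 10 (the standard summary-data approximation of the
first-stage F); and greedy p-value clumping — repeatedly take the smallest-p
unassigned SNP as index and remove same-chromosome SNPs within ±1,000,000 bp
whose pairwise r² ≥ 0.001. Ties on p break on (chromosome, position), making
clumping deterministic. No LD reference panel is computed from genotypes:
the clumper accepts an externally supplied pairwise r² table and otherwise
falls back to distance-only pruning (every same-chromosome SNP inside the
window is removed), which is conservative and exact for the generator's
mutually independent instruments. Pairs absent from a supplied r² table are
treated as independent.

## Harmonization

Outcome records are aligned to the exposure's effect allele; the exposure
side is never altered, so effect signs stay interpretable per
exposure-increasing allele. Same allele pair, swapped orientation → outcome
beta negated and eaf complemented; allele pairs reconcilable only by strand
complement are complemented first. Palindromic SNPs (A/T, C/G) are oriented
purely by allele frequency — the letters are uninformative — and only when
both frequencies lie outside the ambiguity band 0.5 ± 0.08 (configurable);
otherwise they are dropped, as are SNPs with a missing frequency on either
side (conservative). Instruments absent from the outcome GWAS are dropped
and counted; no proxy-SNP search is attempted. Indel and non-ACGT rows are
dropped at I/O validation because the palindrome logic is defined for
single-base SNPs.

## Estimators and inference

* **IVW**: closed-form weighted regression through the origin, weights
  1/σ_Γ². Random effects are multiplicative: the fixed-effects SE is scaled
  by max(1, √(Q/(J−1))), never deflated. Normal reference for p-values.
* **MR-Egger**: weighted regression with intercept after re-orienting each
  SNP so γ ≥ 0 (the intercept is orientation-dependent; this is the
  standard convention). The 2×2 weighted normal equations are solved
  directly so the unit-scale covariance is available even at an exact fit;
  both slope and intercept SEs carry the multiplicative floor
  max(1, σ̂) and use a t reference with J−2 df. With overdispersion
  (σ̂ > 1) this reproduces textbook WLS inference exactly (cross-checked
  against statsmodels in the tests).
* **Weighted median**: per-SNP ratios βⱼ = Γⱼ/γⱼ with normalized weights
  wⱼ = γⱼ²/σ_Γj² (inverse first-order ratio variance); the estimate
  interpolates the weighted empirical quantile function — breakpoints
  pⱼ = (Σ_{i≤j} wᵢ − wⱼ/2)/Σw — at p = 0.5. SE from a parametric bootstrap:
  resample γ*ⱼ ~ N(γ̂ⱼ, σ_γj²), Γ*ⱼ ~ N(Γ̂ⱼ, σ_Γj²), recompute, take the SD
  over n_boot = 1000 seeded replicates. `n_boot = 0` gives the point
  estimate only, used inside large Monte-Carlo loops where only the
  estimate is consumed.
* **CIs** are normal-theory β ± z·SE at 95% by default. Minimum instrument
  counts: 2 (IVW), 3 (Egger, weighted median), 4 (MR-PRESSO); below them a
  dedicated error directs the caller to the Wald ratio.

The estimators are scikit-learn-style regressors (`fit(X, y,
se_outcome=...)`, fitted attributes `beta_`, `se_`, `pval_`, `estimate_`,
plus `predict`), so they compose with sklearn tooling; the module-level
functions wrap them for `HarmonizedSet` inputs.

## Sensitivity diagnostics

Cochran's Q is the weighted residual sum of squares of the fixed-effects
fit (equivalently Σwⱼ(βⱼ − β_FE)² on the ratio scale), chi-square with J−1
df. Heterogeneity is reported, never used to discard pairs — the main
estimate is random-effects IVW, which absorbs it. Leave-one-out refits
random-effects IVW excluding each SNP; an exclusion is flagged as
distorting when it flips the sign of the full-set estimate or loses its
nominal significance.

MR-PRESSO: the observed residual sum of squares uses leave-one-out slopes,
RSS = Σⱼ wⱼ(Γ̂ⱼ − β̂₋ⱼ γ̂ⱼ)² with wⱼ = 1/σ_Γj² (the dimensionally correct
weight; on the ratio scale it coincides with the Q convention). The null
distribution comes from n_sim = 1000 parametric draws Γ*ⱼ ~ N(β̂₋ⱼγ̂ⱼ, σ_Γj²),
γ*ⱼ ~ N(γ̂ⱼ, σ_γj²) with the RSS fully recomputed per draw. Simulation
p-values are (1 + #{sim ≥ obs})/(1 + n_sim), so they are strictly positive;
per-SNP outlier p-values are Bonferroni-multiplied by J and compared to
0.05. Note the resolution limit: with n_sim simulations the smallest
attainable adjusted p is ≈ J/n_sim, so outlier detection at α = 0.05
requires n_sim ≳ 20·J. When outliers are found, the corrected estimate is
random-effects IVW without them, and the distortion p-value compares the
observed slope displacement against 1000 random same-size subset removals.
SNPs are sorted by identifier before simulation, making the outlier set
invariant to row order and exactly reproducible for a given seed.

## Mediation

Product of coefficients: mediated = a·b, direct = total − a·b, proportion =
a·b/total (undefined at total = 0 → explicit error). Only mediator→outcome
pairs passing a nominal p < 0.05 gate are decomposed, with a flag recording
whether they also clear the Bonferroni threshold α/m; the step-2 Bonferroni
denominator is stored explicitly in the plan because published analyses
sometimes report a denominator that differs from the pairwise test count
(the pipeline logs the discrepancy rather than guessing intent). The
delta-method SE for the mediated effect, √(a²σ_b² + b²σ_a²), and the
first-order proportion CI are optional extensions (the workflow this
package mirrors reports none); they treat the three inputs as independent,
which is approximate because the total and step-one fits share exposure
instruments. Proportions are reported as fractions and as percentages
rounded to two decimals.

## Synthetic data generator

The generator emulates large continuous-trait GWAS: per SNP, maf ~
U(0.05, 0.5); SE = 1/√(2·maf(1−maf)·n) (standardized trait); true effects
γⱼ ~ N(0, τ²) resampled until the expected F exceeds 10; observed effects
add N(0, SE²) noise; positions are spaced ≥ 2 Mb apart so instruments are
clumping-independent; allele pairs avoid palindromes except for a
configurable fraction used in harmonization tests. Defaults are the study
conditions the package targets: n_exposure = 766,345, n_outcome = 450,243,
n_mediator = 51,665 (the sample sizes of the motivating
educational-attainment, body-composition, and brain-imaging GWAS);
n_snps = 300 ("hundreds of instruments"); τ = 0.05, which puts typical
instruments well past genome-wide significance at these sample sizes (about
90% of generated SNPs survive the full selection filter); causal effects of
interest around 0.05–0.25 on the standardized scale. The null/calibration
scenario sets β = 0 with no pleiotropy.

Pleiotropy modes: `none`; `balanced`/`directional`, αⱼ ~ N(mean, sd)
aligned to the exposure-increasing allele (multiplied by sign(γⱼ)) — without
this alignment a directional mean would average to zero under Egger's γ ≥ 0
orientation and be unrecoverable by construction; `correlated`, αⱼ = ρ·γⱼ +
noise, violating the InSIDE assumption. Outlier SNPs receive a positive
offset of a configurable multiple (default 10) of their outcome SE.

The mediation chain draws two independent instrument sets — one for the
exposure (mediator effect a·γ, outcome effect (direct + a·b)·γ) and one for
the mediator (outcome effect b·δ) — and assembles three overlapping tables
the way real multi-trait analyses see them.

What the generator does **not** emulate: LD structure (instruments are
independent by construction, so clumping and the r² pathway are exercised
only by dedicated unit fixtures), sample overlap between the two GWAS,
allele-frequency estimation error, case–control traits, winner's-curse
selection in the discovery GWAS, and population stratification. Passing
recovery tests therefore demonstrates correctness of the estimators under
the model they assume, not robustness to those real-data complications.

## Numerical choices and test conditions

* Floats are written with 17 significant digits and parsed round-trip, so
  write→read is bit-exact.
* Weak-instrument attenuation is visible at the generator's mediator sample
  size (SE ≈ 0.007 against effects ~0.05): the mediator→outcome slope
  attenuates by ≈ 2–3%, which is why pipeline recovery checks compare means
  against Monte-Carlo error rather than demanding exactness.
* Monte-Carlo problem sizes used by the validation suite: calibration at
  2,000 (Q, J = 20) and 1,000 (Egger intercept, J = 100) replicates;
  recovery at 500 replicates with J = 100; MR-PRESSO rates at 200
  replicates with J = 50 and n_sim = 1000; end-to-end mediation recovery at
  200 seeds with J = 150 per instrument set, bootstrap 100 and PRESSO
  n_sim = 200 (the diagnostics' simulation sizes do not affect the point
  estimates the recovery check consumes).
* In the weighted-median breakdown scenario, 40 of 100 instruments drawn
  from the weaker 60% share a pleiotropic ratio offset of +0.5, so the
  invalid set carries well under half the weight — the regime the estimator
  is designed for — while IVW is visibly biased upward.

## Known limitations

Distance-only clumping without an r² table can over-prune dense regions.
No Steiger directionality filtering, multivariable MR, proxy-SNP lookup,
mode-based estimators, or funnel/radial plots. The Egger intercept's
meaning depends on the effect-allele orientation convention; analyses mixing
conventions across sources must harmonize to exposure-increasing alleles
first (the pipeline does this automatically).
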