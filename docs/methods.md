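# Methods

`tacpk2pd` models the pharmacokinetics of twice-daily oral tacrolimus in
liver-transplant recipients simultaneously in whole blood (WB, ng/mL) and
inside peripheral blood mononuclear cells (PBMC, pg per million cells),
links intracellular exposure to calcineurin (CaN) inhibition, and asks how
often therapeutic whole-blood troughs actually deliver an inhibitory
intracellular concentration. This note documents the models, the numerical
choices, and what the synthetic cohort does and does not emulate.

## Structural pharmacokinetic model

A linear two-compartment system with double-gamma oral absorption:

    in(t)  = dose · [ r·g(t; b1, a1) + (1−r)·g(t; b2, a2) ]
    dA1/dt = in(t) − (ke + k12)·A1 + k21·A2
    dA2/dt = k12·A1 − k21·A2
    C_WB   = 1000·A1 / V          (ng/mL; A1 mg, V L)
    C_PBMC = S·A2                 (pg per million cells)

where `g(t; b, a)` is a gamma density (rate `a` 1/h, shape `b`). The two
gamma phases describe a fast initial uptake and a prolonged slow input;
bioavailability is absorbed into the apparent parameters (oral data cannot
separate it), so the input integrates to the full dose. The PBMC
compartment exchanges mass both ways (k12/k21); `S` converts peripheral
amount to a per-cell concentration, so per-subject PBMC counts never enter
the structural model. Dosing is strictly q12h; profiles are reported over
the final interval after `n_prior_doses` (default 13, ≈ one week — the
trough then changes by <1 % per interval, see `steady_state_check`).

Because the system is linear and time-invariant, each dose's response is
the convolution of the gamma input with a bi-exponential impulse response
and has a closed form: with eigen-decay rates α ≥ β of the disposition
matrix,

    G(t; b, a, μ) = ∫₀ᵗ g(s; b, a)·e^{−μ(t−s)} ds
                  = e^{−μt} (a/(a−μ))^b P(b, (a−μ)t)          (a > μ)
                  = (at)^b e^{−at} ₁F₁(1; b+1; (a−μ)t)/Γ(b+1)  (a ≤ μ)

with P the regularized incomplete gamma function and ₁F₁ Kummer's
function (whose argument is ≤ 0 in the second branch, where it is bounded
in (0,1] — both branches are numerically stable; the switch is at
a−μ = 10⁻⁶·max(a,1)). Multiple doses superpose. This makes simulation
exact to floating point (verified against the Bateman equation at rtol
10⁻⁶ over random draws), removes any shape restriction on `b`, and
vectorizes over thousands of parameter vectors — which is what makes the
nonparametric fit and Monte-Carlo steps cheap. Near-degenerate
eigenvalues (α≈β) are split by a 10⁻⁹ relative nudge.

## Residual error model

The assay error polynomials are SD = 1 + 0.1·C for whole blood and
SD = 5 + 0.12·C for PBMC, inflated by an additional noise term λ = 1; the
effective residual SD is σ(C) = assay_sd(C) + λ and observation weights
are 1/σ². σ is evaluated at the **observed** concentration (data-fixed),
mirroring how assay-error polynomials are used in nonparametric
pharmacometric software; this keeps the likelihood a plain weighted
least-squares criterion in the prediction. One consequence, documented
because it shows up in diagnostics: with σ growing in the observation,
the weighted-likelihood optimum sits slightly below the true curve, so
even a correctly specified fit leaves a small positive mean weighted
residual (≈ +0.1 at these noise levels) while the truth itself gives
≈ −0.1. The calibration bands used in the tests (|mean| < 0.15,
SD ∈ [0.8, 1.2]) account for this.

## Nonparametric population estimation

The population distribution is a discrete mixing distribution: support
points θⱼ with weights wⱼ, estimated by maximum likelihood. Estimation
works in a transformed space (log for positive parameters, logit for r)
inside a wide box (`DEFAULT_BOUNDS`). The support bank is initialized
with 8192 scrambled-Sobol points plus one likelihood-optimized candidate
per subject (an annealed local search from the subject's best grid point
— the adaptive-grid device that lets each posterior reach its own mode;
without it, posterior-mean predictions flatten the absorption peak).
Weights follow the multiplicative EM update

    wⱼ ← wⱼ · (1/n) Σᵢ Pᵢⱼ / Σₖ wₖPᵢₖ

(log-likelihood provably non-decreasing, asserted at every iteration;
stop at gain < 10⁻⁴, max 500 iterations). Points below 10⁻⁶ of the
maximum weight are condensed away, then three shrinking local
perturbation cycles (±10 %, ±5 %, ±2.5 % of the transformed box) move
surviving points when that improves the likelihood. This is a reduced
form of full adaptive-grid refinement — a documented simplification, not
NPAG's interior-point condensation. Because concentrations are linear in
dose, the likelihood bank needs one vectorized unit-dose simulation per
support bank; a full n = 32 fit takes a few seconds.

Individual parameters are Bayes posterior means over the support
(computed in the transformed space and back-transformed); model AIC uses
the convention P = K(d+1) − 1 free quantities (K support points, d = 10
structural parameters, one simplex constraint), suitable only for
relative comparisons. The VPC simulates replicate cohorts at the observed
design (parameters resampled from the discrete distribution, noise from
σ), bins by nominal sampling time, and reports 5/50/95 percentile bands
with 95 % envelopes plus the fraction of observations inside the median
90 % band; no prediction correction is applied. Covariate screening
regresses posterior parameters on continuous covariates and uses
Mann-Whitney/Kruskal-Wallis for categorical ones, flagging p < 0.01.

## Exposure metrics

C0 is the t = 0 predose sample (equal to the 12 h trough at steady
state), Cmax/Tmax come from the raw samples (earliest maximum on ties),
AUC0-12 from the linear trapezoidal rule — on raw samples, or on a
model-predicted dense profile (0.05 h grid) when a model is supplied.
CL/F = dose/AUC_WB with mg→ng conversion (1.5 mg over 102.3 ng·h/mL
gives 14.7 L/h). The intracellular diffusion ratio is reported as a
concentration ratio: intracellular amounts are converted to ng/mL using
0.2 µL of cell volume per million PBMC (~200 fL per cell), i.e.
ratio = (AUC_PBMC/0.2)/AUC_WB. The raw mixed-unit quotient is ~4.9×
smaller; the volume-converted scale is the one on which the conventional
ratio values (≈ 24) live. Correlations pass a Shapiro gate (α = 0.05 on
both variables, optionally after log-transforming x): Pearson with
regression slope if both look normal, Spearman otherwise (exact
permutation p for n ≤ 8 without ties).

## Pharmacogenetic statistics

Hardy-Weinberg testing is the two-sided exact conditional test
(probabilities of heterozygote counts given allele counts, summed over
outcomes no more probable than observed; monomorphic samples give p = 1),
computed in log-space and verified against exact rational-arithmetic
enumeration for n ≤ 200. Of note, the borderline heterozygote-excess
patterns a cohort of 32 can show (e.g. 2/21/9) reach p ≈ 0.06 under the
exact test even when asymptotic chi-square calls them significant.

Three-locus ABCB1 haplotypes (3435/1236/2677) are inferred by EM over the
eight possible haplotypes; the triallelic 2677 G>T/A is pooled onto the
G/T axis (A counts toward T) for haplotype work while raw genotype tables
keep A distinct. Convergence is declared at a maximum frequency change
< 10⁻⁸, leaving ~10⁻⁷ slack in the log-likelihood (tests allow 10⁻⁶).
Diplotypes are classified HomTTT / HetTTT / other by TTT-haplotype count.
Association tests are Mann-Whitney (exact when the combined n ≤ 20 and
tie-free — cohort subgroups are tiny) or Kruskal-Wallis with pairwise
Mann-Whitney post-hocs, Bonferroni-corrected over the pairs; the family
size is an explicit argument because post-hoc families are
context-dependent. All values tied returns p = 1 by convention.

## Calcineurin inhibition model

Maximal CaN inhibition over the interval (in % of the pre-treatment
basal activity; negative = inhibited) versus peak concentration follows

    E(c) = I_min + (I_max − I_min)/(1 + c/IC50)

the hyperbolic inhibitory form with E(0) = I_max (lowest inhibitory
effect), E(∞) → I_min (highest), E(IC50) at the midpoint, Hill
coefficient fixed at 1. (The form is written so that its stated limits
hold; a literal transcription of the equation as sometimes printed, with
I_min + (I_min − I_max)/(1 + c/IC50), contradicts its own parameter
glossary at c = 0 and is not used.) Fitting is multi-start nonlinear
least squares over (I_min, I_max, log IC50) with IC50 bounded within a
×50 margin of the observed concentration range. A fit is flagged
unidentifiable when IC50 pins to its search boundary, when I_min
collapses onto I_max, or when the predicted effect span across the
observed concentrations is below twice the residual SD (a
signal-to-noise gate; under destroyed pairings it fires in ≳95 % of
permutations, and never on the noise-free or study-condition fits).
Inversion c = IC50·(I_max − target)/(target − I_min) is exact
(round-trip identity to 10⁻¹⁰). Time-course (indirect-response) PD
modelling is out of scope: only Cmax versus maximal inhibition is
modelled.

## Probability of target attainment

Monte-Carlo profiles are drawn either from a fitted nonparametric model
(support points with their weights) or from the generator population
(full covariate + titration emulation, one profile per simulated
subject). Each profile contributes its model-predicted steady-state
whole-blood trough (t = 12 h; true value, no assay noise — attainment
concerns true exposure; a flag adds noise for sensitivity analysis) and
its intracellular Cmax over a 0.05 h grid. Profiles are binned by trough
into half-open TDM strata [0,4), [4,6), [6,10) ng/mL plus an explicit
above-range stratum; per bin and per target (defaults: the intracellular
IC50 of 100 and the IC37 of 65 pg per million cells) the attainment
probability is the fraction of profiles at or above the target. Empty
bins report an undefined probability, never 0.

## Synthetic cohort generator

The generator emulates the study conditions so every stage runs without
external data. Per subject: covariates from range-bounded scaled-beta
distributions (age 62 [51–70] y, weight 97 [50–121] kg, albumin 23.8
[23.0–39.6] g/L, hematocrit 30.5 [22.8–39.1] %, PBMC count 2.3 [1.3–3.6]
G/L, 30/32 male); ABCB1 genotypes as haplotype pairs (recipient TTT
frequency 0.39, giving the observed Het/Hom TTT split) plus direct
genotype draws for 1199G>A (recipient GA 9 %), CYP3A4\*22 and CYP3A5\*3;
log-normal inter-individual variability around the population medians

    r 0.25 · a1 3.0 · b1 3.0 · a2 0.09 · b2 2.0
    V 18.5 L · ke 0.79 /h · k12 0.05 /h · k21 2.5 /h · S 12450

with CVs of 18–30 % (r varies on the logit scale). These medians are
calibration defaults chosen so the simulated cohort reproduces the
published exposure summaries (whole-blood AUC0-12 ≈ 102 ng·h/mL at the
1.5 mg median dose, Cmax ≈ 16–18 ng/mL near 1.5 h, trough ≈ 6 ng/mL,
diffusion ratio ≈ 23.6); the published peak-to-trough pattern (trough
73 % of the interval mean despite a 2.8× peak) forces a small fast
absorption fraction, a long slow phase (mean absorption time ≈ 22 h) and
fast elimination. The recipient 1199GA variant divides V by 1.6 (uniform
whole-blood exposure scale-up) and multiplies S by 3.2; after dose
titration partially compensates, the observed intracellular contrast is
≈ 2×, matching the reported genotype medians, while the whole-blood
contrast is largely masked — which is exactly what therapeutic drug
monitoring does to exposure genetics, and why the association tests in
this package look at the intracellular side.

Dose titration emulates TDM: start at 0.04 mg/kg per 12 h rounded to
0.5 mg steps (bounds 0.5–4 mg), then two adjustment cycles that rescale
the dose toward a 5.2 ng/mL trough **only when** the measured trough
leaves the 4–10 ng/mL range, never cutting by more than ×0.35 or raising
by more than ×2.5 per cycle (clinicians avoid aggressive de-escalation
early post transplant — this cap is also what leaves high-exposure
subjects near the top of the range). Clearance carries 19 % CV
inter-occasion variability between titration occasions and the study
day; that, plus dose rounding, is what leaves ≈ 81 % (not 100 %) of
final troughs in range. Residual noise is additive Gaussian with
SD σ(c) = assay_sd(c) + λ, truncated at zero — deliberately the same
error model the estimator assumes.

The whole-blood↔intracellular AUC correlation (r² ≈ 0.5) is not imposed
by a shared random effect: post-titration, both AUCs are proportional to
dose/ke, so titration imprecision is automatically a shared variance
component; AUC_WB adds V variability and AUC_PBMC adds S/k12/k21
variability, and the CVs above put the squared correlation at the
observed level.

Calcineurin activity is generated as basal × (1 + E(C_PBMC(t))/100) ×
log-normal noise (CV 20 %), with basal ~ log-normal (median 371.6,
CV 66 %) and the inhibition curve I_min = −74 %, I_max = 0, intracellular
IC50 = 100 pg per million cells (whole-blood IC50 18 ng/mL is carried in
the config for completeness). With activity noise at zero, fitting the
inhibition curve on (true Cmax_PBMC, observed maximal inhibition) pairs
recovers IC50 exactly, because the activity minimum falls at the
concentration maximum on the same grid.

What the generator does **not** emulate: assay failures and missing
samples; fluconazole and steroid interactions; donor-genotype effects on
PK; within-day nonstationarity of clearance; cell-volume variation
between patients (the per-cell normalization is taken as exact); any
clinical outcome. Passing tests therefore show that the pipeline's
statistics behave correctly under the stated data-generating model — not
that the model is true of any real cohort.

## Problem sizes used in tests and the acceptance script

Replicate cohort checks use 10 seeds × 320 subjects; target attainment
uses 1000 Monte-Carlo profiles; the VPC uses 200 replicate simulations;
the estimation recovery runs on one n = 32 cohort with the default 8192
+ 32 support bank. These sizes give Monte-Carlo noise well below the
comparison bands (e.g. across-seed spread of the cohort medians ≈ 1–3 %).

## Known limitations

* The refinement stage is a perturbation/candidate scheme, not a full
  adaptive-grid interior-point condensation; with very sparse designs the
  support may under-resolve multimodality.
* The AIC parameter count is a convention; absolute AIC values are not
  comparable across error models.
* σ-at-observed weighting leaves the small systematic residual offset
  discussed above; it is a property of the estimator convention, not a
  bug, and disappears if σ is evaluated at predictions (not done here,
  to keep the likelihood data-fixed).
* The exact Mann-Whitney path is limited to combined n ≤ 20 without
  ties; beyond that the normal approximation with tie correction is
  used.
* Estimation assumes a common q12h steady-state history (13 prior doses)
  for all subjects; irregular regimens are out of scope.
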