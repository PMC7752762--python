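# Methods

`wasatrial` analyzes two-arm macronutrient-restriction weight-loss trials
with the four analysis cells defined by diet (healthy low-carbohydrate,
HLC, vs. healthy low-fat, HLF) and sex. This note records the statistical
models, the synthetic-data generating process, and the numerical and design
choices, in enough detail to reproduce or challenge any of them.

## The WASA adherence score

Both arms share a 20 g/day prescription for their restricted macronutrient
(carbohydrate on HLC, fat on HLF) during the initial restriction phase,
which makes a common adherence scale possible across arms whose absolute
intakes differ by hundreds of grams. For participant *i* at
post-randomization month *t* ∈ {3, 6, 12}:

1. average the reported restricted-macronutrient grams over the available
   24-h recall days (1–3 per visit): *ḡ_it*;
2. deviation *d_it* = 20 − *ḡ_it* (signed; intake below 20 g gives a
   positive deviation — no capping);
3. deviation score DS_it = *d_it* / *w_i0*, with *w_i0* baseline weight in
   kg, so the same absolute overshoot counts for more in a lighter person;
4. z-score DS within each diet × month stratum, pooling sexes
   (z_it = (DS_it − mean)/SD); pooling sexes is what makes the cross-sex
   comparisons of adherence meaningful;
5. WASA_i = mean of the available z_it.

Conventions: the z-score denominator is the sample SD (n − 1) by default,
switchable to the population SD; baseline (month 0) recalls never enter;
a stratum with fewer than two scores or zero spread cannot be normalized
and its z-scores are set missing with a logged warning; a participant with
no post-randomization recalls has no WASA and is excluded from adherence
analyses. Positive deviations (intake below target) are taken literally as
super-adherence rather than capped at zero — the score's defining formula
has no cap, and capping would discard information about the most adherent
tail.

## Longitudinal outcome models

For each measure (weight; DEXA fat mass; DEXA lean mass) the response is
the change from baseline in kg at the post-baseline months (3/6/12 for
weight, 6/12 for DEXA measures):

    change_it = group + month + group×month + β₁·weight_i0 + β₂·bodyfat_i0
                + u_i + e_it,
    u_i ~ N(0, σ²_subject),   e_it ~ N(0, σ²_residual).

Month is categorical (no functional time trend is assumed). Modeling the
change with both baseline covariates reproduces "12-month changes adjusted
for baseline weight and baseline body-fat percentage" directly; covariates
are mean-centered for conditioning (contrasts are unaffected). Because all
available visits enter, estimates are valid when post-baseline missingness
is at random given arm, sex and observed data.

Estimation is REML, profiled over λ = σ²_subject/σ²_residual: for fixed λ
the fixed effects and σ²_residual have closed forms, so the fit is a
bounded one-dimensional search on log λ (tolerance 1e-10, bounds e∓14,
with an explicit λ = 0 boundary check). The fitter is validated in the
test suite against a dense-matrix GLS oracle, against statsmodels MixedLM,
and (during development) against R lme4/lmerTest.

Degenerate inputs: if the within-subject residual variance is numerically
zero the restricted likelihood is unbounded in λ; the fitter detects the
boundary and rescales the limiting estimate so that σ²_subject equals the
between-subject residual mean square with its proper n_subjects − p
denominator (for the toy case of constant-within-subject responses this is
exactly the between-subject variance of the subject means). A design made
rank-deficient by a constant covariate drops the covariate with a warning.

### Satterthwaite degrees of freedom

For a contrast c the denominator df is

    df = 2 [c' V̂_β c]² / Var̂[c' V̂_β(θ̂) c],

with the denominator by the delta method: the gradient of c'V_β(θ)c with
respect to θ = (σ²_subject, σ²_residual) (central differences), propagated
through the asymptotic covariance of θ̂, itself the inverse of the observed
REML information (numerically differentiated). df is capped at the residual
df n − p, which is also the exact limit when σ²_subject = 0. Components
estimated on the boundary are held fixed (zero rows in the covariance);
when no component is free the residual df is used.

Multi-row hypotheses Lβ = 0 (the rank-3 equality of the four groups'
adjusted month-12 changes) use F = (Lβ̂)'(LV̂_βL')⁻¹(Lβ̂)/q and combine
per-eigencontrast Satterthwaite dfs ν_m of the eigen-decomposition of
LV̂_βL' into a single denominator df via E = Σ_{ν_m>2} ν_m/(ν_m − 2),
df₂ = 2E/(E − q) — the same construction lmerTest uses. emmeans's joint
test combines slightly differently; on trial-size data both give df₂ in
the hundreds and indistinguishable p-values.

Pairwise comparisons of interest (HLC−HLF within women; HLC−HLF within
men; men−women within HLC; men−women within HLF) are reported with
Satterthwaite t-tests, 95% CIs, and no multiplicity adjustment.
Kenward-Roger df (sometimes preferred for pairwise contrasts) is not
implemented: it needs a bias-adjusted small-sample covariance, and for
random-intercept models at several hundred subjects the two adjustments
are numerically indistinguishable; Satterthwaite is used throughout.

Analysis sets: because baseline body-fat % is a covariate, the default
weight model is a complete-case analysis restricted to participants with a
baseline DEXA measurement (`analysis_set="dexa"`). The alternative
`analysis_set="all"` mean-imputes baseline body fat so every weighed
participant contributes; neither option is claimed to be canonical, and
the flag makes the choice explicit.

## Adherence regression, correlations, mediation

Hypothesis "adherence differs by diet-sex group" is ordinary least squares
of WASA on the 4-level group factor: omnibus F on (k − 1, n − k) df and
the four pairwise t contrasts with pooled variance, unadjusted for
multiplicity. Adherence–outcome association is the Spearman rank
correlation (average ranks for ties; p by the t approximation, with an
exact permutation p behind a flag for n ≤ 10) between WASA and the
observed 12-month percent change 100·(v₁₂ − v₀)/v₀, within each group.
Mediation is assessed descriptively, not by a formal indirect-effect
estimand: the mixed model is refit with WASA as an extra fixed effect on
exactly the same participants (those with a WASA score), and the pairwise
contrasts are compared side by side; if group differences operate through
adherence the adjusted contrasts shrink toward zero.

## Descriptive tests

Kruskal-Wallis (tie-corrected, χ² reference on k − 1 df; scipy's
implementation behind the module surface) for continuous variables;
Dunn's rank-based pairwise z-tests with the tie term
Σ(t³ − t)/(12(N − 1)), Bonferroni-multiplied p capped at 1, and
shared-letter codes for significant pairs; Fisher's exact test generalized
to r × c tables by the Freeman-Halton rule (two-sided p = total
probability of margin-fixed tables no more probable than the observed one,
with a 1e-10 log-probability tolerance against float round-off). Tables
are enumerated exactly while a cheap product bound on the number of
margin-fixed tables stays below 10⁷; beyond that the p-value is estimated
by ≥10⁵ margin-preserving Monte-Carlo tables (Patefield sampling) and
reported with its binomial standard error. Zero-margin rows/columns are
dropped; on 2 × 2 tables the rule reproduces the classical two-sided
hypergeometric p to 1e-12 (tested against scipy). Displayed percentages
use all randomized participants as the denominator with missing responses
kept as their own category.

## The synthetic cohort generator

No individual-level data from any real trial ship with the package; the
generator produces cohorts with the structure the analysis assumes, so
every stage is testable end to end. Defaults describe a 609-participant
trial: cells HLC-women 179, HLC-men 125, HLF-women 167, HLF-men 138;
baseline weight ~N(89.8, 12²) kg for women and N(106.2, 13.8²) for men;
baseline body fat ~N(40.7, 4²)% and N(30.1, 4.6²)%.

Outcome model per measure:

    value(t) = baseline + f(t)·(Δ_group + γ·a_i) + b_i + ε_it,

with f(0) = 0, f(3) = 0.6, f(6) = 0.85, f(12) = 1 (rapid early loss, the
typical kinetics of diet interventions; configurable), a_i ~ N(0, 1) the
latent adherence trait, γ the adherence effect (−2 kg/SD on weight by
default, split 70/30 between fat and lean mass), b_i ~ N(0, 3²) a subject
intercept and ε ~ N(0, 2.5²) visit noise for weight (DEXA noise scaled to
0.5/0.4 of the weight SDs — DEXA repeatability is better than day-to-day
weight fluctuation). Default group means Δ imply the pairwise differences
the analysis is meant to detect: men HLC−HLF = −2.98 kg weight, −1.51 kg
fat, −1.33 kg lean; HLC men−women = −2.32 kg weight, −1.42 kg lean; null
differences among women and within HLF. Baseline fat mass is
weight × bodyfat%, lean mass is 85% of the fat-free remainder (the rest,
bone mineral and residual mass, keeps fat + lean strictly below weight; a
rare-tail clamp enforces the inequality against independent visit noise).

Reported restricted-macronutrient intake at post-baseline visits is
20 + softplus(80 − 25·a_i + N(0, 30²)) grams — a smooth floor at the 20 g
target that few participants reach, monotone decreasing in the latent
trait so the WASA score can recover it (Spearman ρ ≈ 0.8 against a_i at
default settings). Baseline intake and the unrestricted macronutrients are
drawn at trial-typical moments; energy is the 4/9/4 kcal/g combination
plus reporting noise.

Missingness: each post-baseline visit is attended independently with
probability 0.79 (visit-wise missing at random; recalls are tied to
attendance, with 1–3 recall days per attended visit), and the
earliest-enrolled 12.8% of participants lack all DEXA records including
baseline body fat, mimicking staggered availability of the scanner. A
single master seed drives independent substreams for participants,
outcomes, recalls and attendance, so any component can be regenerated
alone; the latent trait is never written to analysis-facing files.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: reported intake is independent of body
size, so the weight normalization in DS mechanically makes heavier
participants (men) score as more adherent within a diet stratum; the
synthetic adherence-by-group F is therefore larger than a real trial's.
There is no under-reporting of intake, no energy-intake trend over months,
no informative (outcome-dependent) dropout, no within-person tracking of
intake beyond the constant latent trait, and subject/residual variances
are chosen (not estimated from any trial, which would require the raw
repeated-measures data). Within-person correlation of repeated weights is
whatever the random-intercept-plus-noise structure implies.

## Simulation sizes used by the test suite

Chosen as the package's own verification budget: contrast-recovery bias
and CI coverage over 200 full-size (609-participant) replicate cohorts;
omnibus type-I error over 500 null cohorts of 50 per cell; mediation
behavior over 60 replicates of 80 per cell in each regime; power over 20
full-size cohorts with a 6 kg group spread. The acceptance script averages
the headline contrast over 50 replicate cohorts.

## Known limitations

The fitter supports exactly one random intercept (no random slopes, no
crossed effects); mediation is descriptive (no ACME/ADE decomposition or
bootstrap); the Monte-Carlo Fisher p is an estimate with reported standard
error, not an exact value; WASA has no correction for energy intake or
under-reporting; and the exact permutation Spearman p is practical only
for very small groups.
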