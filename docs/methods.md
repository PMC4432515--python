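# Methods

## Model overview

`confsim` simulates observational cohort studies of a hypothetical ICU
treatment whose only causal pathway to mortality is a constant odds ratio
(OR) applied to each treated patient's baseline risk of death. Confounding
by indication is induced by making the probability of treatment increase
with baseline risk; the analyst's defence is a logistic regression adjusting
for a noisy severity score. The framework's outputs are operating
characteristics of that study design — false-harm rates, false-negative
rates, and the distribution of measured ORs — across a grid of sample size,
true OR, confounding strength, and adjuster accuracy.

Assumptions worth making explicit:

* risk is the *only* patient attribute; there are no covariates, no
  treatment-effect heterogeneity, and no calibration error in the adjuster —
  only discrimination error;
* treatment assignment and outcome are conditionally independent given true
  risk, so a perfect adjuster (σ = 0) recovers the true conditional OR;
* each replicate is an independent study: cohorts are iid draws, which is
  distributionally equivalent to sampling with replacement from an
  arbitrarily large source cohort.

## Baseline-risk population

The unimodal population is pinned down by three printed quantile anchors:
10th percentile 0.15, median 0.35, 90th percentile 0.75. `fit_unimodal`
first tries the minimal family, a two-parameter Beta, by least squares on
the anchor quantiles. The best Beta(1.509, 2.202) achieves (0.115, 0.388,
0.728) — every anchor missed by more than the ±0.02 tolerance — so the
fitter escalates to a three-parameter logit-scale skew family:
risk = expit(X), X ~ skew-normal(shape 3.8225, loc −1.8118, scale 1.7694),
which reproduces all three anchors to machine precision. The achieved
quantiles are recorded on the model for audit.

The fitted population's **intrinsic AUROC** — the concordance of true risk
against Bernoulli(risk) outcomes, i.e. the best any risk adjuster built from
true risk can do — is ≈ 0.760 (Monte Carlo, n = 2·10⁵). This ceiling is a
property of the reconstruction, not a tunable: only three quantiles of the
original cohort's distribution are known, and tail mass beyond them moves
the ceiling. Adjuster-accuracy targets are therefore capped at the ceiling;
a grid point at 0.80 would be infeasible for this population and is not part
of the default grid.

The bimodal sensitivity population models a cohort whose outcomes clinicians
can largely foresee: a two-component Beta mixture with component means 0.10
(85% of patients) and 0.80 (15%) and a shared concentration κ; component j
is Beta(μ_j κ, (1−μ_j) κ). As κ → ∞ the components collapse to point masses
and the intrinsic AUROC falls to ≈ 0.77; as κ → 0 it rises toward 1. κ is
bisected (common random numbers) until the intrinsic AUROC hits the target
0.85 ± 0.01, the discrimination reported for clinician predictions of
mortality. The mixture weights and modes are fixed defaults; only the
separation is calibrated.

An empirical population (a user-supplied CSV column of risks, resampled with
replacement) is supported for users who have their own cohort.

## Risk adjuster

The severity score is logit(risk) plus iid Gaussian noise with standard
deviation σ. Noise lives on the log-odds scale so the score stays unbounded
and enters the analysis regression as a single linear term — the scale on
which the true outcome model is itself linear, so σ = 0 makes the analysis
model correctly specified and σ > 0 is classical covariate measurement
error. (Probability-scale noise was evaluated during development and
produced nearly identical operating characteristics; the logit scale was
kept for its cleaner limiting behaviour.)

`calibrate_sigma` maps a target AUROC to σ by bisection on the mean
in-sample AUROC over replicate cohorts (default 20–48 replicates, tolerance
0.005). The same replicate seeds are reused at every σ tried (common random
numbers), making the objective a smooth decreasing function of σ so the
bisection is stable; the achieved mean and sd are then re-estimated with
fresh replicates and stored. Calibration simulates untreated cohorts (null
outcome process); each study replicate additionally records its own realized
in-sample AUROC, so results can be re-binned by realized accuracy if
desired. Targets above the intrinsic ceiling raise an error naming the
ceiling; targets within tolerance of the ceiling return σ = 0.

## Confounding scenarios

Treatment probability follows a logistic curve in logit(risk),
logit P(T=1) = a + b·logit(risk), with (a, b) solved exactly from two
anchors. Built-ins: low (0.15 → 30%, 0.75 → 60%; slope 0.442) and high
(0.15 → 15%, 0.75 → 85%; slope 1.224); "none" is a constant marginal rate,
default 0.45 (the midpoint of the low anchors, keeping the treated fraction
comparable across scenarios). The functional form between and beyond the
anchors is a design choice: the logistic link is smooth, monotone, and
exactly identified by two anchors. Clamped and linear-in-risk alternatives
were evaluated during development; they weaken tail confounding enough that
the low-confounding mean-OR crossing disappears, and were rejected. Custom
anchors (including inverse confounding, treating the healthier more often)
are supported through `calibrate_scenario`.

## Study replicate and analysis

Per replicate: draw the cohort → build the severity score → assign treatment
→ apply the true OR to treated risks (p′ = OR·p/(1−p+OR·p)) → draw deaths →
fit `death ~ treatment + score` (or `death ~ treatment` unadjusted) by
maximum likelihood (statsmodels Logit) → record exp(β_T), its two-sided Wald
p-value, and the conclusion (harm / benefit / null at α = 0.05). Replicates
with a single-class death vector, perfect separation, a non-converged fit,
or an unbounded estimate (|β| > 30) are labelled *degenerate*, counted, and
excluded from OR averages — never silently dropped. Against the truth,
conclusions classify as true_benefit / false_negative / false_harm (true
OR < 1) or true_null / false_benefit / false_harm (true OR = 1).

Randomness: one root seed; every (cell, replicate) gets an independent
`SeedSequence(root, spawn_key=…)` substream, so any replicate is
reproducible in isolation and subset runs match full runs exactly.

## Aggregation

Rates are simple proportions over non-degenerate replicates. The "average
measured OR" is the arithmetic mean of the ORs (the geometric mean — the
natural average on the log-odds scale — is reported alongside). Percentiles
(median, IQR, 2.5th/97.5th) use linear interpolation between order
statistics. The crossing AUROC — where residual confounding exactly cancels
a beneficial effect — is found by linear interpolation of mean OR against
target AUROC on the first segment bracketing 1.0; a curve that never
brackets 1.0 yields a NaN sentinel.

## Problem sizes and tolerances

Headline quantities are recomputed at desk scale: 200 replicates per grid
cell (500–2000 for the null type-I-error and interval-estimate cells, whose
checks are tighter), sample sizes 1,000 and 10,000 as in the study design,
AUROC grid {0.56, 0.60, 0.64, 0.66, 0.70, 0.72, 0.76} plus the intrinsic
ceiling. At 200 replicates the Monte Carlo standard error of a cell's mean
OR at n = 10,000 is below 0.01, and of a rate at most ±3.5 pp.

## What the generator does and does not emulate

The synthetic population reproduces the printed quantile anchors but not the
unpublished tail shape of the original cohort's risk distribution, and the
adjuster noise model is a stated reconstruction, not the original code. Two
headline numbers are sensitive to exactly those unknowns and deviate
consistently: unadjusted mean measured ORs under high confounding run
≈ 0.1–0.2 higher than reported (≈ 1.77 vs 1.6 at true OR 0.6; ≈ 2.21 vs 2.0
at 0.8), and the false-harm rate at AUROC 0.70, n = 1,000 under *low*
confounding runs ≈ 0.33 vs ≈ 0.5 reported. Both discrepancies move in
opposite directions with any tail-mass adjustment (a heavier-tailed
population raises the intrinsic ceiling and the low-confounding false-harm
rate, but inflates the unadjusted bias further), so no anchor-consistent
population removes both; the values are reported as computed. Everything
else — the risk-shift arithmetic, anchor calibrations, type-I-error rate,
all four mean-OR crossing AUROCs, interval estimates, the protective-AUROC
property at 0.76, the monotone structure of false-harm rates in accuracy,
confounding and sample size, and the bimodal population's higher protective
threshold — reproduces within the stated tolerances. Passing tests
demonstrate the *mechanism* at the stated study conditions, not the exact
operating characteristics of any real cohort.

## Known limitations

* No adjuster miscalibration, propensity-score or matching estimators, or
  covariate-level patient simulation — out of scope by design.
* The odds ratio's non-collapsibility means even the unconfounded unadjusted
  mean OR sits slightly nearer 1 than the conditional true OR (e.g. ≈ 0.67
  for true 0.6); this is a property of the estimand, not a bug.
* Single-machine execution; cells run sequentially.
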