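# confsim

Monte Carlo simulation of **confounding by severity of illness** in
observational critical-care studies.

In the ICU, clinicians tend to give aggressive treatments to sicker patients.
An observational study comparing treated with untreated patients therefore
mixes the treatment's real effect on mortality with the fact that the treated
group was sicker to begin with — confounding by indication. The standard
remedy is to adjust for a severity-of-illness score, but real risk adjusters
are imperfect: their discrimination (AUROC) is often 0.6–0.8 in the
population actually studied. `confsim` quantifies what that imperfection
costs: how often a study of a safe treatment (true odds ratio for mortality
OR = 1.0) falsely concludes the treatment is *harmful*, how often a study of
a beneficial treatment (OR = 0.6 or 0.8) concludes it does nothing or causes
harm, and how large the spurious effect sizes can be.

## The simulation model

Each simulated study draws `n` patients from a population of baseline risks
of death `p_i ∈ (0, 1)` (default: a right-skewed distribution with 10th/50th/
90th percentiles at 15% / 35% / 75%, emulating non-surgical mechanically
ventilated patients). The investigator's risk adjuster is a noisy severity
score

    s_i = logit(p_i) + e_i,   e_i ~ N(0, σ²),

with σ calibrated by bisection so that the mean in-sample AUROC of `s`
against death hits a target (0.56 … the population's intrinsic ceiling,
≈ 0.76 here). Treatment is assigned by a Bernoulli draw with probability

    logit P(T_i = 1) = a + b · logit(p_i),

where (a, b) are solved exactly from two anchor points: *low* confounding
treats 15%-risk patients 30% of the time and 75%-risk patients 60% of the
time; *high* confounding uses 15% → 15% and 75% → 85%. A truly beneficial
treatment multiplies the odds of death of treated patients by the true OR:
p′ = OR·p / (1 − p + OR·p). Deaths are Bernoulli(p′ or p); the study then
fits the logistic regression

    logit P(death) = β₀ + β_T · T + β_S · s

(or omits `s` for an unadjusted analysis) and "concludes" harm, benefit, or
no effect from the Wald test on `exp(β_T)` at α = 0.05. Replicating each
study hundreds of times per parameter cell yields false-harm and
false-negative rates and the distribution of measured ORs.

## Worked example

```python
import confsim

pop = confsim.fit_unimodal()              # risk distribution from the anchors
high = confsim.ConfoundingScenario.high() # sickest ~5x as likely treated
adj = confsim.calibrate_sigma(pop, target_auroc=0.70, n=10_000, seed=0)

cfg = confsim.SimulationConfig(
    population=pop, scenario=high, true_or=1.0, n=10_000,
    adjuster_sigma=adj.sigma, target_auroc=0.70, reps=200, seed=0,
)
cell = confsim.summarize_cell(
    confsim.run_cell(cfg), true_or=1.0, n=10_000, scenario="high", target_auroc=0.70,
)
print(f"sigma = {adj.sigma:.3f}  (achieved AUROC {adj.achieved_auroc_mean:.3f})")
print(f"false-harm rate = {cell.false_harm_rate:.2f}")
print(f"mean measured OR = {cell.mean_or:.2f}  95% interval "
      f"({cell.interval_95[0]:.2f}, {cell.interval_95[1]:.2f})")
```

prints

```
sigma = 0.952  (achieved AUROC 0.699)
false-harm rate = 1.00
mean measured OR = 1.68  95% interval (1.55, 1.84)
```

— a *safe* treatment, studied 200 times at n = 10,000 with an AUROC-0.70
adjuster under high confounding, is declared significantly harmful in every
single study, with a typical measured OR of 1.7: residual confounding alone
produces an effect size large enough to be read as clinically meaningful.
Dropping `adjuster_sigma` to `0.0` (a perfect adjuster) brings the
false-harm rate back to the nominal α.

The same machinery is exposed on the command line:

```bash
confsim calibrate --targets 0.60,0.70,0.76 --out calibration.csv
confsim simulate --out run/ --reps 200 --seed 1     # full grid + manifest
confsim summarize --runs run/ --out summary.csv
confsim reproduce-headline --reps 200 --seed 1
```

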