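# Methods

This note documents the models implemented in `vhd_aging`, the choices
made where the design was genuinely open, what the synthetic data do and
do not emulate, and the numerical conventions that affect results.

## Biological-age clocks

**KDM-BA.** Each biomarker is regressed on chronological age (CA) by
ordinary least squares within a sex stratum of the reference
population; `q`, `k` are the intercept and slope and `s` is the
regression standard error `sqrt(SS_res/(n−2))`. Scoring uses the
precision-weighted ratio

    BA = [ Σ (xᵢ−qᵢ)kᵢ/sᵢ² + CA/s_BA² ] / [ Σ (kᵢ/sᵢ)² + 1/s_BA² ].

The scaling factor `s_BA` (years) controls how strongly CA anchors the
estimate; `s_BA → ∞` recovers the biomarker-only estimator. The default
estimator (`s_ba_mode="explained_variance"`) sets `s_BA²` to the
variance of CA multiplied by the R² of the multivariate biomarker → age
regression — i.e. literally "the variance in chronological age explained
by the biomarker panel". The classical alternative
(`s_ba_mode="kdm_correction"`) derives `s_BA²` from the spread of the
biomarker-only age estimate around CA minus a noise-floor correction
based on the characteristic biomarker–age correlation; the mode is
recorded in the serialized parameters so scores are always attributable
to an estimator. Training requires ≥ 30 rows per stratum and rejects
degenerate biomarkers (zero variance, |slope| < 1e−10, or an exact fit).

**PhenoAge.** The published coefficients are hard-coded
(`PhenoAgeModel`): a linear predictor `xb` over albumin (g/L),
creatinine (µmol/L), glucose (mmol/L), ln CRP (mg/dL), lymphocyte %,
MCV (fL), RDW (%), ALP (U/L), WBC (10³/µL) and CA (years) is converted
to a 120-month Gompertz mortality risk (shape γ = 0.0076927) and then
to the age at which the age-only Gompertz model gives the same risk:

    PhenoAge = 141.50225 + ln(−0.00553 · ln(1 − risk)) / 0.090165.

Because `−ln(1 − risk)` equals the cumulative hazard
`exp(xb)·(exp(120γ)−1)/γ` algebraically, the implementation evaluates
that form directly; the naive `1 − risk` round trip loses all precision
once risk exceeds ~1 − 1e−16 (the map's fixed point at 141.50225 lives
in that region). The map is strictly increasing in `xb`, hence in every
positively weighted biomarker. Units are validated by convention, not
converted implicitly: the coefficients are unit-bound.

**BAA.** Biological age acceleration is the residual of OLS BA ~ CA on
the *analytic* cohort (i.e. after exclusions, the default order;
scoring before exclusions is available by simply scoring the full
cohort first). The regression is pooled across sexes by default.
Residuals are standardized with the sample SD (ddof = 1) and cut at
linear-interpolation sample quartiles; a value equal to a boundary goes
to the lower quartile, making Q1 = (−∞, q25] the reference group.

## Synthetic cohorts

The generator is the package's study-conditions definition, not a
fitting target. One latent aging factor `z ~ N(0,1)` (scaled by
`latent_aging_sd` = 5 years where year units are needed) drives both the
biomarker panel and all event hazards, so the true exposure is known per
participant (`latent_z` column). Biomarkers are
`q*(sex) + k*(sex)·age + λ·z + N(0, σ)`, with CRP generated on the log
scale (strictly positive, right-skewed) and lymphocyte % clipped to
[1, 99]. Intercepts and slopes give plausible mid-life means; loadings
share the sign of each biomarker's mortality association, so higher `z`
means an older-looking panel on both clocks.

Cohorts add covariates at roughly the prevalences of a large UK
middle-aged cohort (46.2% men, 90.8% White, 32.4% college-educated,
smoking 54.7/34.7/10.6%, etc.). Confounding is built in: current
smoking shifts the latent factor by +0.35 SD and deprivation by
+0.12 SD per SD, and both also enter the hazards directly. Six valvular
outcomes get independent cause-specific Weibull hazards (shape 1.25–1.3,
log-HRs: 0.3 per SD latent, 0.09/year age, 0.45 male, 0.15 per smoking
level, 0.05 per deprivation SD) inverted in closed form; competing
non-VHD death is Gompertz (`a·e^{bt}`, a = 2.2e−3, b = 0.045) with age,
sex and latent effects; censoring is administrative (uniform over a
4-year entry window centered 13.9 years before close-out) plus a small
exponential dropout (rate 0.004/yr). Weibull scales were calibrated
once so the default cohort reproduces the study-scale crude rates
(AS ≈ 8.4, AR ≈ 3.0, MR ≈ 9.0, composite events ≈ 3.2/0.45/0.93 per
10,000 person-years) and the median follow-up lands near 13.9 years.

What the generator does **not** emulate: realistic marginal shapes for
every covariate, correlation among comorbidities, informative dropout,
time-varying biomarkers, or any dependence between a valve outcome and
its composite intervention/death outcome (they are drawn as separate
processes). Passing tests therefore demonstrate estimator correctness
under a known proportional-hazards data-generating process, not
robustness to real-data pathologies.

Because hazards are driven by the latent factor while the analysis
measures clock-derived BAA (correlation ≈ 0.6 with the latent factor at
the default noise levels), quartile hazard ratios estimated from
measured BAA are attenuated relative to the true 0.3/SD — deliberately,
since the same attenuation operates in real clock studies. Recovery
tests of the 0.3/SD effect therefore regress on `latent_z` itself.

## Survival modelling

* **Cox models** use lifelines (Efron ties, Newton precision 1e−9).
  Quartile exposures expand to indicators with Q1 as reference; CIs are
  `exp(β ± 1.96·se)`.
* **Schoenfeld diagnostics** use the lifelines score test with the
  Kaplan–Meier time transform (default); the global statistic sums the
  per-term chi-squares.
* **Fine–Gray** is implemented in-package. Subjects failing from the
  competing cause stay in later risk sets with weight
  `G(t−)/G(Tᵢ−)` from the pooled (not covariate-adjusted)
  left-continuous Kaplan–Meier estimator of censoring, floored at
  1e−8. The weighted Breslow partial likelihood is maximized by Newton
  with step-halving (analytic gradient and Hessian via prefix/suffix
  cumulative sums, O(n·p²)). With no competing events it reduces
  exactly to Breslow Cox. The reported variance is the inverse observed
  information; the censoring-weight estimation term of the full
  sandwich is not propagated, so SEs can differ by a few percent from
  sandwich implementations while coefficients agree to ~1e−7. The
  baseline cumulative incidence uses the product-limit form
  `1 − Π(1 − dĤ)`, which matches the Aalen–Johansen estimator on null
  covariates to < 1e−3.
* **Restricted cubic splines** use the truncated-power natural-spline
  basis normalized by `(t_k − t_1)²`, linear beyond the boundary knots,
  with knots at Harrell's symmetric quantiles for k = 3…7. The knot
  count minimizes the partial-likelihood AIC; the hazard-ratio curve is
  anchored to 1 at the cohort median exposure; the non-linearity
  p-value is a Wald test that all nonlinear coefficients vanish. Note
  the p-value is reported for the AIC-selected model; under a truly
  linear effect selection favors 3 knots, and the fixed-3-knot test is
  calibrated (type-I error ≈ 5%).
* **Adjusted cumulative curves** refit the Cox model on the attained-age
  timescale with left truncation at entry age and average the implied
  survival over the observed covariate distribution per exposure group
  (g-computation), conditioning on survival to the first grid age.

## Incidence rates

Crude rates are per 10,000 person-years with exact Poisson (chi-square
inversion) intervals. Adjusted rates fit a Poisson GLM with a log
person-time offset (exposure strata + covariates, no interactions) and
standardize by predicting each participant's rate under every stratum
and averaging unweighted over participants; with no covariates this
collapses to the crude rate exactly (up to IRLS tolerance, ~1e−9).
Whether the study derived its "estimated marginal means" from a Poisson
or a Cox scale is not stated; Poisson was chosen and is flagged here.
Differences and ratios versus Q1 take percentile CIs from the same
participant-level bootstrap replicates (default 1,000, seeded), so the
three quantities are mutually consistent. Event percentages round
half-up to 2 decimals; the Bonferroni threshold is α/m at 4 decimals.

## Absolute risks

Case-base sampling draws `base_ratio × cases` person-moments uniformly
over observed person-time. The logistic model with offset
`log(total person-time / base size)` then estimates the log hazard
directly; the default time term is `log(t)` (Weibull-like), with linear
and spline-in-time alternatives. The event of interest and competing
death are fitted as two cause-specific hazard models against their own
base series (equivalent to the multinomial formulation for distinct
causes, and better-conditioned at these event counts). Absolute risk

    risk(t) = ∫₀ᵗ h_event(u) · exp(−H_event(u) − H_death(u)) du

is integrated by an adaptive high-order Runge–Kutta system in
(H, risk) with rtol 1e−9 — orders of magnitude inside the 1e−6
reporting tolerance; closed-form exponential and competing-exponential
cases are reproduced to 1e−6 and large-base-ratio risks match
Aalen–Johansen within 0.01. The published-style risk table uses sex ×
age band (40–50, 50–60, 60–70) × BAA group (<25th, 25th–75th, >75th
full-cohort percentiles), evaluating each stratum at the age-band
midpoint and the group's indicator profile, with any extra covariates
held at supplied modal values.

## Pipeline and scale choices

`run_pipeline` sequences simulate/ingest → exclusions (three analytic
cohorts: full; minus cardiovascular comorbidity; additionally minus
follow-up < 2 years) → clock training/scoring → per-outcome models and
tables, stamping every output with the config hash and seed; identical
configs produce byte-identical files. Regression tables adjust for
baseline age on top of the Model-1/Model-2 covariate sets, since the
follow-up timescale does not absorb age. The default problem sizes —
20,000 participants, 10,000-row reference, 200–1,000 bootstrap
replicates, base ratio 50–100 — are the package's chosen desk-scale
study conditions: large enough that every estimator is comfortably
identified (≈ 230–260 events per outcome), small enough to iterate on.
The published cohort size (408,783) is reachable through
`SimulationConfig` but is not required by any test.

## Known limitations

* Fine–Gray SEs are model-based (see above); p-values for
  subdistribution HRs are correspondingly approximate.
* The composite "-related event" outcomes are simulated independently
  of their parent diagnoses, so joint analyses of diagnosis + event are
  outside the generator's fidelity.
* Single-imputation-free: the exclusion stage models missingness only
  as row flags; no imputation machinery is provided.
* The spline non-linearity p-value after AIC selection is
  post-selection and slightly anti-conservative; the fixed-knot test is
  the calibrated one.
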