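# vhd-aging

Biological-age clocks and the epidemiology of degenerative valvular
heart disease (VHD), as a tested, reusable Python pipeline.

Aging drives aortic stenosis (AS), aortic regurgitation (AR) and mitral
regurgitation (MR), but people of the same chronological age (CA) age
physiologically at different speeds. This package implements the full
analysis chain used to ask whether *biological age acceleration* (BAA)
predicts incident degenerative VHD in a large prospective cohort, and it
ships a seeded synthetic-cohort generator with known ground truth so
every stage can be exercised and verified without access-restricted
biobank data. It is aimed at epidemiologists and biostatisticians who
want the individual pieces (clocks, competing-risk regression, marginal
standardization, case-base absolute risks) or the assembled pipeline.

## What it computes

**Clocks.** The Klemera–Doubal biological age combines per-biomarker
regressions of biomarker *x<sub>i</sub>* on CA (intercept *q<sub>i</sub>*,
slope *k<sub>i</sub>*, RMSE *s<sub>i</sub>*) trained on a reference
population:

```
KDM-BA = [ Σᵢ (xᵢ − qᵢ) kᵢ/sᵢ² + CA/s_BA² ] / [ Σᵢ (kᵢ/sᵢ)² + 1/s_BA² ]
```

PhenoAge maps a fixed linear predictor *xb* over nine blood chemistries
plus CA through a Gompertz mortality model,

```
risk     = 1 − exp(−exp(xb)·(exp(120γ) − 1)/γ),         γ = 0.0076927
PhenoAge = 141.50225 + ln(−0.00553·ln(1 − risk)) / 0.090165
```

BAA is the residual of BA regressed on CA (orthogonal to CA by
construction), standardized to mean 0 / SD 1 and cut at quartiles.

**Models.** Cox proportional hazards (lifelines, Efron ties) with
Schoenfeld diagnostics; a Fine–Gray subdistribution-hazard model for
competing death (authored here: pooled Kaplan–Meier censoring weights,
Breslow ties, Newton–Raphson; coefficients validated against an exact
brute-force likelihood maximizer); restricted-cubic-spline dose–response
with the knot count (3–7) chosen by minimum AIC and the hazard ratio
anchored at the median exposure; crude rates per 10,000 person-years
with exact Poisson intervals; marginally standardized (g-computation)
rates, differences and ratios with participant-bootstrap intervals;
and 5-/10-year absolute risks from case-base sampling with smooth
parametric hazards and competing death.

## Worked example

```python
from vhd_aging import clocks, survival_models as sv, synthetic_cohort as sc

cfg = sc.SimulationConfig(n_participants=20_000, seed=42)
cohort, events = sc.simulate_cohort(cfg)
reference = sc.simulate_reference_population(
    sc.SimulationConfig(n_participants=10_000, seed=43, age_range=(30.0, 75.0)))
params = {s: clocks.fit_kdm_parameters(reference, sex_stratum=s)
          for s in ("male", "female")}
scored = clocks.score_cohort(cohort, kdm_params=params)

d = sc.event_table_for_outcome(scored, events, "MR")
d["event"] = (d["status"] == 1).astype(int)
print(sv.quartile_hr_table(
    d, "phenoage_quartile",
    sv.MODEL1_COVARIATES + ("chronological_age",)).round(3))
```

prints

```
  stratum     hr  hr_lower  hr_upper      p
0      Q1  1.000       NaN       NaN    NaN
1      Q2  1.308     0.845     2.025  0.228
2      Q3  1.870     1.240     2.822  0.003
3      Q4  1.724     1.132     2.626  0.011
```

the adjusted hazard-ratio column of a quartile dose–response table:
mitral-regurgitation hazard rises across PhenoAge-acceleration
quartiles (the generator's true effect is 0.3 log-HR per SD of the
latent aging factor; single-cohort quartile estimates carry the
sampling noise of ~240 events).

The same objects feed `incidence_rates.rate_table` (crude + adjusted
rates), `survival_models.fit_dose_response` (spline curves and
P-non-linear), `survival_models.fit_fine_gray` (competing-risk HRs) and
`absolute_risk.absolute_risk_table` (5-/10-year risks by sex, age band
and BAA group). `vhd-pipeline run --seed 1 --n 20000 --outcomes AS`
runs every stage and writes stamped CSV tables.

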