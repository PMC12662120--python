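"""Seeded synthetic reference populations and biobank-style cohorts.

The generator emulates the statistical structure of a large prospective
biobank study of degenerative valvular heart disease (VHD):

* a shared latent aging factor drives both the biomarker panel and the
  cause-specific event hazards, so the *true* biological age
  acceleration is a known simulated exposure;
* biomarkers follow sex-specific linear age trends plus latent-factor
  loading plus Gaussian noise (C-reactive protein is generated on the
  log scale and exponentiated, keeping it strictly positive and
  right-skewed);
* six valvular outcomes — incident aortic stenosis (AS), aortic
  regurgitation (AR), mitral regurgitation (MR) and the corresponding
  composite intervention-or-death events — are drawn from Weibull
  proportional-hazards models by inverse transform, with an independent
  Gompertz non-VHD death process as the competing event and
  administrative censoring targeting a ~13.9-year median follow-up;
* baseline covariates (sex, ethnicity, education, smoking, alcohol,
  physical activity, area deprivation, comorbidities, medications)
  confound the exposure-outcome relation: smoking and deprivation shift
  both the latent factor and the hazards.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BiomarkerSpec",
    "OutcomeSpec",
    "SimulationConfig",
    "OUTCOMES",
    "ICD10_CODES",
    "simulate_reference_population",
    "simulate_cohort",
    "event_table_for_outcome",
    "apply_exclusions",
    "EXCLUSION_CRITERIA",
]

#: Outcome labels; the ``*_event`` outcomes are the composite
#: valve-intervention-or-death secondary endpoints.
OUTCOMES = ("AS", "AR", "MR", "AS_event", "AR_event", "MR_event")

#: ICD-10 code assigned to an incident diagnosis of each valve lesion.
ICD10_CODES = {
    "AS": ("I35.0", "I35.2"),
    "AR": ("I35.1",),
    "MR": ("I34.0",),
    "AS_event": ("I35.0", "I35.2"),
    "AR_event": ("I35.1",),
    "MR_event": ("I34.0",),
}


@dataclass(frozen=True)
class BiomarkerSpec:
    """Generating model for one biomarker: sex-specific intercept and age
    slope, loading on the latent aging factor, and residual noise SD.
    ``log_scale`` generates on the natural-log scale and exponentiates."""

    q_male: float
    q_female: float
    k_male: float
    k_female: float
    loading: float
    noise_sd: float
    log_scale: bool = False


# Intercepts/slopes give plausible mid-life means in the clock's unit
# convention; loadings are per SD of the latent aging factor and share
# the sign of each biomarker's published mortality association.
DEFAULT_BIOMARKERS = {
    "albumin": BiomarkerSpec(48.0, 47.5, -0.055, -0.050, -0.9, 2.4),
    "alkaline_phosphatase": BiomarkerSpec(58.0, 52.0, 0.40, 0.55, 6.0, 18.0),
    "blood_urea_nitrogen": BiomarkerSpec(3.6, 3.3, 0.033, 0.031, 0.25, 1.0),
    "creatinine": BiomarkerSpec(74.0, 59.0, 0.16, 0.13, 3.0, 9.0),
    "c_reactive_protein": BiomarkerSpec(-2.1, -2.0, 0.012, 0.011, 0.28, 0.95, log_scale=True),
    "hba1c": BiomarkerSpec(4.85, 4.88, 0.0105, 0.0100, 0.12, 0.45),
    "total_cholesterol": BiomarkerSpec(4.95, 4.80, 0.010, 0.016, 0.10, 1.00),
    "fev1": BiomarkerSpec(5.05, 3.70, -0.031, -0.025, -0.10, 0.42),
    "systolic_bp": BiomarkerSpec(116.0, 104.0, 0.40, 0.55, 3.5, 14.5),
    "glucose": BiomarkerSpec(4.35, 4.25, 0.0125, 0.0120, 0.15, 0.75),
    "mean_cell_volume": BiomarkerSpec(88.5, 88.0, 0.045, 0.042, 0.50, 4.2),
    "red_cell_distribution_width": BiomarkerSpec(13.1, 13.0, 0.0075, 0.0070, 0.28, 0.80),
    "white_blood_cell_count": BiomarkerSpec(6.75, 6.85, 0.004, 0.004, 0.55, 1.55),
    "lymphocyte_percent": BiomarkerSpec(32.5, 33.5, -0.055, -0.050, -1.6, 6.0),
}


@dataclass(frozen=True)
class OutcomeSpec:
    """Weibull baseline hazard h0(t) = scale * shape * t^(shape-1) plus
    log-hazard-ratio effects of age (per year), male sex, smoking level
    and deprivation z-score; the latent-factor effect is configured
    globally via ``log_hr_per_sd_baa``."""

    weibull_shape: float
    weibull_scale: float
    log_hr_age: float = 0.09
    log_hr_male: float = 0.45
    log_hr_smoking: float = 0.15
    log_hr_deprivation: float = 0.05


# Scales calibrated once so the default cohort reproduces event
# frequencies of the same order as the study (AS ~1.1%, AR ~0.4%,
# MR ~1.2%, composite events rarer) over ~14 years of follow-up.
DEFAULT_OUTCOMES = {
    "AS": OutcomeSpec(1.30, 2.13e-4),
    "AR": OutcomeSpec(1.25, 8.1e-5),
    "MR": OutcomeSpec(1.25, 2.37e-4),
    "AS_event": OutcomeSpec(1.30, 7.6e-5),
    "AR_event": OutcomeSpec(1.25, 1.4e-5),
    "MR_event": OutcomeSpec(1.25, 2.4e-5),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated study.

    The defaults define the package's reference study conditions:
    baseline ages 37-73, ~46% men, a latent aging factor with a 5-year
    SD, a true exposure effect of 0.3 log-hazard-ratio per SD of the
    latent factor on every valvular outcome, and administrative
    censoring drawn uniformly over an entry window so the median
    observed follow-up lands near 13.9 years.
    """

    n_participants: int = 20_000
    seed: int = 0
    age_range: tuple = (37.0, 73.0)
    sex_fraction_male: float = 0.4617
    latent_aging_sd: float = 5.0
    biomarkers: dict = field(default_factory=lambda: dict(DEFAULT_BIOMARKERS))
    outcomes: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOMES))
    log_hr_per_sd_baa: dict = field(
        default_factory=lambda: {o: 0.3 for o in OUTCOMES}
    )
    # Gompertz non-VHD death hazard a*exp(b*t), modified by age and sex
    death_hazard_a: float = 2.2e-3
    death_hazard_b: float = 0.045
    death_log_hr_age: float = 0.085
    death_log_hr_male: float = 0.40
    death_log_hr_latent: float = 0.15
    # entry spread over a recruitment window => admin censor time varies
    admin_censor_years: float = 13.9
    entry_window_years: float = 4.0
    dropout_rate: float = 0.004
    # confounding: shifts of the latent factor mean (in SD units)
    latent_shift_current_smoker: float = 0.35
    latent_shift_deprivation: float = 0.12
    covariate_prevalences: dict = field(
        default_factory=lambda: {
            "ethnicity_white": 0.9078,
            "education_college": 0.3238,
            "smoking": (0.5471, 0.3470, 0.1059),  # never / former / current
            "alcohol": (0.0796, 0.7161, 0.2043),  # never / month-week / daily
            "physical_activity": 0.5415,
            "hypertension": 0.3421,
            "obesity": 0.0263,
            "dyslipidemia": 0.2889,
            "diabetes": 0.0626,
            "osteoporosis": 0.0208,
            "coronary_artery_disease": 0.0522,
            "heart_failure": 0.0043,
            "atrial_fibrillation": 0.0148,
            "cardiomyopathy": 0.0096,
            "chronic_kidney_disease": 0.0114,
            "antidiabetic_medication": 0.0367,
            "antithrombotic_medication": 0.1494,
        }
    )
    # flags used only by the exclusion stage
    missing_biomarker_rate: float = 0.0
    baseline_vhd_rate: float = 0.0

    def __post_init__(self):
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not (0 <= self.sex_fraction_male <= 1):
            raise ValueError("sex_fraction_male must be in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (lo, hi) with lo < hi")
        if self.latent_aging_sd <= 0:
            raise ValueError("latent_aging_sd must be positive")
        for name, spec in self.outcomes.items():
            if spec.weibull_shape <= 0 or spec.weibull_scale <= 0:
                raise ValueError(f"outcome {name!r}: Weibull parameters must be positive")
        if self.death_hazard_a <= 0:
            raise ValueError("death_hazard_a must be positive")
        for key, p in self.covariate_prevalences.items():
            probs = p if isinstance(p, tuple) else (p,)
            if any(not (0 <= x <= 1) for x in probs):
                raise ValueError(f"prevalence for {key!r} outside [0, 1]")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _draw_biomarkers(rng, spec_map, age, male, latent_z):
    cols = {}
    for name, sp in spec_map.items():
        q = np.where(male, sp.q_male, sp.q_female)
        k = np.where(male, sp.k_male, sp.k_female)
        x = q + k * age + sp.loading * latent_z + rng.normal(0.0, sp.noise_sd, len(age))
        if sp.log_scale:
            x = np.exp(x)
        if name == "lymphocyte_percent":
            x = np.clip(x, 1.0, 99.0)
        cols[name] = x
    return cols


def simulate_reference_population(config: SimulationConfig = None, **overrides) -> pd.DataFrame:
    """Simulate a clock-training reference population.

    Ages are uniform over ``config.age_range`` (pass ``age_range=(30, 75)``
    to mimic a broad survey-style reference).  Output columns: sex,
    chronological_age and the full biomarker panel.  Byte-identical
    under a fixed config.
    """
    config = (config or SimulationConfig()).with_(**overrides) if overrides else (config or SimulationConfig())
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    age = rng.uniform(*config.age_range, n)
    male = rng.random(n) < config.sex_fraction_male
    latent_z = rng.normal(0.0, 1.0, n)
    df = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "sex": np.where(male, "male", "female"),
            "chronological_age": age,
            "latent_z": latent_z,
        }
    )
    for name, col in _draw_biomarkers(rng, config.biomarkers, age, male, latent_z).items():
        df[name] = col
    return df


def _categorical(rng, n, probs, labels):
    u = rng.random(n)
    edges = np.cumsum(probs)
    idx = np.searchsorted(edges, u, side="right").clip(0, len(labels) - 1)
    return np.asarray(labels)[idx]


def _weibull_time(rng, shape, scale, loghr, n):
    # inverse transform for h(t) = scale*shape*t^(shape-1)*exp(loghr)
    u = rng.random(n)
    return (-np.log(u) / (scale * np.exp(loghr))) ** (1.0 / shape)


def _gompertz_time(rng, a, b, loghr, n):
    # H(t) = a/b (e^{bt}-1) e^{loghr}
    u = rng.random(n)
    arg = 1.0 + b * (-np.log(u)) / (a * np.exp(loghr))
    return np.log(arg) / b


def simulate_cohort(config: SimulationConfig = None, **overrides):
    """Simulate an analytic cohort and its outcome event table.

    Returns ``(cohort, events)``:

    * ``cohort`` — one row per participant with biomarkers, covariates,
      the true latent aging factor ``latent_z`` (the simulated exposure
      of record, in SD units), censoring time and death time;
    * ``events`` — long table with one terminal record per participant
      per outcome analysis: columns ``participant_id, outcome,
      icd10_code, time, status`` with status in ``{"event",
      "competing_death", "censored"}``.
    """
    config = (config or SimulationConfig()).with_(**overrides) if overrides else (config or SimulationConfig())
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    prev = config.covariate_prevalences

    age = rng.uniform(*config.age_range, n)
    male = rng.random(n) < config.sex_fraction_male
    smoking = _categorical(rng, n, prev["smoking"], ["never", "former", "current"])
    alcohol = _categorical(rng, n, prev["alcohol"], ["never", "month_to_week", "daily"])
    deprivation = rng.normal(-1.5, 3.0, n)
    deprivation_z = (deprivation + 1.5) / 3.0

    # latent aging factor, confounded by smoking and deprivation
    latent_z = (
        rng.normal(0.0, 1.0, n)
        + config.latent_shift_current_smoker * (smoking == "current")
        + config.latent_shift_deprivation * deprivation_z
    )

    cohort = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "sex": np.where(male, "male", "female"),
            "chronological_age": age,
            "latent_z": latent_z,
            "smoking": smoking,
            "alcohol": alcohol,
            "townsend_deprivation": deprivation,
        }
    )
    for key in ("ethnicity_white", "education_college", "physical_activity"):
        cohort[key] = rng.random(n) < prev[key]
    comorbidities = (
        "hypertension",
        "obesity",
        "dyslipidemia",
        "diabetes",
        "osteoporosis",
        "coronary_artery_disease",
        "heart_failure",
        "atrial_fibrillation",
        "cardiomyopathy",
        "chronic_kidney_disease",
    )
    for key in comorbidities:
        cohort[key] = rng.random(n) < prev[key]
    # medication use concentrates in the corresponding comorbidity group
    cohort["antidiabetic_medication"] = rng.random(n) < np.where(
        cohort["diabetes"], 0.55, 0.005
    )
    cohort["antithrombotic_medication"] = rng.random(n) < np.where(
        cohort["coronary_artery_disease"] | cohort["atrial_fibrillation"], 0.75, 0.10
    )
    cohort["antihypertensive_medication"] = rng.random(n) < np.where(
        cohort["hypertension"], 0.72, 0.03
    )
    cohort["lipid_lowering_medication"] = rng.random(n) < np.where(
        cohort["dyslipidemia"], 0.80, 0.05
    )
    cohort["cv_comorbidity"] = (
        cohort["coronary_artery_disease"]
        | cohort["heart_failure"]
        | cohort["atrial_fibrillation"]
        | cohort["cardiomyopathy"]
        | cohort["chronic_kidney_disease"]
    )

    for name, col in _draw_biomarkers(rng, config.biomarkers, age, male, latent_z).items():
        cohort[name] = col

    smoking_level = pd.Series(smoking).map({"never": 0, "former": 1, "current": 2}).to_numpy()
    age_c = age - 56.5

    # competing non-VHD death
    death_lp = (
        config.death_log_hr_age * age_c
        + config.death_log_hr_male * male
        + config.death_log_hr_latent * latent_z
    )
    t_death = _gompertz_time(rng, config.death_hazard_a, config.death_hazard_b, death_lp, n)

    # censoring: administrative (entry spread over recruitment window) + dropout
    half = config.entry_window_years / 2.0
    t_admin = config.admin_censor_years + rng.uniform(-half, half, n)
    if config.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / config.dropout_rate, n)
        t_censor = np.minimum(t_admin, t_drop)
    else:
        t_censor = t_admin
    cohort["censor_time"] = t_censor
    cohort["death_time"] = t_death

    records = []
    for outcome in config.outcomes:
        sp = config.outcomes[outcome]
        lp = (
            config.log_hr_per_sd_baa.get(outcome, 0.0) * latent_z
            + sp.log_hr_age * age_c
            + sp.log_hr_male * male
            + sp.log_hr_smoking * smoking_level
            + sp.log_hr_deprivation * deprivation_z
        )
        one_year_p = 1.0 - np.exp(-sp.weibull_scale * np.exp(lp))
        if np.any(one_year_p > 0.99):
            raise ValueError(
                f"outcome {outcome!r}: configured hazards imply >99% 1-year "
                "event probability for some participants"
            )
        t_event = _weibull_time(rng, sp.weibull_shape, sp.weibull_scale, lp, n)
        time = np.minimum.reduce([t_event, t_death, t_censor])
        status = np.where(
            t_event <= np.minimum(t_death, t_censor),
            "event",
            np.where(t_death <= t_censor, "competing_death", "censored"),
        )
        codes = np.asarray(ICD10_CODES[outcome])
        icd = np.where(
            status == "event",
            codes[rng.integers(0, len(codes), n)],
            "none",
        )
        records.append(
            pd.DataFrame(
                {
                    "participant_id": np.arange(n),
                    "outcome": outcome,
                    "icd10_code": icd,
                    "time": np.maximum(time, 1e-8),
                    "status": status,
                }
            )
        )
    events = pd.concat(records, ignore_index=True)

    # exclusion-stage flags
    cohort["missing_biomarkers"] = rng.random(n) < config.missing_biomarker_rate
    cohort["baseline_vhd"] = rng.random(n) < config.baseline_vhd_rate
    return cohort, events


def event_table_for_outcome(cohort: pd.DataFrame, events: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Merge one outcome's terminal records onto the cohort table.

    Adds ``time`` and numeric ``status`` (0 censored, 1 event,
    2 competing death) columns restricted to participants present in
    ``cohort``.
    """
    if outcome not in set(events["outcome"]):
        raise ValueError(f"unknown outcome {outcome!r}")
    ev = events[events["outcome"] == outcome][["participant_id", "time", "status"]]
    merged = cohort.merge(ev, on="participant_id", how="inner", validate="one_to_one")
    merged["status"] = merged["status"].map(
        {"censored": 0, "event": 1, "competing_death": 2}
    ).astype(int)
    return merged


#: Named exclusion criteria: label -> predicate over the cohort frame
#: returning a boolean "remove this row" mask.
EXCLUSION_CRITERIA = {
    "missing_biomarkers": lambda df: df["missing_biomarkers"].to_numpy(bool),
    "baseline_vhd": lambda df: df["baseline_vhd"].to_numpy(bool),
    "cv_comorbidity": lambda df: df["cv_comorbidity"].to_numpy(bool),
    "followup_lt_2y": lambda df: df["censor_time"].to_numpy(float) < 2.0,
}


def apply_exclusions(cohort: pd.DataFrame, criteria):
    """Apply ordered exclusion criteria and account for every row.

    ``criteria`` is an ordered list of labels from
    :data:`EXCLUSION_CRITERIA` or ``(label, predicate)`` pairs.  Returns
    ``(filtered_cohort, report)`` where the report is a DataFrame with
    columns ``criterion, n_removed, n_remaining`` whose counts reconcile
    exactly with the input size.
    """
    df = cohort
    rows = []
    for crit in criteria:
        if isinstance(crit, str):
            if crit not in EXCLUSION_CRITERIA:
                raise KeyError(
                    f"unknown exclusion criterion {crit!r}; "
                    f"known: {sorted(EXCLUSION_CRITERIA)}"
                )
            label, pred = crit, EXCLUSION_CRITERIA[crit]
        else:
            label, pred = crit
        mask = np.asarray(pred(df), dtype=bool)
        if mask.shape != (len(df),):
            raise ValueError(f"criterion {label!r} returned a mask of wrong length")
        n_removed = int(mask.sum())
        df = df.loc[~mask]
        rows.append({"criterion": label, "n_removed": n_removed, "n_remaining": len(df)})
    report = pd.DataFrame(rows, columns=["criterion", "n_removed", "n_remaining"])
    if len(report):
        assert report["n_remaining"].iloc[-1] == len(cohort) - report["n_removed"].sum()
    return df.copy(), report
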