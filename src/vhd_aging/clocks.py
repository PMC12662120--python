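"""Blood-chemistry biological-age clocks and biological age acceleration.

Two clocks are implemented:

* **KDM-BA** (Klemera-Doubal biological age): each biomarker is regressed
  on chronological age in a reference population, yielding per-biomarker
  intercept ``q``, slope ``k`` and root-mean-squared error ``s``.  A
  participant's biological age is the precision-weighted combination of
  the biomarker-implied ages and chronological age,

      BA = [ sum_i (x_i - q_i) k_i / s_i^2  +  CA / s_BA^2 ]
           / [ sum_i (k_i / s_i)^2  +  1 / s_BA^2 ],

  where ``s_BA`` scales the contribution of chronological age.
* **PhenoAge**: a fixed, published linear predictor over nine blood
  chemistries plus chronological age is mapped through a Gompertz
  proportional-hazards model to a 120-month mortality risk, which is then
  converted back to the chronological age of an average person with the
  same risk.

Biological age acceleration (BAA) is the residual from an ordinary
least-squares regression of biological age on chronological age; by
construction it is uncorrelated with chronological age in the cohort it
is computed on.  BAA is standardized (mean 0, SD 1) for continuous
analyses and cut at its quartiles for dose-response analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "KDM_BIOMARKERS",
    "PHENOAGE_BIOMARKERS",
    "BIOMARKER_UNITS",
    "KDMParameters",
    "PhenoAgeModel",
    "DegenerateBiomarkerError",
    "StratumMismatchError",
    "fit_kdm_parameters",
    "kdm_biological_age",
    "phenoage_linear_predictor",
    "phenoage",
    "phenoage_from_panel",
    "compute_acceleration",
    "standardize_and_quartile",
    "score_cohort",
]

#: Biomarkers entering the KDM-BA clock: FEV1, systolic blood pressure and
#: seven blood chemistries.
KDM_BIOMARKERS = (
    "fev1",
    "systolic_bp",
    "albumin",
    "alkaline_phosphatase",
    "blood_urea_nitrogen",
    "creatinine",
    "c_reactive_protein",
    "hba1c",
    "total_cholesterol",
)

#: Biomarkers entering the PhenoAge linear predictor (besides age).
PHENOAGE_BIOMARKERS = (
    "albumin",
    "creatinine",
    "glucose",
    "c_reactive_protein",
    "lymphocyte_percent",
    "mean_cell_volume",
    "red_cell_distribution_width",
    "alkaline_phosphatase",
    "white_blood_cell_count",
)

#: Unit convention for every clock input.  The published clock
#: coefficients are unit-bound, so inputs must arrive in these units.
BIOMARKER_UNITS = {
    "albumin": "g/L",
    "alkaline_phosphatase": "U/L",
    "blood_urea_nitrogen": "mmol/L",
    "creatinine": "umol/L",
    "c_reactive_protein": "mg/dL",
    "hba1c": "%",
    "total_cholesterol": "mmol/L",
    "fev1": "L",
    "systolic_bp": "mmHg",
    "glucose": "mmol/L",
    "mean_cell_volume": "fL",
    "red_cell_distribution_width": "%",
    "white_blood_cell_count": "10^3 cells/uL",
    "lymphocyte_percent": "%",
    "chronological_age": "years",
}


class DegenerateBiomarkerError(ValueError):
    """A biomarker cannot support KDM training (zero variance, zero slope,
    or a perfect fit with zero residual error)."""


class StratumMismatchError(ValueError):
    """A panel is scored with parameters trained on a different sex stratum."""


@dataclass
class KDMParameters:
    """Trained KDM-BA parameters for one sex stratum.

    ``q``, ``k`` and ``s`` map biomarker name to the intercept, slope and
    root-mean-squared error of the simple regression of the biomarker on
    chronological age in the reference population.  ``s_ba`` (years) is
    the scaling factor applied to chronological age; ``np.inf`` is the
    biomarker-only limit.
    """

    biomarkers: tuple
    q: dict
    k: dict
    s: dict
    s_ba: float
    sex_stratum: str
    reference_age_range: tuple
    n_reference: int
    s_ba_mode: str = "explained_variance"
    units: dict = field(default_factory=lambda: dict(BIOMARKER_UNITS))

    def __post_init__(self):
        for name in self.biomarkers:
            if self.s[name] <= 0:
                raise DegenerateBiomarkerError(
                    f"biomarker {name!r}: s must be > 0, got {self.s[name]!r}"
                )
            if self.k[name] == 0:
                raise DegenerateBiomarkerError(
                    f"biomarker {name!r}: slope k must be nonzero"
                )
        if not self.s_ba > 0:
            raise ValueError(f"s_ba must be > 0, got {self.s_ba!r}")

    def to_dict(self) -> dict:
        return {
            "biomarkers": list(self.biomarkers),
            "q": {b: float(self.q[b]) for b in self.biomarkers},
            "k": {b: float(self.k[b]) for b in self.biomarkers},
            "s": {b: float(self.s[b]) for b in self.biomarkers},
            "s_ba": float(self.s_ba) if np.isfinite(self.s_ba) else ".inf",
            "sex_stratum": self.sex_stratum,
            "reference_age_range": [float(a) for a in self.reference_age_range],
            "n_reference": int(self.n_reference),
            "s_ba_mode": self.s_ba_mode,
            "units": dict(self.units),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KDMParameters":
        s_ba = d["s_ba"]
        if s_ba == ".inf":
            s_ba = np.inf
        return cls(
            biomarkers=tuple(d["biomarkers"]),
            q=dict(d["q"]),
            k=dict(d["k"]),
            s=dict(d["s"]),
            s_ba=float(s_ba),
            sex_stratum=d["sex_stratum"],
            reference_age_range=tuple(d["reference_age_range"]),
            n_reference=int(d["n_reference"]),
            s_ba_mode=d.get("s_ba_mode", "explained_variance"),
            units=dict(d.get("units", BIOMARKER_UNITS)),
        )

    def to_yaml(self, path=None) -> str:
        # repr-roundtrip floats so reloaded parameters score bit-identically
        text = yaml.safe_dump(
            _float_repr_tree(self.to_dict()), sort_keys=True, default_flow_style=False
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "KDMParameters":
        if hasattr(source, "read"):
            raw = source.read()
        else:
            try:
                with open(source) as fh:
                    raw = fh.read()
            except (OSError, ValueError):
                raw = source
        d = yaml.safe_load(raw)
        for key in ("q", "k", "s"):
            d[key] = {b: float(v) for b, v in d[key].items()}
        if d["s_ba"] != ".inf":
            d["s_ba"] = float(d["s_ba"])
        d["reference_age_range"] = [float(a) for a in d["reference_age_range"]]
        return cls.from_dict(d)


def _float_repr_tree(obj):
    """Render floats as full-precision repr strings for lossless YAML."""
    if isinstance(obj, float):
        return repr(obj)
    if isinstance(obj, dict):
        return {k: _float_repr_tree(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_float_repr_tree(v) for v in obj]
    return obj


@dataclass(frozen=True)
class PhenoAgeModel:
    """Published PhenoAge coefficients and Gompertz constants.

    The linear predictor ``xb`` is mapped to the probability of death
    within ``horizon_months`` under a Gompertz hazard with shape
    ``gamma``, and that risk is mapped back to years via the age-only
    Gompertz model encoded by ``const_a``, ``const_b`` and ``const_c``.
    """

    intercept: float = -19.907
    coef_albumin: float = -0.0336
    coef_creatinine: float = 0.0095
    coef_glucose: float = 0.1953
    coef_ln_crp: float = 0.0954
    coef_lymphocyte_pct: float = -0.012
    coef_mcv: float = 0.0268
    coef_rdw: float = 0.3306
    coef_alp: float = 0.00188
    coef_wbc: float = 0.0554
    coef_age: float = 0.0804
    gamma: float = 0.0076927
    horizon_months: float = 120.0
    const_a: float = 141.50225
    const_b: float = 0.090165
    const_c: float = 0.00553

    def __post_init__(self):
        if not (self.gamma > 0 and self.horizon_months > 0):
            raise ValueError("gamma and horizon_months must be positive")


_PHENOAGE_TERMS = (
    ("albumin", "coef_albumin", False),
    ("creatinine", "coef_creatinine", False),
    ("glucose", "coef_glucose", False),
    ("c_reactive_protein", "coef_ln_crp", True),
    ("lymphocyte_percent", "coef_lymphocyte_pct", False),
    ("mean_cell_volume", "coef_mcv", False),
    ("red_cell_distribution_width", "coef_rdw", False),
    ("alkaline_phosphatase", "coef_alp", False),
    ("white_blood_cell_count", "coef_wbc", False),
    ("chronological_age", "coef_age", False),
)


def _as_frame(panel) -> pd.DataFrame:
    if isinstance(panel, pd.Series):
        return panel.to_frame().T
    if isinstance(panel, dict):
        return pd.DataFrame([panel])
    return panel


def _require_columns(df: pd.DataFrame, names) -> None:
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise KeyError(f"panel is missing required biomarker field(s): {missing}")


def fit_kdm_parameters(
    reference: pd.DataFrame,
    biomarkers=KDM_BIOMARKERS,
    sex_stratum: str = None,
    age_range: tuple = None,
    s_ba_mode: str = "explained_variance",
    slope_tol: float = 1e-10,
) -> KDMParameters:
    """Train per-biomarker KDM regressions on a reference population.

    Parameters
    ----------
    reference
        Reference table with one row per participant, containing the
        biomarker columns, ``chronological_age`` and (if ``sex_stratum``
        is given) a ``sex`` column.
    biomarkers
        Names of the biomarker columns to train on.
    sex_stratum
        ``"male"`` or ``"female"``; rows of the other sex are dropped and
        the trained parameters are tagged with the stratum.  ``None``
        trains pooled parameters tagged ``"pooled"``.
    age_range
        Optional ``(lo, hi)`` restriction on chronological age.
    s_ba_mode
        ``"explained_variance"`` (default): ``s_BA^2`` is the variance of
        chronological age multiplied by the R-squared of the multivariate
        regression of age on the biomarker panel — i.e. the variance in
        age explained by the panel.  ``"kdm_correction"``: the original
        Klemera-Doubal estimator based on the spread of the
        biomarker-only age estimate around chronological age, with the
        characteristic-correlation correction term.

    Returns
    -------
    KDMParameters

    Raises
    ------
    DegenerateBiomarkerError
        If any biomarker has (near-)zero variance, a slope below
        ``slope_tol`` in absolute value, or a perfect fit (``s`` = 0).
    """
    biomarkers = tuple(biomarkers)
    df = reference
    if sex_stratum is not None:
        df = df[df["sex"] == sex_stratum]
    if age_range is not None:
        lo, hi = age_range
        df = df[(df["chronological_age"] >= lo) & (df["chronological_age"] <= hi)]
    if len(df) == 0:
        raise ValueError(f"empty reference stratum (sex={sex_stratum!r}, age_range={age_range!r})")
    if len(df) < 30:
        raise ValueError(f"reference stratum has {len(df)} rows; at least 30 required")
    _require_columns(df, list(biomarkers) + ["chronological_age"])

    ca = df["chronological_age"].to_numpy(float)
    if np.var(ca) == 0:
        raise ValueError("chronological age has zero variance in the reference")

    q, k, s = {}, {}, {}
    n = len(df)
    for name in biomarkers:
        x = df[name].to_numpy(float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"biomarker {name!r} contains non-finite values")
        if np.var(x) == 0:
            raise DegenerateBiomarkerError(f"biomarker {name!r} has zero variance")
        slope, intercept = np.polyfit(ca, x, 1)
        resid = x - (intercept + slope * ca)
        # regression standard error with 2 fitted parameters
        rmse = float(np.sqrt(np.sum(resid**2) / max(n - 2, 1)))
        if abs(slope) < slope_tol:
            raise DegenerateBiomarkerError(
                f"biomarker {name!r}: slope {slope:.3e} below tolerance {slope_tol:g}"
            )
        if rmse <= 1e-10 * max(1.0, float(np.max(np.abs(x)))):
            raise DegenerateBiomarkerError(
                f"biomarker {name!r}: perfect fit on chronological age (s = 0)"
            )
        q[name], k[name], s[name] = float(intercept), float(slope), rmse

    s_ba = _estimate_s_ba(df, biomarkers, ca, q, k, s, mode=s_ba_mode)
    return KDMParameters(
        biomarkers=biomarkers,
        q=q,
        k=k,
        s=s,
        s_ba=s_ba,
        sex_stratum=sex_stratum if sex_stratum is not None else "pooled",
        reference_age_range=(float(ca.min()), float(ca.max()))
        if age_range is None
        else (float(age_range[0]), float(age_range[1])),
        n_reference=n,
        s_ba_mode=s_ba_mode,
    )


def _estimate_s_ba(df, biomarkers, ca, q, k, s, mode):
    X = df[list(biomarkers)].to_numpy(float)
    n = len(ca)
    if mode == "explained_variance":
        # R^2 of the multivariate biomarkers -> age fit
        A = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(A, ca, rcond=None)
        resid = ca - A @ beta
        ss_tot = np.sum((ca - ca.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        s_ba2 = np.var(ca, ddof=1) * r2
        if s_ba2 <= 0:
            raise ValueError("biomarker panel explains no age variance; s_BA undefined")
        return float(np.sqrt(s_ba2))
    if mode == "kdm_correction":
        # Original estimator: spread of the biomarker-only age estimate
        # around CA, minus the noise floor implied by the characteristic
        # biomarker-age correlation.
        w = np.array([(k[b] / s[b]) ** 2 for b in biomarkers])
        num = np.zeros(n)
        for j, b in enumerate(biomarkers):
            num += (X[:, j] - q[b]) * k[b] / s[b] ** 2
        ba_e = num / w.sum()
        diff = ba_e - ca
        r_char = abs(np.corrcoef(ba_e, ca)[0, 1])
        m = len(biomarkers)
        correction = ((1.0 - r_char**2) / r_char**2) * ((ca.max() - ca.min()) ** 2) / (12.0 * m)
        s_ba2 = np.mean((diff - diff.mean()) ** 2) - correction
        if s_ba2 <= 0:
            raise ValueError("kdm_correction s_BA estimate is non-positive; panel too weak")
        return float(np.sqrt(s_ba2))
    raise ValueError(f"unknown s_ba_mode {mode!r}")


def kdm_biological_age(panel, params: KDMParameters, check_stratum: bool = True):
    """Score KDM biological age for one panel or a table of panels.

    Implements the precision-weighted ratio

        BA = [ sum_i (x_i - q_i) k_i / s_i^2 + CA / s_BA^2 ]
             / [ sum_i (k_i / s_i)^2 + 1 / s_BA^2 ].

    ``params.s_ba = inf`` gives the biomarker-only estimator.  Returns a
    float for a single panel, an ndarray for a table.
    """
    df = _as_frame(panel)
    _require_columns(df, list(params.biomarkers) + ["chronological_age"])
    if check_stratum and params.sex_stratum != "pooled" and "sex" in df.columns:
        bad = df["sex"] != params.sex_stratum
        if bad.any():
            raise StratumMismatchError(
                f"{int(bad.sum())} panel row(s) have sex != {params.sex_stratum!r}; "
                "score each stratum with its own parameters"
            )
    ca = df["chronological_age"].to_numpy(float)
    num = np.zeros(len(df))
    den = 0.0
    for b in params.biomarkers:
        x = df[b].to_numpy(float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"biomarker {b!r} contains non-finite values")
        num += (x - params.q[b]) * params.k[b] / params.s[b] ** 2
        den += (params.k[b] / params.s[b]) ** 2
    if np.isfinite(params.s_ba):
        num += ca / params.s_ba**2
        den += 1.0 / params.s_ba**2
    ba = num / den
    if not np.all(np.isfinite(ba)):
        raise ValueError("non-finite biological age produced")
    return ba if isinstance(panel, pd.DataFrame) else float(ba[0])


def phenoage_linear_predictor(panel, model: PhenoAgeModel = PhenoAgeModel()):
    """Linear predictor ``xb`` of the PhenoAge mortality model.

    C-reactive protein (mg/dL) enters as its natural logarithm and must
    therefore be strictly positive.
    """
    df = _as_frame(panel)
    _require_columns(df, [name for name, _, _ in _PHENOAGE_TERMS])
    crp = df["c_reactive_protein"].to_numpy(float)
    if np.any(crp <= 0):
        raise ValueError("c_reactive_protein must be strictly positive (entered as ln CRP)")
    xb = np.full(len(df), model.intercept)
    for name, coef_attr, log_transform in _PHENOAGE_TERMS:
        v = df[name].to_numpy(float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"field {name!r} contains non-finite values")
        xb += getattr(model, coef_attr) * (np.log(v) if log_transform else v)
    return xb if isinstance(panel, pd.DataFrame) else float(xb[0])


def phenoage_mortality_risk(xb, model: PhenoAgeModel = PhenoAgeModel()):
    """Gompertz mortality risk over the model horizon (120 months):
    ``1 - exp(-exp(xb) * (exp(gamma*horizon) - 1) / gamma)``."""
    xb_arr = np.asarray(xb, dtype=float)
    cum = np.exp(xb_arr) * (np.exp(model.gamma * model.horizon_months) - 1.0) / model.gamma
    out = -np.expm1(-cum)
    return out if np.ndim(xb) else float(out)


def phenoage(xb, model: PhenoAgeModel = PhenoAgeModel()):
    """Map the linear predictor to PhenoAge in years.

    Two-step composition of Gompertz models::

        risk     = 1 - exp(-exp(xb) * (exp(gamma * horizon) - 1) / gamma)
        PhenoAge = const_a + ln(-const_c * ln(1 - risk)) / const_b

    ``-ln(1 - risk)`` equals the cumulative hazard
    ``exp(xb) * (exp(gamma*horizon) - 1) / gamma`` algebraically, and is
    evaluated in that form so extreme risks near 0 or 1 do not lose
    precision to the ``1 - risk`` round trip.  Strictly increasing in
    ``xb``.  Raises where the risk degenerates to exactly 0 or 1 (the
    outer log is undefined there).
    """
    xb_arr = np.asarray(xb, dtype=float)
    if not np.all(np.isfinite(xb_arr)):
        raise ValueError("xb must be finite")
    cum = np.exp(xb_arr) * (np.exp(model.gamma * model.horizon_months) - 1.0) / model.gamma
    if np.any(cum == 0.0) or not np.all(np.isfinite(cum)):
        raise ValueError("mortality risk is numerically 0 or 1; PhenoAge undefined")
    out = model.const_a + np.log(model.const_c * cum) / model.const_b
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite PhenoAge produced")
    return out if np.ndim(xb) else float(out)


def phenoage_from_panel(panel, model: PhenoAgeModel = PhenoAgeModel()):
    """Convenience composition: panel -> xb -> PhenoAge (years)."""
    return phenoage(phenoage_linear_predictor(panel, model), model)


def compute_acceleration(ba, ca):
    """Residual biological age acceleration from the BA ~ CA regression.

    Fits ordinary least squares of biological age on chronological age
    over the cohort and returns the residuals.  By construction the
    residuals have mean zero and zero sample correlation with
    chronological age.
    """
    ba = np.asarray(ba, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if ba.shape != ca.shape or ba.ndim != 1:
        raise ValueError("ba and ca must be 1-d arrays of equal length")
    if len(ca) < 3:
        raise ValueError("at least 3 participants required")
    if np.var(ca) == 0:
        raise ValueError("chronological age is constant; BAA regression undefined")
    slope, intercept = np.polyfit(ca, ba, 1)
    return ba - (intercept + slope * ca)


def standardize_and_quartile(baa):
    """Standardize BAA to mean 0 / SD 1 and cut at sample quartiles.

    Quartile boundaries are linear-interpolation sample quantiles; a
    value equal to a boundary is assigned to the lower quartile, i.e.
    Q1 = (-inf, q25], Q2 = (q25, q50], Q3 = (q50, q75], Q4 = (q75, inf).
    Q1 (lowest BAA) is the reference group.

    Returns ``(baa_z, labels)`` where labels is a pandas Categorical with
    ordered categories Q1 < Q2 < Q3 < Q4.
    """
    baa = np.asarray(baa, dtype=float)
    if len(np.unique(baa)) < 4:
        raise ValueError("at least 4 distinct BAA values required for quartiles")
    sd = baa.std(ddof=1)
    if sd == 0:
        raise ValueError("BAA has zero variance")
    z = (baa - baa.mean()) / sd
    q25, q50, q75 = np.quantile(baa, [0.25, 0.5, 0.75], method="linear")
    idx = (baa > q25).astype(int) + (baa > q50) + (baa > q75)
    labels = pd.Categorical.from_codes(idx, categories=["Q1", "Q2", "Q3", "Q4"], ordered=True)
    return z, labels


def score_cohort(
    cohort: pd.DataFrame,
    kdm_params: dict = None,
    phenoage_model: PhenoAgeModel = PhenoAgeModel(),
    id_col: str = "participant_id",
) -> pd.DataFrame:
    """Score a cohort with both clocks and derive BAA, z-scores, quartiles.

    Parameters
    ----------
    cohort
        Table with biomarker columns, ``chronological_age`` and ``sex``.
    kdm_params
        Mapping ``{"male": KDMParameters, "female": KDMParameters}`` (or
        ``{"pooled": ...}``).  ``None`` skips the KDM clock.

    Returns a copy of the cohort with added columns per clock:
    ``{kdm,phenoage}_ba``, ``..._baa``, ``..._baa_z``, ``..._quartile``.
    """
    out = cohort.copy()
    ca = out["chronological_age"].to_numpy(float)

    if kdm_params is not None:
        ba = np.empty(len(out))
        if "pooled" in kdm_params:
            ba[:] = kdm_biological_age(out, kdm_params["pooled"], check_stratum=False)
        else:
            for sex, params in kdm_params.items():
                mask = (out["sex"] == sex).to_numpy()
                if mask.any():
                    ba[mask] = kdm_biological_age(out.loc[mask], params)
        out["kdm_ba"] = ba
        out["kdm_baa"] = compute_acceleration(ba, ca)
        z, q = standardize_and_quartile(out["kdm_baa"].to_numpy())
        out["kdm_baa_z"] = z
        out["kdm_quartile"] = q

    out["phenoage_ba"] = phenoage_from_panel(out, phenoage_model)
    out["phenoage_baa"] = compute_acceleration(out["phenoage_ba"].to_numpy(), ca)
    z, q = standardize_and_quartile(out["phenoage_baa"].to_numpy())
    out["phenoage_baa_z"] = z
    out["phenoage_quartile"] = q
    return out
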