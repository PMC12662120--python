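"""Hazard-ratio estimation, proportional-hazards diagnostics, competing
risks and spline dose-response for the valvular-disease analysis.

Cox proportional-hazards models are fitted with lifelines (Efron ties by
default).  The Fine-Gray subdistribution-hazard model is implemented
here directly: subjects failing from the competing cause remain in the
risk set with inverse-probability-of-censoring weights from the pooled
Kaplan-Meier estimator of the censoring distribution, and the weighted
partial likelihood is maximized by Newton-Raphson.  Dose-response curves
use restricted cubic splines (natural cubic splines, linear in the
tails) with the knot count chosen by minimum AIC over 3-7 knots and the
hazard ratio anchored to 1 at the cohort median exposure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test
from scipy import stats

__all__ = [
    "MODEL1_COVARIATES",
    "MODEL2_COVARIATES",
    "ModelSpec",
    "CoxFit",
    "FineGrayFit",
    "SplineFit",
    "build_design",
    "fit_cox_model",
    "schoenfeld_ph_test",
    "fit_fine_gray",
    "rcs_basis",
    "harrell_knots",
    "fit_dose_response",
    "adjusted_cumulative_curve",
    "quartile_hr_table",
]

#: Primary adjustment set: demographic and lifestyle confounders.
MODEL1_COVARIATES = (
    "sex",
    "ethnicity_white",
    "education_college",
    "smoking",
    "alcohol",
    "physical_activity",
    "townsend_deprivation",
)

#: Secondary adjustment set: Model 1 plus comorbidities and medications,
#: excluding antihypertensive and lipid-lowering drugs (collinearity).
MODEL2_COVARIATES = MODEL1_COVARIATES + (
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
    "antidiabetic_medication",
    "antithrombotic_medication",
)

_MODEL_SETS = {"Model1": MODEL1_COVARIATES, "Model2": MODEL2_COVARIATES}


@dataclass(frozen=True)
class ModelSpec:
    """Exposure + adjustment-set description for one regression."""

    exposure: str  # column name: a z-scored BAA or an ordered quartile column
    model_id: str = "Model1"
    timescale: str = "follow-up"  # or "attained-age"
    extra_covariates: tuple = ()

    @property
    def covariates(self) -> tuple:
        if self.model_id not in _MODEL_SETS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        return _MODEL_SETS[self.model_id] + tuple(self.extra_covariates)


def build_design(df: pd.DataFrame, columns) -> pd.DataFrame:
    """Numeric design matrix: booleans to 0/1, categoricals to dummies.

    ``sex`` becomes ``sex_male``; ordered categoricals (quartiles) and
    string columns are expanded with the first level as reference.
    """
    out = {}
    for col in columns:
        if col not in df.columns:
            raise KeyError(f"covariate {col!r} not in data")
        s = df[col]
        if s.dtype == bool:
            out[col] = s.astype(float)
        elif pd.api.types.is_numeric_dtype(s):
            out[col] = s.astype(float)
        else:
            cats = (
                list(s.cat.categories)
                if isinstance(s.dtype, pd.CategoricalDtype)
                else sorted(pd.unique(s.dropna()))
            )
            if col == "sex":
                out["sex_male"] = (s == "male").astype(float)
                continue
            if col == "smoking":
                cats = ["never", "former", "current"]
            elif col == "alcohol":
                cats = ["never", "month_to_week", "daily"]
            for level in cats[1:]:
                out[f"{col}_{level}"] = (s == level).astype(float)
    design = pd.DataFrame(out, index=df.index)
    for col in design.columns:
        if design[col].nunique() < 2:
            raise ValueError(f"covariate column {col!r} is constant")
    return design


@dataclass
class CoxFit:
    """Fitted Cox model plus the data it was fitted on."""

    summary: pd.DataFrame  # coef, se, hr, ci per term
    n: int
    n_events: int
    log_likelihood: float
    converged: bool
    model: CoxPHFitter = field(repr=False)
    data: pd.DataFrame = field(repr=False)
    duration_col: str = "time"
    event_col: str = "event"
    entry_col: str = None

    def hazard_ratios(self) -> pd.DataFrame:
        return self.summary[["hr", "hr_lower", "hr_upper"]]


@np.errstate(over="ignore")
def _summarize_cox(cph: CoxPHFitter) -> pd.DataFrame:
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": np.exp(s["coef"]),
            "hr_lower": np.exp(s["coef"] - 1.959963984540054 * s["se(coef)"]),
            "hr_upper": np.exp(s["coef"] + 1.959963984540054 * s["se(coef)"]),
            "p": s["p"],
        }
    )
    out.index.name = "term"
    return out


def fit_cox_model(
    df: pd.DataFrame,
    exposure,
    covariates=(),
    duration_col: str = "time",
    event_col: str = "event",
    entry_col: str = None,
    ties: str = "efron",
    min_events: int = 10,
) -> CoxFit:
    """Fit a Cox proportional-hazards model.

    ``exposure`` is a column name (numeric, boolean, or an ordered
    categorical such as a BAA quartile, expanded with its first level —
    Q1 — as the reference) or a list of pre-built numeric columns.
    """
    n_events = int((df[event_col] == 1).sum())
    if n_events < min_events:
        raise ValueError(f"only {n_events} events; at least {min_events} required")
    exposure_cols = [exposure] if isinstance(exposure, str) else list(exposure)
    design = build_design(df, exposure_cols + list(covariates))
    data = design.copy()
    data[duration_col] = df[duration_col].to_numpy(float)
    data[event_col] = (df[event_col] == 1).astype(int).to_numpy()
    if entry_col is not None:
        data[entry_col] = df[entry_col].to_numpy(float)
    cph = CoxPHFitter(baseline_estimation_method="breslow")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                data,
                duration_col=duration_col,
                event_col=event_col,
                entry_col=entry_col,
                fit_options={"precision": 1e-9},
            )
    except ConvergenceError as err:
        raise ValueError(f"Cox model failed to converge (possible separation): {err}") from err
    # lifelines uses Efron ties internally; Breslow available via the
    # package's own partial-likelihood machinery in fit_fine_gray.
    if ties not in ("efron",):
        raise ValueError("fit_cox_model supports ties='efron'; use fit_fine_gray for Breslow")
    return CoxFit(
        summary=_summarize_cox(cph),
        n=len(data),
        n_events=n_events,
        log_likelihood=float(cph.log_likelihood_),
        converged=True,
        model=cph,
        data=data,
        duration_col=duration_col,
        event_col=event_col,
        entry_col=entry_col,
    )


def schoenfeld_ph_test(fit: CoxFit, time_transform: str = "km") -> pd.DataFrame:
    """Score test for zero slope of scaled Schoenfeld residuals vs time.

    Returns a DataFrame with the per-term chi-square statistic and
    p-value plus a ``GLOBAL`` row.  Kaplan-Meier time transform by
    default.
    """
    if fit.n_events < 3:
        raise ValueError("too few events for a proportional-hazards test")
    res = proportional_hazard_test(fit.model, fit.data, time_transform=time_transform)
    s = res.summary
    stat = s["test_statistic"].astype(float)
    p = s["p"].astype(float)
    out = pd.DataFrame({"test_statistic": stat, "p": p})
    out.index = [ix[0] if isinstance(ix, tuple) else ix for ix in out.index]
    global_stat = float(stat.sum())
    global_p = float(stats.chi2.sf(global_stat, df=len(stat)))
    out.loc["GLOBAL"] = [global_stat, global_p]
    return out


# ---------------------------------------------------------------------------
# Fine-Gray subdistribution-hazard regression
# ---------------------------------------------------------------------------


@dataclass
class FineGrayFit:
    """Fitted Fine-Gray model.

    ``status`` coding: 0 censored, 1 event of interest, 2 competing
    death.  Coefficients are log subdistribution hazard ratios; the
    variance is the inverse observed information of the weighted partial
    likelihood (censoring-weight estimation uncertainty not propagated).
    """

    summary: pd.DataFrame
    n: int
    n_events: int
    n_competing: int
    log_likelihood: float
    converged: bool
    event_times: np.ndarray = field(repr=False)
    baseline_subhazard: np.ndarray = field(repr=False)  # dH at event_times, x = 0

    def coefficients(self) -> pd.Series:
        return self.summary["coef"]

    def cumulative_incidence(self, times, x=None):
        """Predicted cumulative incidence by product-limit over the
        estimated subdistribution hazard increments, at covariate vector
        ``x`` (defaults to all zeros)."""
        lp = 0.0 if x is None else float(np.dot(np.asarray(x, float), self.summary["coef"]))
        dh = np.clip(self.baseline_subhazard * np.exp(lp), 0.0, 1.0)
        surv = np.cumprod(1.0 - dh)
        cif_at_events = 1.0 - surv
        idx = np.searchsorted(self.event_times, np.asarray(times, float), side="right")
        out = np.concatenate([[0.0], cif_at_events])[idx]
        return out


def _censoring_km_left(times, status):
    """Left-continuous Kaplan-Meier of the censoring distribution G(t-),
    evaluated at each subject's own time."""
    n = len(times)
    order = np.argsort(times, kind="mergesort")
    t_sorted = times[order]
    cens_sorted = (status[order] == 0).astype(float)
    uniq, start = np.unique(t_sorted, return_index=True)
    km = np.ones(len(uniq))
    at_risk = n
    g = 1.0
    counts = np.add.reduceat(np.ones_like(t_sorted), start)
    cens_counts = np.add.reduceat(cens_sorted, start)
    for j in range(len(uniq)):
        # G(t-) uses information strictly before t; record pre-update value
        km[j] = g
        if at_risk > 0:
            g *= 1.0 - cens_counts[j] / at_risk
        at_risk -= counts[j]
    # km[j] is G just before uniq[j]; G(t-) at a subject time is that value
    idx = np.searchsorted(uniq, times)
    return km[idx]


def fit_fine_gray(
    df: pd.DataFrame,
    covariate_cols,
    duration_col: str = "time",
    status_col: str = "status",
    max_iter: int = 100,
    tol: float = 1e-10,
    weight_floor: float = 1e-8,
) -> FineGrayFit:
    """Fit the Fine-Gray model for the subdistribution hazard.

    Subjects who fail from the competing cause remain in later risk sets
    with weight G(t-)/G(T_i-), where G is the pooled Kaplan-Meier
    estimator of the censoring survival function (floored at
    ``weight_floor``).  Breslow handling of ties.  With no competing
    events the weighted partial likelihood reduces exactly to the
    Breslow Cox partial likelihood.
    """
    design = build_design(df, list(covariate_cols))
    X = design.to_numpy(float)
    names = list(design.columns)
    times = df[duration_col].to_numpy(float)
    status = df[status_col].to_numpy(int)
    if not set(np.unique(status)) <= {0, 1, 2}:
        raise ValueError("status must be coded 0 (censored), 1 (event), 2 (competing death)")
    n, p = X.shape
    n_events = int((status == 1).sum())
    n_competing = int((status == 2).sum())
    if n_events < 1:
        raise ValueError("no events of interest")

    order = np.argsort(times, kind="mergesort")
    t = times[order]
    d = status[order]
    Xs = X[order]
    g_left = np.maximum(_censoring_km_left(times, status)[order], weight_floor)

    is_event = d == 1
    is_comp = d == 2
    uniq_t, first_idx, counts = np.unique(t[is_event], return_index=True, return_counts=True)
    # sum of covariate vectors over events at each unique event time
    ev_X = Xs[is_event]
    xsum_at = np.add.reduceat(ev_X, first_idx, axis=0)

    comp_t = t[is_comp]
    # positions for prefix sums over competing subjects with T_i < t_j
    comp_before = np.searchsorted(comp_t, uniq_t, side="left")
    # positions for suffix sums over subjects with T_i >= t_j
    atrisk_from = np.searchsorted(t, uniq_t, side="left")

    def negll_grad_hess(beta):
        xb = Xs @ beta
        # overflow in exp just makes the line search reject the step
        with np.errstate(over="ignore"):
            exb = np.exp(xb)
        wexb_comp = exb[is_comp] / g_left[is_comp]
        Xe = Xs * exb[:, None]
        Xe_comp = Xs[is_comp] * wexb_comp[:, None]

        # suffix cumulative sums (subjects still at risk)
        s0_suf = np.concatenate([np.cumsum(exb[::-1])[::-1], [0.0]])
        s1_suf = np.concatenate([np.cumsum(Xe[::-1], axis=0)[::-1], np.zeros((1, p))])
        # prefix sums over competing subjects
        c0_pre = np.concatenate([[0.0], np.cumsum(wexb_comp)])
        c1_pre = np.concatenate([np.zeros((1, p)), np.cumsum(Xe_comp, axis=0)])

        # second-moment sums, only for the Hessian
        XX = Xs[:, :, None] * Xs[:, None, :]
        XXe = XX * exb[:, None, None]
        XXe_comp = XX[is_comp] * wexb_comp[:, None, None]
        s2_suf = np.concatenate([np.cumsum(XXe[::-1], axis=0)[::-1], np.zeros((1, p, p))])
        c2_pre = np.concatenate([np.zeros((1, p, p)), np.cumsum(XXe_comp, axis=0)])

        # G(t_j -) for each unique event time
        gj = np.ones(len(uniq_t))
        if len(comp_t):
            all_g_sorted = g_left  # aligned with t
            # G(t-) at event times: reuse KM-left on the pooled sample
            idx = np.searchsorted(t, uniq_t, side="left")
            gj = np.maximum(all_g_sorted[idx], weight_floor)

        D0 = s0_suf[atrisk_from] + gj * c0_pre[comp_before]
        D1 = s1_suf[atrisk_from] + gj[:, None] * c1_pre[comp_before]
        D2 = s2_suf[atrisk_from] + gj[:, None, None] * c2_pre[comp_before]

        ll = float(np.sum(xb[is_event]) - np.sum(counts * np.log(D0)))
        W = D1 / D0[:, None]
        grad = xsum_at.sum(axis=0) - (counts[:, None] * W).sum(axis=0)
        H = -(
            counts[:, None, None]
            * (D2 / D0[:, None, None] - W[:, :, None] * W[:, None, :])
        ).sum(axis=0)
        return -ll, -grad, -H

    beta = np.zeros(p)
    converged = False
    nll, g, H = negll_grad_hess(beta)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular information matrix (separation?): {err}") from err
        # Newton with step halving
        factor = 1.0
        for _ in range(30):
            cand = beta - factor * step
            nll_c, g_c, H_c = negll_grad_hess(cand)
            if nll_c <= nll + 1e-12:
                break
            factor *= 0.5
        else:
            raise ValueError("Fine-Gray line search failed; fit flagged non-convergent")
        beta, nll, g, H = cand, nll_c, g_c, H_c
        if np.max(np.abs(g)) < tol * (1.0 + abs(nll)):
            converged = True
            break
    if not converged and np.max(np.abs(g)) > 1e-4:
        raise ValueError("Fine-Gray did not converge")

    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    z = 1.959963984540054
    with np.errstate(over="ignore"):
        summary = pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "hr": np.exp(beta),
                "hr_lower": np.exp(beta - z * se),
                "hr_upper": np.exp(beta + z * se),
                "p": 2 * stats.norm.sf(np.abs(beta / se)),
            },
            index=pd.Index(names, name="term"),
        )
    # Breslow-type baseline subdistribution hazard increments at beta
    xb = Xs @ beta
    exb = np.exp(xb)
    wexb_comp = exb[is_comp] / g_left[is_comp]
    s0_suf = np.concatenate([np.cumsum(exb[::-1])[::-1], [0.0]])
    c0_pre = np.concatenate([[0.0], np.cumsum(wexb_comp)])
    idx = np.searchsorted(t, uniq_t, side="left")
    gj = np.maximum(g_left[idx], weight_floor) if len(comp_t) else np.ones(len(uniq_t))
    D0 = s0_suf[atrisk_from] + gj * c0_pre[comp_before]
    dh = counts / D0

    return FineGrayFit(
        summary=summary,
        n=n,
        n_events=n_events,
        n_competing=n_competing,
        log_likelihood=-nll,
        converged=True,
        event_times=uniq_t,
        baseline_subhazard=dh,
    )


# ---------------------------------------------------------------------------
# Restricted cubic splines
# ---------------------------------------------------------------------------

#: Harrell's symmetric knot quantiles per knot count.
_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


def harrell_knots(x, k: int) -> np.ndarray:
    """Knot locations at Harrell's symmetric sample quantiles."""
    if k not in _KNOT_QUANTILES:
        raise ValueError(f"knot count must be in {sorted(_KNOT_QUANTILES)}")
    knots = np.quantile(np.asarray(x, float), _KNOT_QUANTILES[k], method="linear")
    if len(np.unique(knots)) != k:
        raise ValueError("duplicate knots; exposure too discrete for this knot count")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis, truncated-power form.

    ``k`` knots give ``k-1`` columns: the identity (linear term) plus
    ``k-2`` nonlinear terms

        c_j(x) = [ (x-t_j)+^3
                   - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
                   + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1}) ] / (t_k-t_1)^2,

    which are linear beyond the boundary knots and twice continuously
    differentiable at every knot.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing")
    k = len(t)
    if k < 3:
        raise ValueError("at least 3 knots required")
    norm = (t[-1] - t[0]) ** 2

    def plus3(v):
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        c = (
            plus3(x - t[j])
            - plus3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + plus3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / norm
        cols.append(c)
    return np.column_stack(cols)


@dataclass
class SplineFit:
    """Minimum-AIC restricted-cubic-spline dose-response fit."""

    knot_count: int
    knot_locations: np.ndarray
    spline_coefs: np.ndarray
    spline_cov: np.ndarray
    aic: float
    reference_value: float
    nonlinearity_p: float
    aic_by_knots: dict
    cox_fit: CoxFit = field(repr=False)

    def log_hazard_ratio(self, x):
        b = rcs_basis(np.atleast_1d(np.asarray(x, float)), self.knot_locations)
        b_ref = rcs_basis(np.array([self.reference_value]), self.knot_locations)
        out = (b - b_ref) @ self.spline_coefs
        return out if np.ndim(x) else float(out[0])

    def hazard_ratio(self, x):
        return np.exp(self.log_hazard_ratio(x))


def fit_dose_response(
    df: pd.DataFrame,
    exposure: str,
    covariates=(),
    duration_col: str = "time",
    event_col: str = "event",
    knot_range=(3, 7),
) -> SplineFit:
    """Cox dose-response with RCS in the exposure; min-AIC knot count.

    Fits one Cox model per candidate knot count (knots at Harrell
    quantiles of the exposure), keeps the minimum-AIC fit, anchors the
    hazard-ratio curve at the cohort median exposure, and reports a Wald
    test that all nonlinear spline coefficients are zero.
    """
    x = df[exposure].to_numpy(float)
    ref = float(np.median(x))
    best = None
    aics = {}
    last_err = None
    for k in range(knot_range[0], knot_range[1] + 1):
        try:
            knots = harrell_knots(x, k)
            basis = rcs_basis(x, knots)
            work = df.copy()
            cols = [f"{exposure}_rcs{i}" for i in range(basis.shape[1])]
            for i, c in enumerate(cols):
                work[c] = basis[:, i]
            fit = fit_cox_model(
                work, cols, covariates, duration_col=duration_col, event_col=event_col
            )
        except (ValueError, KeyError) as err:
            last_err = err
            continue
        aic = -2.0 * fit.log_likelihood + 2.0 * len(fit.summary)
        aics[k] = aic
        if best is None or aic < best[0]:
            best = (aic, k, knots, cols, fit)
    if best is None:
        raise ValueError(f"no candidate spline fit converged (last error: {last_err})")
    aic, k, knots, cols, fit = best
    coefs = fit.summary.loc[cols, "coef"].to_numpy()
    cov_full = fit.model.variance_matrix_
    cov = cov_full.loc[cols, cols].to_numpy()
    nl = coefs[1:]
    nl_cov = cov[1:, 1:]
    wald = float(nl @ np.linalg.solve(nl_cov, nl))
    p_nl = float(stats.chi2.sf(wald, df=len(nl)))
    return SplineFit(
        knot_count=k,
        knot_locations=knots,
        spline_coefs=coefs,
        spline_cov=cov,
        aic=aic,
        reference_value=ref,
        nonlinearity_p=p_nl,
        aic_by_knots=aics,
        cox_fit=fit,
    )


def adjusted_cumulative_curve(
    df: pd.DataFrame,
    group_col: str,
    covariates=(),
    entry_col: str = "age_entry",
    exit_col: str = "age_exit",
    event_col: str = "event",
    age_grid=None,
) -> pd.DataFrame:
    """Marginally standardized cumulative-risk curves on the attained-age
    timescale (g-computation).

    Fits a Cox model with age as the timescale (left truncation at entry
    age), then for each exposure group sets every participant's group to
    that level, averages the model-implied survival over the observed
    covariate distribution, and reports cumulative risk 1 - S(age)
    conditional on being event-free at the first grid age.  Curves are
    truncated to the observed age range.
    """
    fit = fit_cox_model(
        df,
        group_col,
        covariates,
        duration_col=exit_col,
        event_col=event_col,
        entry_col=entry_col,
    )
    groups = (
        list(df[group_col].cat.categories)
        if isinstance(df[group_col].dtype, pd.CategoricalDtype)
        else sorted(pd.unique(df[group_col]))
    )
    lo, hi = float(df[entry_col].min()), float(df[exit_col].max())
    if age_grid is None:
        age_grid = np.linspace(lo, hi, 101)
    else:
        age_grid = np.asarray(age_grid, float)
        if age_grid.min() < lo or age_grid.max() > hi:
            warnings.warn("age grid truncated to the observed age range")
            age_grid = age_grid[(age_grid >= lo) & (age_grid <= hi)]

    # baseline cumulative hazard on the grid (design at 0 => exp(lp) weights)
    bch = fit.model.baseline_cumulative_hazard_
    h_times = bch.index.to_numpy(float)
    h_vals = bch.iloc[:, 0].to_numpy(float)
    idx = np.searchsorted(h_times, age_grid, side="right") - 1
    H0 = np.where(idx >= 0, h_vals[np.clip(idx, 0, None)], 0.0)
    H0 = H0 - H0[0]  # risk accrues from the first grid age

    design_cols = list(fit.summary.index)
    beta = fit.summary["coef"].to_numpy()
    group_dummy_cols = [c for c in design_cols if c.startswith(f"{group_col}_")]

    out = {"age": age_grid}
    base = fit.data[design_cols].copy()
    # lifelines centers covariates at their training means
    means = fit.model._norm_mean.reindex(design_cols).to_numpy(float)
    for g in groups:
        cf = base.copy()
        for c in group_dummy_cols:
            cf[c] = 1.0 if c == f"{group_col}_{g}" else 0.0
        lp = (cf.to_numpy(float) - means) @ beta
        surv = np.exp(-np.outer(H0, np.exp(lp)))  # ages x subjects
        out[str(g)] = 1.0 - surv.mean(axis=1)
    return pd.DataFrame(out)


def quartile_hr_table(
    df: pd.DataFrame,
    quartile_col: str,
    covariates=(),
    duration_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Hazard ratios across quartiles with Q1 as the reference row."""
    fit = fit_cox_model(df, quartile_col, covariates, duration_col, event_col)
    rows = [{"stratum": "Q1", "hr": 1.0, "hr_lower": np.nan, "hr_upper": np.nan, "p": np.nan}]
    for q in ("Q2", "Q3", "Q4"):
        term = f"{quartile_col}_{q}"
        if term in fit.summary.index:
            s = fit.summary.loc[term]
            rows.append(
                {"stratum": q, "hr": s["hr"], "hr_lower": s["hr_lower"],
                 "hr_upper": s["hr_upper"], "p": s["p"]}
            )
    return pd.DataFrame(rows)
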