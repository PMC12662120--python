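"""Crude and marginally standardized incidence rates, contrasts, VIF
diagnostics and the multiplicity threshold.

Crude rates are events per 10,000 person-years with exact Poisson
confidence intervals.  Adjusted rates use a Poisson regression with a
log person-time offset over the exposure strata and confounders; each
stratum's standardized rate is the average, over every cohort member,
of the model-predicted rate had that member been in the stratum
(g-computation / marginal standardization).  Confidence intervals for
adjusted rates, rate differences and rate ratios come from a seeded
participant-level nonparametric bootstrap with percentile intervals.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from vhd_aging.survival_models import build_design

__all__ = [
    "event_proportion",
    "crude_incidence_rate",
    "adjusted_incidence_rate",
    "rate_contrasts",
    "rate_table",
    "vif_diagnostics",
    "bonferroni_threshold",
    "PER",
]

#: Rate denominator convention: per 10,000 person-years.
PER = 10_000.0


def event_proportion(events: int, denominator: int) -> float:
    """Event percentage, rounded half-up to 2 decimals (table format)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= events <= denominator):
        raise ValueError("events must be between 0 and denominator")
    pct = decimal.Decimal(100 * events) / decimal.Decimal(denominator)
    return float(pct.quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))


def crude_incidence_rate(events: int, person_years: float, alpha: float = 0.05):
    """Crude rate per 10,000 person-years with the exact Poisson CI.

    Returns ``(rate, lower, upper)``.
    """
    if events < 0 or person_years <= 0:
        raise ValueError("events must be >= 0 and person_years > 0")
    rate = PER * events / person_years
    if events == 0:
        lower = 0.0
    else:
        lower = PER * stats.chi2.ppf(alpha / 2, 2 * events) / 2 / person_years
    upper = PER * stats.chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2 / person_years
    return rate, lower, upper


def _design_arrays(df, stratum_col, covariates, duration_col, event_col, strata):
    """Assemble (X, y, log person-time offset, stratum column slice) once;
    column 0 is the intercept, columns 1..k-1 the stratum indicators."""
    n = len(df)
    n_strata = len(strata)
    X = np.ones((n, n_strata))
    for j, s in enumerate(strata[1:], start=1):
        X[:, j] = (df[stratum_col] == s).to_numpy()
    if covariates:
        design = build_design(df, list(covariates))
        X = np.column_stack([X, design.to_numpy(float)])
    y = (df[event_col] == 1).to_numpy(float)
    offset = np.log(df[duration_col].to_numpy(float))
    return X, y, offset


def _standardized_rates_arrays(X, y, offset, n_strata):
    """Fit the Poisson rate model and return the g-computation
    standardized rate per stratum (per person-year)."""
    res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    if not res.converged:
        raise ValueError("Poisson rate model did not converge")
    beta = np.asarray(res.params)
    base_lp = X @ beta - X[:, 1:n_strata] @ beta[1:n_strata]
    rates = np.empty(n_strata)
    rates[0] = np.mean(np.exp(base_lp))
    for j in range(1, n_strata):
        rates[j] = np.mean(np.exp(base_lp + beta[j]))
    return rates


def adjusted_incidence_rate(
    df: pd.DataFrame,
    stratum_col: str,
    covariates=(),
    duration_col: str = "time",
    event_col: str = "event",
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
):
    """Marginally standardized incidence rates per stratum.

    Returns ``(table, boot_rates)`` where ``table`` has one row per
    stratum with the point rate (per 10,000 person-years) and percentile
    bootstrap CI, and ``boot_rates`` is the (n_boot x n_strata) matrix of
    bootstrap replicate rates for reuse in :func:`rate_contrasts`.

    With an empty covariate set the standardized rate collapses to the
    crude rate in every stratum.  A stratum with zero events yields rate
    ~0 and is flagged.
    """
    strata = (
        list(df[stratum_col].cat.categories)
        if isinstance(df[stratum_col].dtype, pd.CategoricalDtype)
        else sorted(pd.unique(df[stratum_col]))
    )
    X, y, offset = _design_arrays(df, stratum_col, covariates, duration_col, event_col, strata)
    k = len(strata)
    point = dict(zip(strata, _standardized_rates_arrays(X, y, offset, k)))

    rng = np.random.default_rng(seed)
    n = len(df)
    boot = np.empty((n_boot, k))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            boot[b] = _standardized_rates_arrays(X[idx], y[idx], offset[idx], k)
        except (ValueError, np.linalg.LinAlgError):
            boot[b] = np.nan
    lo = np.nanquantile(boot, alpha / 2, axis=0)
    hi = np.nanquantile(boot, 1 - alpha / 2, axis=0)

    rows = []
    for j, s in enumerate(strata):
        n_ev = int(((df[stratum_col] == s) & (df[event_col] == 1)).sum())
        rows.append(
            {
                "stratum": s,
                "events": n_ev,
                "person_years": float(df.loc[df[stratum_col] == s, duration_col].sum()),
                "adjusted_rate": PER * point[s],
                "adjusted_rate_lower": PER * lo[j],
                "adjusted_rate_upper": PER * hi[j],
                "zero_events": n_ev == 0,
            }
        )
    return pd.DataFrame(rows), PER * boot


def rate_contrasts(table: pd.DataFrame, boot_rates: np.ndarray, reference=None, alpha=0.05):
    """Rate differences and ratios versus the reference stratum.

    CIs are percentile intervals over the same bootstrap replicates used
    for the adjusted rates, so all three quantities are mutually
    consistent.
    """
    strata = list(table["stratum"])
    ref = strata[0] if reference is None else reference
    if ref not in strata:
        raise ValueError(f"reference stratum {ref!r} not present")
    j_ref = strata.index(ref)
    ref_rate = table["adjusted_rate"].iloc[j_ref]
    if ref_rate == 0:
        raise ZeroDivisionError("reference stratum has zero rate; ratio undefined")
    out = table.copy()
    diffs = boot_rates - boot_rates[:, [j_ref]]
    ratios = boot_rates / boot_rates[:, [j_ref]]
    out["rate_difference"] = out["adjusted_rate"] - ref_rate
    out["rate_difference_lower"] = np.nanquantile(diffs, alpha / 2, axis=0)
    out["rate_difference_upper"] = np.nanquantile(diffs, 1 - alpha / 2, axis=0)
    out["rate_ratio"] = out["adjusted_rate"] / ref_rate
    out["rate_ratio_lower"] = np.nanquantile(ratios, alpha / 2, axis=0)
    out["rate_ratio_upper"] = np.nanquantile(ratios, 1 - alpha / 2, axis=0)
    # the reference contrasts itself: difference 0, ratio 1, no interval
    for col in ("rate_difference_lower", "rate_difference_upper"):
        out.loc[out.index[j_ref], col] = 0.0
    for col in ("rate_ratio_lower", "rate_ratio_upper"):
        out.loc[out.index[j_ref], col] = 1.0
    return out


def rate_table(
    df: pd.DataFrame,
    stratum_col: str,
    covariates=(),
    duration_col: str = "time",
    event_col: str = "event",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-stratum rate table: crude + adjusted rates and contrasts."""
    adj, boot = adjusted_incidence_rate(
        df, stratum_col, covariates, duration_col, event_col, n_boot=n_boot, seed=seed
    )
    crude = []
    for _, row in adj.iterrows():
        r, lo, hi = crude_incidence_rate(int(row["events"]), row["person_years"])
        crude.append((r, lo, hi))
    adj["crude_rate"], adj["crude_rate_lower"], adj["crude_rate_upper"] = zip(*crude)
    return rate_contrasts(adj, boot)


def vif_diagnostics(df: pd.DataFrame, covariates) -> pd.Series:
    """Variance inflation factor per covariate: VIF_j = 1 / (1 - R2_j)
    from regressing covariate j on all the others (with intercept).
    Perfect collinearity reports ``inf``."""
    design = build_design(df, list(covariates))
    if design.shape[1] < 2:
        raise ValueError("at least two covariate columns required")
    X = design.to_numpy(float)
    n, p = X.shape
    out = {}
    for j in range(p):
        y = X[:, j]
        A = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            raise ValueError(f"covariate {design.columns[j]!r} is constant")
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[design.columns[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def bonferroni_threshold(alpha: float = 0.05, m: int = 6) -> float:
    """Bonferroni-corrected significance threshold alpha/m, 4 decimals."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return round(alpha / m, 4)
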