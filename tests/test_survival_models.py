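"""Survival-model tests: brute-force partial-likelihood oracles for Cox
and Fine-Gray on tiny datasets, proportional-hazards diagnostics,
restricted-cubic-spline properties and marginal adjusted curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from vhd_aging import survival_models as sv


def cox_partial_loglik_oracle(beta, time, event, x):
    """Longhand Breslow partial likelihood for a single covariate,
    written independently of the package implementation."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] != 1:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def fine_gray_loglik_oracle(beta, time, status, x):
    """Longhand weighted Fine-Gray partial likelihood with Kaplan-Meier
    censoring weights, fully written out with explicit loops."""
    n = len(time)

    def g_left(t):  # left-continuous censoring KM
        g = 1.0
        for u in sorted(set(time)):
            if u >= t:
                break
            at_risk = sum(time[j] >= u for j in range(n))
            d_c = sum((time[j] == u) and (status[j] == 0) for j in range(n))
            if at_risk > 0:
                g *= 1.0 - d_c / at_risk
        return g

    ll = 0.0
    for i in range(n):
        if status[i] != 1:
            continue
        t_i = time[i]
        denom = 0.0
        for j in range(n):
            if time[j] >= t_i:
                w = 1.0
            elif status[j] == 2:
                w = g_left(t_i) / g_left(time[j])
            else:
                continue
            denom += w * np.exp(beta * x[j])
        ll += beta * x[i] - np.log(denom)
    return ll


class TestCox:
    def test_eight_subject_toy_matches_brute_force(self):
        """beta-hat equals the grid/numeric maximizer of the hand-written
        partial likelihood to 1e-4 (no ties, one binary covariate)."""
        time = np.array([1.1, 2.3, 3.1, 4.7, 5.2, 6.9, 8.0, 9.4])
        event = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        df = pd.DataFrame({"time": time, "event": event, "x": x})
        fit = sv.fit_cox_model(df, "x", (), min_events=1)
        res = minimize(
            lambda b: -cox_partial_loglik_oracle(b[0], time, event, x),
            [0.0],
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12},
        )
        assert fit.summary.loc["x", "coef"] == pytest.approx(res.x[0], abs=1e-4)

    def test_duplicating_subjects_preserves_beta(self):
        """Duplicating every subject multiplies the Breslow partial
        likelihood by a beta-free constant, so beta-hat is unchanged and
        the standard error shrinks.  (The Efron tie correction does not
        share this exact invariance, so the Breslow path is used.)"""
        rng = np.random.default_rng(8)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        df = pd.DataFrame({"time": t, "status": 1, "x": x})
        fit1 = sv.fit_fine_gray(df, ["x"])  # no competing events: Breslow Cox
        fit2 = sv.fit_fine_gray(pd.concat([df, df], ignore_index=True), ["x"])
        assert fit2.summary.loc["x", "coef"] == pytest.approx(
            fit1.summary.loc["x", "coef"], abs=1e-6
        )
        assert fit2.summary.loc["x", "se"] < fit1.summary.loc["x", "se"]

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 0, 0], "x": [1.0, 0.0, 1.0]})
        with pytest.raises(ValueError, match="events"):
            sv.fit_cox_model(df, "x", ())

    def test_ci_is_exp_of_beta_pm_1p96_se(self, as_analysis):
        fit = sv.fit_cox_model(as_analysis, "phenoage_baa_z", ("sex",))
        row = fit.summary.loc["phenoage_baa_z"]
        assert row["hr_lower"] == pytest.approx(
            np.exp(row["coef"] - 1.959963984540054 * row["se"]), rel=1e-10
        )


class TestSchoenfeld:
    def test_type_i_error_calibrated(self):
        """Under proportional hazards the per-term rejection rate at
        alpha = 0.05 stays within [0.02, 0.09]."""
        rejections = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(500 + rep)
            n = 200
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.4 * x))
            c = rng.uniform(0, 3.0, n)
            df = pd.DataFrame(
                {"time": np.minimum(t, c), "event": (t <= c).astype(int), "x": x}
            )
            fit = sv.fit_cox_model(df, "x", (), min_events=5)
            p = sv.schoenfeld_ph_test(fit).loc["x", "p"]
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_detects_sign_flipping_effect(self):
        """A strong effect whose sign flips at the median follow-up is
        flagged (p < 0.05) in at least 80% of replicates."""
        hits = 0
        reps = 40
        for rep in range(reps):
            rng = np.random.default_rng(900 + rep)
            n = 800
            x = (rng.random(n) < 0.5).astype(float)
            # piecewise hazard: HR e^{+1} before t=1, e^{-1} after
            t = rng.exponential(np.exp(-1.0 * x))
            late = t > 1.0
            # rescaling residual time by e^{+2x} turns the late hazard
            # from e^{+x} into e^{-x}: the effect reverses sign
            t[late] = 1.0 + (t[late] - 1.0) * np.exp(2.0 * x[late])
            df = pd.DataFrame({"time": np.minimum(t, 4.0), "event": (t <= 4.0).astype(int), "x": x})
            fit = sv.fit_cox_model(df, "x", (), min_events=5)
            hits += sv.schoenfeld_ph_test(fit).loc["x", "p"] < 0.05
        assert hits / reps >= 0.8

    def test_residual_means_are_zero(self, as_analysis):
        fit = sv.fit_cox_model(as_analysis, "phenoage_baa_z", ("sex",))
        resid = fit.model.compute_residuals(fit.data, kind="schoenfeld")
        assert np.abs(resid.mean()).max() < 1e-6


class TestFineGray:
    def test_collapses_to_cox_without_competing_events(self):
        rng = np.random.default_rng(2)
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.6 * x))
        df = pd.DataFrame({"time": t, "status": 1, "x": x})
        fg = sv.fit_fine_gray(df, ["x"])
        # exact Cox (Breslow) maximizer via an independent 1-d optimizer
        from scipy.optimize import minimize_scalar

        order = np.argsort(t)
        ts, xs = t[order], x[order]

        def nll(b):
            exb = np.exp(b * xs)
            suffix = np.cumsum(exb[::-1])[::-1]
            return -(np.sum(b * xs) - np.sum(np.log(suffix)))

        exact = minimize_scalar(nll, bounds=(-3, 3), method="bounded",
                                options={"xatol": 1e-12}).x
        assert fg.summary.loc["x", "coef"] == pytest.approx(exact, abs=1e-6)
        # and agrees with the lifelines (Efron; no ties here) fit
        cox = sv.fit_cox_model(df.assign(event=1), "x", ())
        assert fg.summary.loc["x", "coef"] == pytest.approx(
            cox.summary.loc["x", "coef"], abs=1e-4
        )

    def test_ten_subject_toy_matches_longhand_likelihood(self):
        """Coefficient equals the numeric maximizer of the longhand
        weighted partial likelihood to 4 decimals."""
        time = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0])
        status = np.array([1, 0, 2, 1, 0, 1, 2, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        df = pd.DataFrame({"time": time, "status": status, "x": x})
        fg = sv.fit_fine_gray(df, ["x"])
        res = minimize(
            lambda b: -fine_gray_loglik_oracle(b[0], time, status, x),
            [0.0],
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-13},
        )
        assert fg.summary.loc["x", "coef"] == pytest.approx(res.x[0], abs=1e-4)

    def test_cumulative_incidence_matches_aalen_johansen(self):
        """Null-covariate CIF agrees with the Aalen-Johansen estimator
        within 1e-3 at every event time."""
        from lifelines import AalenJohansenFitter

        rng = np.random.default_rng(7)
        n = 2000
        t1 = rng.exponential(10, n)
        t2 = rng.exponential(15, n)
        c = rng.uniform(0, 12, n)
        time = np.minimum.reduce([t1, t2, c])
        status = np.where(t1 <= np.minimum(t2, c), 1, np.where(t2 <= c, 2, 0))
        df = pd.DataFrame({"time": time, "status": status, "x": rng.normal(size=n) * 1e-8})
        fg = sv.fit_fine_gray(df, ["x"])
        aj = AalenJohansenFitter(calculate_variance=False)
        aj.fit(df["time"], df["status"], event_of_interest=1)
        aj_t = aj.cumulative_density_.index.to_numpy()
        aj_v = aj.cumulative_density_.iloc[:, 0].to_numpy()
        idx = np.searchsorted(aj_t, fg.event_times, side="right") - 1
        cif_aj = np.where(idx >= 0, aj_v[np.clip(idx, 0, None)], 0.0)
        cif_fg = fg.cumulative_incidence(fg.event_times)
        assert np.max(np.abs(cif_fg - cif_aj)) < 1e-3

    def test_status_coding_validated(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "status": [1, 3], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="status"):
            sv.fit_fine_gray(df, ["x"])


class TestRCSBasis:
    def test_linear_tail_below_first_knot(self):
        knots = np.array([-1.0, 0.0, 1.0, 2.0])
        x = np.array([-3.0, -2.0, -1.5])
        b = sv.rcs_basis(x, knots)
        assert np.allclose(b[:, 0], x)
        assert np.allclose(b[:, 1:], 0.0)

    def test_three_knot_truncated_power_oracle(self):
        """Basis values at probe points match an independent evaluation
        of the truncated-power formula."""
        knots = np.array([-1.0, 0.5, 2.0])
        probes = np.array([-2.0, -0.5, 0.7, 1.9, 3.5])
        b = sv.rcs_basis(probes, knots)
        t1, t2, t3 = knots
        for i, x in enumerate(probes):
            p3 = lambda v: max(v, 0.0) ** 3
            expected = (
                p3(x - t1)
                - p3(x - t2) * (t3 - t1) / (t3 - t2)
                + p3(x - t3) * (t2 - t1) / (t3 - t2)
            ) / (t3 - t1) ** 2
            assert b[i, 0] == pytest.approx(x)
            assert b[i, 1] == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_second_derivative_continuity_at_knots(self):
        knots = np.array([-1.0, 0.0, 1.5, 3.0])
        h = 1e-5
        for t in knots:
            x = np.array([t - 2 * h, t - h, t, t + h, t + 2 * h])
            b = sv.rcs_basis(x, knots)
            d2 = (b[:-2] - 2 * b[1:-1] + b[2:]) / h**2
            assert np.allclose(d2[0], d2[-1], atol=1e-3)

    def test_linear_tails_beyond_last_knot(self):
        knots = np.array([-1.0, 0.0, 1.0, 2.0])
        x = np.array([3.0, 4.0, 5.0])
        b = sv.rcs_basis(x, knots)
        # all columns affine in x beyond the boundary knot
        for j in range(b.shape[1]):
            diffs = np.diff(b[:, j])
            assert diffs[0] == pytest.approx(diffs[1], rel=1e-9)

    def test_affine_transform_spans_same_space(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        knots = np.quantile(x, [0.1, 0.5, 0.9])
        b1 = np.column_stack([np.ones(200), sv.rcs_basis(x, knots)])
        y = 2.0 + 3.0 * x
        b2 = np.column_stack([np.ones(200), sv.rcs_basis(y, 2.0 + 3.0 * knots)])
        # project each column of b2 onto span(b1): residuals vanish
        proj, *_ = np.linalg.lstsq(b1, b2, rcond=None)
        assert np.allclose(b1 @ proj, b2, atol=1e-8)

    def test_duplicate_knots_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            sv.rcs_basis(np.array([0.0, 1.0]), np.array([0.0, 0.0, 1.0]))


class TestDoseResponse:
    def _sim_linear(self, seed, n=1500, beta=0.4):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-beta * x))
        c = rng.uniform(0, 4.0, n)
        return pd.DataFrame(
            {"time": np.minimum(t, c), "event": (t <= c).astype(int), "x": x}
        )

    def test_hazard_ratio_is_one_at_median(self):
        df = self._sim_linear(3)
        fit = sv.fit_dose_response(df, "x", (), knot_range=(3, 5))
        assert fit.hazard_ratio(fit.reference_value) == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(fit.knot_locations) > 0)
        assert 3 <= fit.knot_count <= 5

    def test_linear_truth_selects_three_knots_majority(self):
        """AIC selection prefers the most parsimonious spline when the
        log-hazard truly is linear."""
        chosen = [
            sv.fit_dose_response(self._sim_linear(40 + r, n=2000), "x", ()).knot_count
            for r in range(10)
        ]
        assert sum(k == 3 for k in chosen) > 5

    def test_threshold_effect_detected_as_nonlinear(self):
        rng = np.random.default_rng(77)
        n = 8000
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.8 * (x > 0.5)))
        c = rng.uniform(0, 4.0, n)
        df = pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int), "x": x})
        fit = sv.fit_dose_response(df, "x", ())
        assert fit.nonlinearity_p < 0.001


@pytest.fixture(scope="module")
def aged(as_analysis):
    d = as_analysis.copy()
    d["age_entry"] = d["chronological_age"]
    d["age_exit"] = d["chronological_age"] + d["time"]
    return d


class TestAdjustedCurves:

    def test_survival_starts_at_one_and_risk_monotone(self, aged):
        curves = sv.adjusted_cumulative_curve(
            aged, "phenoage_quartile", ("sex",), age_grid=np.linspace(45, 80, 20)
        )
        for q in ("Q1", "Q4"):
            assert curves[q].iloc[0] == pytest.approx(0.0, abs=1e-12)
            assert (np.diff(curves[q]) >= -1e-12).all()

    def test_marginal_curve_equals_mean_of_individual_curves(self, aged):
        """g-computation output equals brute-force per-subject averaging
        of lifelines-predicted survival curves."""
        sub = aged.iloc[:4000]
        grid = np.linspace(46, 78, 9)
        curves = sv.adjusted_cumulative_curve(sub, "phenoage_quartile", ("sex",), age_grid=grid)
        fit = sv.fit_cox_model(
            sub, "phenoage_quartile", ("sex",),
            duration_col="age_exit", event_col="event", entry_col="age_entry",
        )
        cf = fit.data[list(fit.summary.index)].copy()
        for c in cf.columns:
            if c.startswith("phenoage_quartile_"):
                cf[c] = 1.0 if c.endswith("Q4") else 0.0
        surv = fit.model.predict_survival_function(cf, times=grid)
        # conditional on surviving to the first grid age, subject by subject
        surv_cond = surv.div(surv.iloc[0], axis=1)
        brute = 1.0 - surv_cond.mean(axis=1).to_numpy()
        assert np.allclose(curves["Q4"].to_numpy(), brute, atol=1e-10)

    def test_null_exposure_collapses_groups(self):
        rng = np.random.default_rng(11)
        n = 3000
        age0 = rng.uniform(40, 70, n)
        t = rng.exponential(20, n)
        df = pd.DataFrame(
            {
                "age_entry": age0,
                "age_exit": age0 + np.minimum(t, 12.0),
                "event": (t <= 12.0).astype(int),
                "g": pd.Categorical(rng.choice(["Q1", "Q2"], n)),
                "z": rng.normal(size=n),
            }
        )
        curves = sv.adjusted_cumulative_curve(
            df, "g", ("z",), age_grid=np.linspace(42, 78, 15)
        )
        assert np.max(np.abs(curves["Q1"] - curves["Q2"])) < 0.03


def test_model_specs_enumerate_documented_covariates():
    spec1 = sv.ModelSpec(exposure="phenoage_baa_z", model_id="Model1")
    assert set(spec1.covariates) == set(sv.MODEL1_COVARIATES)
    spec2 = sv.ModelSpec(exposure="phenoage_baa_z", model_id="Model2")
    extra = set(spec2.covariates) - set(spec1.covariates)
    assert "antihypertensive_medication" not in extra
    assert "lipid_lowering_medication" not in extra
    assert {"hypertension", "diabetes", "antidiabetic_medication"} <= extra
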