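"""Survival machinery: Kaplan-Meier against hand product-limit oracles, Cox
against brute-force likelihood maximization and lifelines, score-test /
log-rank equivalence, screen and model-building rules, and the power formula."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from dasikit.errors import ConvergenceError, ValidationError
from dasikit.survival import (
    CovariateSpec,
    ScreenResult,
    _expand_design,
    build_multivariable,
    chi_square_independence,
    compare_groups,
    cox_fit,
    cox_score_test,
    km_fit,
    logrank_test,
    min_detectable_hr,
    univariate_screen,
)


class TestKaplanMeier:
    def test_censored_fixture_matches_hand_product_limit(self):
        # deaths at 6,6; censor at 7; death at 9:
        # S(6) = 1 - 2/4 = 0.5; S(9) = 0.5 * (1 - 1/1) = 0
        c = km_fit([6, 6, 7, 9], [1, 1, 0, 1])
        assert c.survival_at(6) == pytest.approx(0.5, abs=1e-12)
        assert c.survival_at(9) == pytest.approx(0.0, abs=1e-12)
        assert c.median == 6.0
        # Greenwood at t=6: S^2 * d/(n(n-d)) = 0.25 * 2/(4*2)
        assert c.variance[0] == pytest.approx(0.0625, abs=1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(42)
        t = rng.exponential(10.0, size=50)
        c = km_fit(t, np.ones(50, bool))
        for q in np.linspace(t.min(), t.max(), 23):
            assert c.survival_at(q) == pytest.approx(np.mean(t > q), abs=1e-12)
        assert c.survival_at(2.0) == pytest.approx(np.mean(t > 2.0), abs=1e-12)

    def test_uncensored_quartet(self):
        c = km_fit([1, 2, 3, 4], [1, 1, 1, 1])
        assert c.survival_at(2) == pytest.approx(0.5)
        assert c.median == 2.0

    def test_all_censored_curve_flat_median_undefined(self):
        c = km_fit([5, 6, 7], [0, 0, 0])
        assert c.median is None
        assert c.n_events == 0

    def test_median_ci_can_be_undetermined(self):
        # late plateau: upper band never crosses 0.5
        t = [10, 20, 30, 40, 50, 60, 70, 80]
        e = [1, 1, 1, 1, 0, 0, 0, 0]
        c = km_fit(t, e)
        assert c.median_ci[1] is None

    def test_invalid_samples_rejected(self):
        with pytest.raises(ValidationError):
            km_fit([], [])
        with pytest.raises(ValidationError):
            km_fit([0.0, 1.0], [1, 1])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t, e = [1.0, 2.0, 3.0], [1, 1, 0]
        r = logrank_test([(t, e), (t, e)])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_three_identical_groups_df_two(self):
        t, e = [1.0, 2.0, 3.0], [1, 1, 1]
        r = logrank_test([(t, e), (t, e), (t, e)])
        assert r.df == 2
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_group_validation(self):
        with pytest.raises(ValidationError):
            logrank_test([([1.0], [1])])
        with pytest.raises(ValidationError):
            logrank_test([([1.0], [1]), ([], [])])


def _hand_partial_loglik(beta, t, e, x):
    """Independent Breslow partial likelihood for untied 1-covariate data."""
    ll = 0.0
    for i in range(len(t)):
        if not e[i]:
            continue
        risk = [j for j in range(len(t)) if t[j] >= t[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


class TestCox:
    def test_exchangeable_groups_give_null_coefficient(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0], bool)
        x = np.array([0, 0, 0, 1, 1, 1.0])
        f = cox_fit(t, e, x)
        assert f.coef[0] == pytest.approx(0.0, abs=1e-8)
        assert f.hazard_ratio[0] == pytest.approx(1.0, abs=1e-8)

    def test_six_subject_fixture_matches_grid_search(self):
        t = [2.0, 5.0, 9.0, 1.0, 4.0, 8.0]  # deaths interleaved across groups
        e = [1, 1, 0, 1, 1, 1]
        x = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
        grid = np.linspace(-3, 3, 120001)
        lls = [_hand_partial_loglik(b, t, e, x) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        f = cox_fit(t, e, x, ties="breslow")
        assert f.coef[0] == pytest.approx(beta_grid, abs=1e-4)

    def test_matches_lifelines_on_tied_data(self):
        rng = np.random.default_rng(7)
        n = 120
        X = rng.normal(size=(n, 2))
        t = np.ceil(rng.exponential(20.0 / np.exp(0.5 * X[:, 0] - 0.3 * X[:, 1])))
        e = rng.random(n) < 0.8
        f = cox_fit(t, e, X, names=["a", "b"], ties="efron")
        df = pd.DataFrame({"t": t, "e": e.astype(int), "a": X[:, 0], "b": X[:, 1]})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert f.coef == pytest.approx(cph.params_.to_numpy(), abs=1e-5)
        assert f.se == pytest.approx(cph.standard_errors_.to_numpy(), abs=1e-5)
        assert f.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_score_test_equals_logrank_on_untied_data(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        e = np.ones(8, bool)
        g = np.array([0, 1, 0, 1, 0, 1, 1, 0], float)
        stat, df, _ = cox_score_test(t, e, g, ties="breslow")
        lr = logrank_test([(t[g == 0], e[g == 0]), (t[g == 1], e[g == 1])])
        assert df == 1
        assert stat == pytest.approx(lr.statistic, abs=1e-8)

    def test_complete_separation_raises_diagnostic(self):
        t = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        e = [1, 1, 1, 1, 1, 1]
        x = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
        with pytest.raises(ConvergenceError, match="monotone|separation"):
            cox_fit(t, e, x)

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        X = np.column_stack([x, 2.0 * x])
        t = np.ceil(rng.exponential(10, size=20)) + 1
        with pytest.raises(ValidationError, match="collinear"):
            cox_fit(t, np.ones(20, bool), X, names=["x", "x_twice"])

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            cox_fit([1.0, 2.0, 3.0], [1, 1, 1], [1.0, 1.0, 1.0])

    def test_hr_and_ci_consistent_with_coef(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        t = np.ceil(rng.exponential(10.0 / np.exp(0.4 * x)))
        f = cox_fit(t, np.ones(60, bool), x)
        assert f.hazard_ratio[0] == pytest.approx(math.exp(f.coef[0]), rel=1e-12)
        assert f.ci_lower[0] < f.hazard_ratio[0] < f.ci_upper[0]
        assert 0.0 <= f.p_values[0] <= 1.0


class TestScreenAndModel:
    def _frame(self, n=160, seed=2):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        t = np.ceil(rng.exponential(100.0 / np.exp(0.8 * x)))
        cmax = np.quantile(t, 0.7)
        return pd.DataFrame({
            "survival_time": np.minimum(t, cmax), "event": t <= cmax,
            "x": x, "noise": noise, "flat": 1.0,
        })

    def test_screen_selects_signal_not_constant(self):
        df = self._frame()
        reg = [
            CovariateSpec("x", "x"),
            CovariateSpec("noise", "noise"),
            CovariateSpec("flat", "flat"),
        ]
        res = univariate_screen(df, reg)
        assert "x" in res.selected
        assert "flat" in res.degenerate
        note = res.table.loc[res.table["covariate"] == "flat", "note"].iloc[0]
        assert "degenerate" in note

    def test_log_transform_enters_design_as_log(self):
        df = pd.DataFrame({"v": [1.0, math.e, math.e**2]})
        design, _ = _expand_design(df, CovariateSpec("v", "v", log_transform=True))
        assert design["v"].to_numpy() == pytest.approx([0.0, 1.0, 2.0])
        design1, _ = _expand_design(
            df - 1.0, CovariateSpec("v", "v", log_transform=True, log_plus_one=True)
        )
        assert design1["v"].to_numpy() == pytest.approx([0.0, 1.0, 2.0])

    def _collinear_registry(self):
        return [
            CovariateSpec("nlr", "nlr", collinear_group="inflammation", representative=True),
            CovariateSpec("sii", "sii", collinear_group="inflammation"),
            CovariateSpec("wbc", "wbc"),
            CovariateSpec("forcedcov", "forcedcov", forced=True),
        ]

    def test_collinear_group_collapses_to_representative(self):
        rng = np.random.default_rng(9)
        n = 200
        base = rng.normal(size=n)
        df = pd.DataFrame({
            "nlr": base + 0.05 * rng.normal(size=n),
            "sii": base + 0.05 * rng.normal(size=n),
            "wbc": rng.normal(size=n),
            "forcedcov": rng.normal(size=n),
        })
        t = np.ceil(np.exp(3.0 - 0.8 * base + rng.normal(size=n)))
        df["survival_time"] = t
        df["event"] = True
        reg = self._collinear_registry()
        screen = univariate_screen(df, reg)
        assert {"nlr", "sii"} <= set(screen.selected)
        fit, chosen = build_multivariable(df, screen, reg)
        assert "nlr" in chosen and "sii" not in chosen
        assert "forcedcov" in chosen  # forced regardless of significance

    def test_forced_only_model_when_nothing_selected(self):
        rng = np.random.default_rng(11)
        n = 120
        df = pd.DataFrame({
            "nlr": rng.normal(size=n), "sii": rng.normal(size=n),
            "wbc": rng.normal(size=n), "forcedcov": rng.normal(size=n),
            "survival_time": np.ceil(rng.exponential(50, size=n)), "event": True,
        })
        reg = self._collinear_registry()
        screen = ScreenResult(table=pd.DataFrame(), selected=[], degenerate=[])
        fit, chosen = build_multivariable(df, screen, reg)
        assert chosen == ["forcedcov"]

    def test_over_budget_model_raises(self):
        rng = np.random.default_rng(13)
        n = 300
        cols = {f"c{i}": rng.normal(size=n) for i in range(14)}
        df = pd.DataFrame(cols)
        df["survival_time"] = np.ceil(rng.exponential(50, size=n))
        df["event"] = True
        reg = [CovariateSpec(c, c) for c in cols]
        screen = ScreenResult(table=pd.DataFrame(), selected=list(cols), degenerate=[])
        with pytest.raises(ValidationError, match="budget"):
            build_multivariable(df, screen, reg, forced=[], max_covariates=13)


class TestCompareGroups:
    def test_chi_square_matches_textbook_oracle(self):
        # observed DASI band x readmission contingency
        obs = np.array([[25, 54], [69, 64], [38, 16]], float)
        stat, df, p = chi_square_independence(obs)
        # independent oracle: sum (O-E)^2 / E
        rowsum = obs.sum(axis=1, keepdims=True)
        colsum = obs.sum(axis=0, keepdims=True)
        expected = rowsum @ colsum / obs.sum()
        oracle = ((obs - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(oracle, abs=1e-8)
        assert df == 2
        assert p < 0.001

    def test_duplicated_groups_f_zero_and_constant_not_computable(self):
        df = pd.DataFrame({
            "g": ["a"] * 4 + ["b"] * 4,
            "num": [1.0, 2.0, 3.0, 4.0] * 2,   # equal means/variances
            "const": 5.0,
            "cat": ["x", "y"] * 4,
        })
        out = compare_groups(df, "g", ["num", "const"], ["cat"])
        num_row = out[out["variable"] == "num"].iloc[0]
        assert num_row["p_value"] == pytest.approx(1.0)
        const_row = out[out["variable"] == "const"].iloc[0]
        assert const_row["note"] == "not computable"
        assert np.isnan(const_row["p_value"])

    def test_single_group_rejected(self):
        df = pd.DataFrame({"g": ["a", "a"], "num": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            compare_groups(df, "g", ["num"], [])


class TestMinDetectableHR:
    def test_formula_oracle(self):
        # (1.959964 + 0.841621) / sqrt(100 * 0.25) = 0.560317 -> e^0.560317
        assert min_detectable_hr(100, 0.5, 0.05, 0.80) == pytest.approx(1.7512, abs=2e-4)

    def test_half_power_drops_power_quantile(self):
        got = min_detectable_hr(100, 0.5, 0.05, 0.50)
        expect = math.exp(1.959963984540054 / math.sqrt(25.0))
        assert got == pytest.approx(expect, rel=1e-12)

    def test_monotone_in_events(self):
        assert min_detectable_hr(200, 0.5) < min_detectable_hr(100, 0.5)

    @pytest.mark.parametrize("kwargs", [
        {"n_events": 0}, {"n_events": 10, "allocation": 0.0},
        {"n_events": 10, "allocation": 1.0}, {"n_events": 10, "alpha": 0.0},
    ])
    def test_degenerate_inputs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            min_detectable_hr(**kwargs)
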