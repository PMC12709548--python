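"""Behavioral statistics: entropy, lie rate, CR bookkeeping, fits, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from conftest import make_trials
from moraltrace.behavior import (cr_features, fit_psychometric,
                                 fit_random_intercept, lie_rate,
                                 min_detectable_correlation,
                                 power_by_simulation, response_entropy)


class TestEntropy:
    def test_degenerate_endpoints_zero(self):
        assert response_entropy(0.0) == 0.0
        assert response_entropy(1.0) == 0.0

    def test_maximum_at_half(self):
        assert response_entropy(0.5) == pytest.approx(1.0)

    def test_quarter_value(self):
        assert response_entropy(0.25) == pytest.approx(0.8113, abs=5e-5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            response_entropy(1.2)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0))
    def test_symmetry(self, p):
        assert response_entropy(p) == pytest.approx(response_entropy(1 - p))

    def test_concavity_on_grid(self):
        grid = np.linspace(0.0, 1.0, 101)
        h = np.array([response_entropy(p) for p in grid])
        assert np.all(np.diff(h, 2) < 0)


class TestLieRate:
    def test_all_lies(self):
        assert lie_rate(make_trials([1, 1, 1])) == 1.0

    def test_fraction(self):
        choices = [1] * 69 + [0] * 111
        assert lie_rate(make_trials(choices)) == pytest.approx(69 / 180)

    def test_timeouts_excluded_from_denominator(self):
        tr = make_trials([1, 0, 1], timeouts=[False, False, True])
        assert lie_rate(tr) == pytest.approx(0.5)

    def test_all_timeouts_undefined(self):
        tr = make_trials([1], timeouts=[True])
        with pytest.raises(ValueError):
            lie_rate(tr)


class TestCRFeatures:
    def test_running_counts(self):
        # choices lie, honest, lie over runs 1-3: before run 4 the
        # counters read 2 dishonest / 1 honest, relative CR +1
        tr = make_trials([1, 0, 1, 0], runs=[1, 2, 3, 4])
        out = cr_features(tr)
        last = out.iloc[3]
        assert last["cr_incorrect"] == 2
        assert last["cr_correct"] == 1
        assert last["relative_cr"] == 1
        assert last["dishonest_cr"] == 2

    def test_run1_has_no_history(self):
        out = cr_features(make_trials([1, 0], runs=[1, 2]))
        assert out.iloc[0]["relative_cr"] == 0
        assert out.iloc[0]["history"] == 0
        assert out.iloc[1]["history"] == 1

    def test_timeout_does_not_advance_counters(self):
        tr = make_trials([1, 0, 0], runs=[1, 2, 3],
                         timeouts=[False, True, False])
        out = cr_features(tr)
        third = out.iloc[2]
        assert third["cr_incorrect"] == 1 and third["cr_correct"] == 0
        assert third["history"] == 0  # previous run timed out

    def test_duplicate_rows_rejected(self):
        tr = make_trials([1, 0], runs=[1, 1])
        with pytest.raises(ValueError):
            cr_features(tr)


def _psychometric_data(slope, intercept=0.0, n=2000, seed=0, cr_shift=0.0):
    rng = np.random.default_rng(seed)
    rel = rng.integers(-8, 9, n).astype(float)
    p = 1 / (1 + np.exp(-(intercept + slope * rel + cr_shift)))
    y = rng.random(n) < p
    return pd.DataFrame({
        "relative_reward": rel, "islie": y.astype(float),
        "timeout": False, "relative_cr": 0,
    })


class TestPsychometric:
    def test_slope_recovery(self):
        df = _psychometric_data(slope=0.5, n=2000, seed=1)
        res = fit_psychometric(df)
        assert res["slope"] == pytest.approx(0.5, abs=0.1)
        assert not res.extra["separated"]

    def test_complete_separation_flagged(self):
        df = _psychometric_data(slope=0.5, n=200, seed=2)
        df["islie"] = (df["relative_reward"] > 0).astype(float)
        res = fit_psychometric(df)
        assert res.extra["separated"]
        assert np.isfinite(res["slope"])

    def test_cr_strata_shift_intercept_ordering(self):
        # positive relative-CR history shifts the curve toward more lying
        rng = np.random.default_rng(3)
        frames = []
        for cr, shift in ((-2, -1.0), (0, 0.0), (2, 1.0)):
            df = _psychometric_data(slope=0.4, n=3000,
                                    seed=int(rng.integers(1e6)),
                                    cr_shift=shift)
            df["relative_cr"] = cr
            frames.append(df)
        data = pd.concat(frames, ignore_index=True)
        inters = {s: fit_psychometric(data, stratum=s)["intercept"]
                  for s in ("+", "0", "-")}
        assert inters["+"] > inters["0"] > inters["-"]


class TestRandomIntercept:
    def test_zero_group_variance_matches_ols(self):
        rng = np.random.default_rng(4)
        n_sub, n_run = 20, 9
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n_sub), n_run),
            "x": rng.normal(size=n_sub * n_run),
        })
        df["y"] = 1.0 + 0.5 * df["x"] + rng.normal(0, 0.3, len(df))
        res = fit_random_intercept(df, "y", ["x"])
        X = np.column_stack([np.ones(len(df)), df["x"]])
        beta_ols = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        assert res["x"] == pytest.approx(beta_ols[1], abs=0.01)

    def test_entropy_effect_recovery_at_reported_size(self):
        # the linear mixed model recovers a subject-level entropy effect of
        # the size reported for AUC (beta = 0.11) within 2 SE
        rng = np.random.default_rng(5)
        n_sub, n_run = 34, 9
        entropy = rng.uniform(0, 1, n_sub)
        lie = rng.uniform(0, 1, n_sub)
        intercepts = rng.normal(0, 0.1, n_sub)
        rows = []
        for j in range(n_sub):
            for r in range(n_run):
                rows.append({
                    "subject": j, "entropy": entropy[j], "lie_rate": lie[j],
                    "auc": 0.2 + 0.11 * entropy[j] + intercepts[j]
                    + rng.normal(0, 0.1)})
        df = pd.DataFrame(rows)
        res = fit_random_intercept(df, "auc", ["lie_rate", "entropy"])
        assert abs(res["entropy"] - 0.11) < 2 * res.se["entropy"]

    def test_binomial_family_runs(self):
        rng = np.random.default_rng(6)
        n_sub, n_run = 15, 9
        u = rng.normal(0, 0.5, n_sub)
        rows = []
        for j in range(n_sub):
            for r in range(n_run):
                x = rng.normal()
                p = 1 / (1 + np.exp(-(0.8 * x + u[j])))
                rows.append({"subject": j, "x": x,
                             "y": float(rng.random() < p)})
        df = pd.DataFrame(rows)
        res = fit_random_intercept(df, "y", ["x"], family="binomial")
        assert res["x"] > 0
        assert res.pvalues["x"] < 0.05


class TestMinDetectableCorrelation:
    def test_reported_design_value(self):
        # n = 34, 80% power, two-tailed alpha .05
        assert min_detectable_correlation(34, 0.80, 0.05, 2) == \
            pytest.approx(0.46, abs=0.005)

    def test_large_n_root(self):
        # frozen from the brentq root of the Fisher-z power equation
        def power_fn(r, n=1000, alpha=0.05):
            return stats.norm.sf(stats.norm.ppf(1 - alpha / 2)
                                 - np.arctanh(r) * np.sqrt(n - 3))
        r_oracle = optimize.brentq(lambda r: power_fn(r) - 0.80, 1e-6, 0.99)
        assert min_detectable_correlation(1000, 0.80, 0.05, 2) == \
            pytest.approx(r_oracle, abs=1e-6)
        assert min_detectable_correlation(1000, 0.80, 0.05, 2) == \
            pytest.approx(0.0885, abs=5e-5)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        r = pingouin.power_corr(n=34, power=0.80, alpha=0.05,
                                alternative="two-sided")
        assert min_detectable_correlation(34, 0.80, 0.05, 2) == \
            pytest.approx(r, abs=5e-3)

    def test_limit_to_zero(self):
        assert min_detectable_correlation(10_000_000, 0.5 + 1e-9, 0.05, 2) \
            < 1e-3

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            min_detectable_correlation(3)


class TestPowerBySimulation:
    @staticmethod
    def _gen(beta, rng, n=34):
        x = rng.standard_normal(n)
        y = beta * x + rng.standard_normal(n) * np.sqrt(max(1 - beta**2, 1e-9))
        return x, y

    @staticmethod
    def _fit(data):
        return stats.pearsonr(*data).pvalue

    def test_null_calibration_and_monotonicity(self):
        res = power_by_simulation(self._gen, self._fit,
                                  beta_grid=[0.0, 0.3, 0.6], n_sims=200,
                                  alpha=0.05, seed=0)
        assert res.loc[0, "power"] == pytest.approx(0.05, abs=0.04)
        assert res["power"].is_monotonic_increasing

    def test_matches_analytic_power_at_mdc(self):
        r = min_detectable_correlation(34, 0.80, 0.05, 2)
        res = power_by_simulation(self._gen, self._fit, beta_grid=[r],
                                  n_sims=400, alpha=0.05, seed=1)
        assert res.loc[0, "power"] == pytest.approx(0.80, abs=0.06)

    def test_failures_reported(self):
        def bad_fit(data):
            raise RuntimeError("boom")
        res = power_by_simulation(self._gen, bad_fit, beta_grid=[0.0],
                                  n_sims=20, seed=2)
        assert res.loc[0, "n_failed"] == 20
        assert np.isnan(res.loc[0, "power"])
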