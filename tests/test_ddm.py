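"""Diffusion-model core: density, simulator, likelihood, MCMC machinery."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from moraltrace.ddm import (DDMModelSpec, absorption_upper, assemble_covariates,
                            dic, posterior_prob, rhat, simulate_ddm_trial,
                            simulate_many, trial_loglik, wiener_density)
from moraltrace.ddm.fit import PosteriorSet


class TestWienerDensity:
    def test_symmetry_unbiased_driftless(self):
        t = np.linspace(0.05, 3, 50)
        up = wiener_density(t, "upper", 0.0, 1.2, 0.5, 0.0)
        lo = wiener_density(t, "lower", 0.0, 1.2, 0.5, 0.0)
        assert np.allclose(up, lo)

    def test_quadrature_absorption_probability(self):
        p = integrate.quad(lambda t: wiener_density(t, "upper", 0.0, 1.0,
                                                    0.5, 0.0), 0, 60,
                           limit=200)[0]
        assert p == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("v,a,z", [(0.5, 0.8, 0.4), (-3.0, 2.0, 0.6),
                                       (5.0, 1.5, 0.3), (0.0, 3.0, 0.7)])
    def test_normalization_over_parameter_grid(self, v, a, z):
        up = integrate.quad(lambda t: wiener_density(t, "upper", v, a, z, 0.0),
                            0, 100, limit=300)[0]
        lo = integrate.quad(lambda t: wiener_density(t, "lower", v, a, z, 0.0),
                            0, 100, limit=300)[0]
        assert up + lo == pytest.approx(1.0, abs=1e-4)
        assert up == pytest.approx(absorption_upper(v, a, z), abs=1e-4)

    def test_zero_before_nondecision_time(self):
        assert wiener_density(0.2, "upper", 1.0, 1.0, 0.5, 0.3) == 0.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            wiener_density(1.0, "upper", 0.0, -1.0, 0.5)
        with pytest.raises(ValueError):
            wiener_density(1.0, "upper", 0.0, 1.0, 1.5)

    def test_time_rescaling_invariance(self):
        # scaling time by c^2 while scaling (a, v, t0) consistently leaves
        # the density equal up to the Jacobian 1/c^2
        c = 2.0
        t = 0.8
        d1 = wiener_density(t, "upper", 1.0, 1.2, 0.4, 0.0)
        d2 = wiener_density(t * c * c, "upper", 1.0 / c, 1.2 * c, 0.4, 0.0)
        assert d1 == pytest.approx(d2 * c * c, rel=1e-8)


class TestEulerSimulator:
    def test_unbiased_start_is_fair(self):
        up, _ = simulate_many(np.zeros(10_000), 1.0, 0.5, 0.0, dt=1e-3,
                              seed=0)
        assert up.mean() == pytest.approx(0.5, abs=0.02)

    def test_strong_drift_hits_upper(self):
        up, _ = simulate_many(np.full(1000, 5.0), 1.0, 0.5, 0.0, dt=1e-4,
                              seed=1)
        assert up.mean() > 0.95

    def test_matches_analytic_absorption(self):
        # z-test of the simulated upper fraction against the analytic value
        n = 10_000
        v, a, z = 0.8, 1.4, 0.45
        up, _ = simulate_many(np.full(n, v), a, z, 0.0, dt=2e-4, seed=2)
        p = absorption_upper(v, a, z)
        zstat = (up.mean() - p) / np.sqrt(p * (1 - p) / n)
        assert abs(zstat) < 4.0

    def test_threshold_raises_mean_rt(self):
        _, rt1 = simulate_many(np.full(10_000, 0.5), 1.0, 0.5, 0.0,
                               dt=1e-3, seed=3)
        _, rt2 = simulate_many(np.full(10_000, 0.5), 2.0, 0.5, 0.0,
                               dt=1e-3, seed=4)
        assert rt2.mean() > rt1.mean()

    def test_single_trial_interface_and_dt_warning(self):
        b, rt = simulate_ddm_trial(1.0, 1.0, 0.5, 0.3, seed=5)
        assert b in ("upper", "lower") and rt > 0.3
        with pytest.warns(UserWarning):
            simulate_ddm_trial(1.0, 1.0, 0.5, 0.3, dt=0.02, seed=5)
        with pytest.raises(ValueError):
            simulate_ddm_trial(np.nan, 1.0, 0.5, 0.3)

    def test_determinism(self):
        a = simulate_many(np.full(50, 1.0), 1.0, 0.5, 0.2, seed=9)
        b = simulate_many(np.full(50, 1.0), 1.0, 0.5, 0.2, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestModelSpec:
    def test_family_active_sets(self):
        assert "d_c" not in DDMModelSpec("M1").active
        assert "d_c" in DDMModelSpec("M2").active
        assert "zeta_s" in DDMModelSpec("M5").active
        assert "zeta_h" in DDMModelSpec("M6").active
        assert "w_h" in DDMModelSpec("M7").active

    def test_inactive_pinned_to_zero(self):
        spec = DDMModelSpec("M1")
        full = spec.full_vector({"w_r": 1.0, "t0": 0.3})
        assert full[2] == 0.0 and full[3] == 0.0  # d_r, d_c
        with pytest.raises(ValueError):
            spec.full_vector({"d_c": 1.0})

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            DDMModelSpec("M8")

    def test_session_scaling_spans_unit_interval(self):
        df = pd.DataFrame({
            "subject": "s01", "run": np.arange(1, 10), "question": 1,
            "reward_correct": 5,
            "reward_incorrect": np.arange(1, 10),
            "relative_cr": 0, "timeout": False, "history": 0,
        })
        out = assemble_covariates(df, DDMModelSpec("M5"))
        assert out["s_tilde"].min() == -1.0 and out["s_tilde"].max() == 1.0


class TestTrialLoglik:
    def _record(self, islie=1, rt=1.0, r=0.5, c=-0.3, s=0.0, h=0):
        return {"timeout": False, "rt": rt, "islie": islie, "r_tilde": r,
                "c_tilde": c, "s_tilde": s, "history": h}

    def test_zero_weights_ignore_covariates(self):
        spec = DDMModelSpec("M5")
        full = spec.full_vector({"alpha0": 0.3, "t0": 0.25})
        l1 = trial_loglik(self._record(r=1.0, c=2.0), full, spec)
        l2 = trial_loglik(self._record(r=-1.0, c=0.0), full, spec)
        assert l1 == pytest.approx(l2)

    def test_choice_flip_symmetry_at_fair_start(self):
        spec = DDMModelSpec("M5")
        full = spec.full_vector({"alpha0": 0.3, "t0": 0.25})
        l1 = trial_loglik(self._record(islie=1), full, spec)
        l2 = trial_loglik(self._record(islie=0), full, spec)
        assert l1 == pytest.approx(l2)

    def test_matches_simulated_choice_rt_histogram(self):
        # joint density of (boundary, rt) from the analytic formula should
        # integrate to the same bin masses as a large Euler simulation
        spec = DDMModelSpec("M1")
        vals = {"w_r": 0.0, "w_c": 0.0, "alpha0": np.log(1.5), "alpha_s": 0.0,
                "zeta0": 0.4, "t0": 0.3}
        full = spec.full_vector(vals)
        z = 1 / (1 + np.exp(-0.4))
        n = 60_000
        up, rt = simulate_many(np.zeros(n), 1.5, z, 0.3, dt=2e-4, seed=11)
        edges = np.array([0.4, 0.7, 1.0, 1.5, 2.5])
        for lo, hi in zip(edges[:-1], edges[1:]):
            frac = np.mean((up == 1) & (rt >= lo) & (rt < hi))
            mass = integrate.quad(
                lambda t: wiener_density(t, "upper", 0.0, 1.5, z, 0.3),
                lo, hi)[0]
            assert frac == pytest.approx(mass, abs=4 * np.sqrt(mass / n) + 2e-3)

    def test_excluded_rt_rejected(self):
        spec = DDMModelSpec("M5")
        full = spec.full_vector({"alpha0": 0.3, "t0": 0.25})
        with pytest.raises(ValueError):
            trial_loglik(self._record(rt=0.1), full, spec)
        with pytest.raises(ValueError):
            trial_loglik({**self._record(), "timeout": True}, full, spec)


class TestRhat:
    def test_common_distribution_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((4, 10_000))
        assert rhat(chains) < 1.01

    def test_disjoint_supports_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(8, 1, 500)])
        assert rhat(chains) > 1.1

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((4, 400)) + np.arange(4)[:, None] * 0.1
        assert rhat(chains) == pytest.approx(rhat(chains[::-1]))

    def test_zero_within_variance(self):
        chains = np.stack([np.ones(100), np.full(100, 2.0)])
        assert rhat(chains) == np.inf

    def test_agrees_with_arviz_on_mixed_chains(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((4, 2000))
        az_val = arviz.rhat(chains)
        if hasattr(az_val, "values"):
            az_val = az_val.values
        assert rhat(chains) == pytest.approx(float(az_val), abs=0.02)


def _fake_posterior(draws_by_name):
    names = sorted({n.split("mu_")[1] for n in draws_by_name})
    return PosteriorSet(spec=DDMModelSpec("M5"), param_names=names,
                        subjects=["s1"], group_draws=draws_by_name,
                        subject_draws=np.zeros((1, 1, 1, len(names))),
                        rhat={k: 1.0 for k in draws_by_name})


class TestPosteriorProb:
    def test_all_positive_draws(self):
        post = _fake_posterior({"mu_w_r": np.abs(np.random.default_rng(0)
                                                 .standard_normal((2, 100)))})
        assert posterior_prob(post, "w_r > 0") == 1.0

    def test_symmetric_null_near_half(self):
        post = _fake_posterior({"mu_w_r": np.random.default_rng(1)
                                .standard_normal((2, 5000))})
        assert posterior_prob(post, "w_r > 0") == pytest.approx(0.5,
                                                                abs=0.03)

    def test_absolute_value_comparison(self):
        rng = np.random.default_rng(2)
        post = _fake_posterior({
            "mu_w_r": rng.normal(0.5, 0.1, (2, 1000)),
            "mu_w_c": rng.normal(1.5, 0.1, (2, 1000)),
        })
        assert posterior_prob(post, "|w_c| > |w_r|") > 0.99

    def test_unknown_name_rejected(self):
        post = _fake_posterior({"mu_w_r": np.zeros((2, 100))})
        with pytest.raises(ValueError):
            posterior_prob(post, "bogus > 0")


class TestHierarchicalFit:
    def test_fit_attributes_and_convergence(self, m5_fit):
        post = m5_fit.posterior_
        assert set(post.param_names) == {"w_r", "w_c", "d_r", "d_c",
                                         "alpha0", "alpha_s", "zeta0",
                                         "zeta_s", "t0"}
        assert m5_fit.rhat_ == post.rhat
        mu_rhats = [v for k, v in post.rhat.items() if k.startswith("mu_")]
        assert max(mu_rhats) < 1.1
        assert post.dic is not None and post.pd_eff > 0

    def test_group_means_recover_truth(self, m5_fit, m5_dataset):
        _, _, gp = m5_dataset
        post = m5_fit.posterior_
        for name in ("w_r", "w_c", "alpha0", "zeta0", "t0"):
            d = post.group_mean_draws(name)
            lo, hi = np.percentile(d, [0.5, 99.5])
            assert lo - 0.15 <= gp.means[name] <= hi + 0.15, name

    def test_expected_sign_posteriors(self, m5_fit):
        # reward and consistency weights generated positive; threshold
        # slope generated negative (faster runs)
        assert m5_fit.posterior_prob("w_c > 0") > 0.99
        assert m5_fit.posterior_prob("w_r > 0") > 0.95
        assert m5_fit.posterior_prob("alpha_s < 0") > 0.99

    def test_dic_degenerate_posterior(self, m5_fit):
        post = m5_fit.posterior_
        frozen = PosteriorSet(
            spec=post.spec, param_names=post.param_names,
            subjects=post.subjects, group_draws=post.group_draws,
            subject_draws=np.repeat(
                post.subject_draws.mean(axis=(0, 1))[None, None],
                50, axis=1)[None][0].reshape(1, 50, *post.subject_draws.shape[2:]),
            rhat=post.rhat, extra=post.extra)
        d, p_eff, dbar = dic(frozen)
        assert p_eff == pytest.approx(0.0, abs=1e-6)
        assert d == pytest.approx(dbar, abs=1e-6)

    def test_posterior_predictive_coverage(self, m5_fit):
        ppc = m5_fit.posterior_predictive(n_draws=60, seed=1)
        assert ppc["covered"].mean() >= 0.85
        props = ppc[ppc["stat"] == "choice_prop"]
        assert len(props) == 9

    def test_misspecified_weights_fail_ppc(self, m5_fit, m5_dataset):
        # zeroing the fitted weights must break choice-proportion coverage
        from moraltrace.ddm.fit import posterior_predictive

        post = m5_fit.posterior_
        broken = PosteriorSet(
            spec=post.spec, param_names=post.param_names,
            subjects=post.subjects, group_draws=post.group_draws,
            subject_draws=post.subject_draws.copy(), rhat=post.rhat,
            extra=post.extra)
        for i, name in enumerate(post.param_names):
            if name in ("w_r", "w_c"):
                broken.subject_draws[..., i] = 0.0
            if name == "zeta0":
                broken.subject_draws[..., i] = 2.0  # strong dishonest bias
        ppc = posterior_predictive(broken, m5_fit.trials_, n_draws=40,
                                   seed=2)
        props = ppc[ppc["stat"] == "choice_prop"]
        assert props["covered"].mean() < 0.5

    def test_validation_errors(self, m5_dataset):
        from moraltrace.ddm import HierarchicalDDM

        trials, _, _ = m5_dataset
        with pytest.raises(ValueError):
            HierarchicalDDM(chains=1).fit(trials)
        with pytest.raises(ValueError):
            HierarchicalDDM().fit(trials[trials["subject"] == "s01"])
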