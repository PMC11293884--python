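import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dispersalkit.experiments import _toy_clogit_instance, grid_search_clogit
from dispersalkit.issa import (
    IssaFit,
    ModelSpec,
    MovementKernel,
    fit_clogit,
    fit_tentative_kernel,
    generate_random_steps,
    log_rss,
    steps_from_burst,
    update_kernel,
)
from dispersalkit.preprocess import Burst

from conftest import make_fixes


class TestTentativeKernel:
    def test_gamma_mle_recovers_parameters(self):
        rng = np.random.default_rng(20)
        sl = rng.gamma(2.0, 500.0, size=10000)
        kernel = fit_tentative_kernel(sl, rng.uniform(-np.pi, np.pi, 100))
        assert 1.9 <= kernel.gamma_shape <= 2.1
        assert 475 <= kernel.gamma_scale <= 525

    def test_uniform_angles_give_zero_concentration(self):
        rng = np.random.default_rng(21)
        kernel = fit_tentative_kernel(rng.gamma(2, 400, 100),
                                      rng.uniform(-np.pi, np.pi, 10000))
        assert kernel.vm_kappa < 0.05

    def test_tight_angles_give_high_concentration(self):
        rng = np.random.default_rng(22)
        kernel = fit_tentative_kernel(rng.gamma(2, 400, 100),
                                      rng.normal(0, 0.05, 1000))
        assert kernel.vm_kappa > 50

    def test_zero_step_lengths_floored_not_fatal(self):
        rng = np.random.default_rng(23)
        sl = rng.gamma(2, 400, 200)
        sl[:20] = 0.0
        kernel = fit_tentative_kernel(sl, rng.uniform(-np.pi, np.pi, 100))
        assert kernel.gamma_shape > 0

    def test_all_zero_step_lengths_error(self):
        with pytest.raises(ValueError):
            fit_tentative_kernel(np.zeros(50), np.zeros(50))


class TestRandomSteps:
    def _burst(self, n=40, seed=24):
        rng = np.random.default_rng(seed)
        xy = np.cumsum(rng.normal(300, 200, size=(n, 2)), axis=0)
        return Burst("a", make_fixes(np.arange(n) * 4.0, xy), 240.0)

    def test_each_stratum_has_one_used_and_n_random(self):
        b = self._burst()
        kernel = MovementKernel(2.0, 400.0, 0.5)
        steps = generate_random_steps(b, kernel, n_random=20, seed=1)
        counts = steps.groupby("stratum_id")["case"].agg(["sum", "count"])
        assert (counts["sum"] == 1).all()
        assert (counts["count"] == 21).all()
        # first step of the burst (no turning angle) forms no stratum
        assert steps["stratum_id"].nunique() == len(b) - 2

    def test_fixed_seed_reproducible(self):
        b = self._burst()
        kernel = MovementKernel(2.0, 400.0, 0.5)
        s1 = generate_random_steps(b, kernel, n_random=5, seed=42)
        s2 = generate_random_steps(b, kernel, n_random=5, seed=42)
        pd.testing.assert_frame_equal(s1, s2)

    def test_degenerate_kernel_clusters_at_dead_reckoned_point(self):
        # near-deterministic kernel: available endpoints sit at the mean
        # step length straight ahead of the incoming bearing
        b = Burst("a", make_fixes([0, 4, 8],
                                  [(0, 0), (500, 0), (1000, 0)]), 240.0)
        kernel = MovementKernel(gamma_shape=1e6, gamma_scale=500.0 / 1e6, vm_kappa=1e6)
        steps = generate_random_steps(b, kernel, n_random=50, seed=2)
        avail = steps[steps["case"] == 0]
        # start point is the second fix (500, 0); one mean step ahead = 1000
        np.testing.assert_allclose(avail["x_end"], 1000.0, atol=5.0)
        np.testing.assert_allclose(avail["y_end"], 0.0, atol=5.0)

    def test_invalid_n_random_rejected(self):
        b = self._burst()
        with pytest.raises(ValueError):
            generate_random_steps(b, MovementKernel(2, 400, 0.5), n_random=0)


class TestFitClogit:
    def test_matches_grid_search_on_toy_instances(self):
        rng = np.random.default_rng(25)
        for p in (1, 2):
            X, strata, y = _toy_clogit_instance(rng, 8, 3, p, rng.uniform(-1, 1, p))
            fit = fit_clogit(X, strata_ids=strata, y=y,
                             names=[f"b{j}" for j in range(p)], min_strata=1)
            if not fit.converged:
                continue
            ref = grid_search_clogit(X, strata, y)
            est = np.array([fit.beta[f"b{j}"] for j in range(p)])
            assert np.max(np.abs(est - ref)) < 1e-4

    def test_matches_statsmodels_conditional_logit(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(26)
        X, strata, y = _toy_clogit_instance(rng, 200, 5, 2, np.array([0.5, -0.3]))
        fit = fit_clogit(X, strata_ids=strata, y=y, names=["a", "b"], min_strata=1)
        sm_fit = ConditionalLogit(y, X, groups=strata).fit(disp=0)
        # statsmodels' BFGS stops at a looser gradient tolerance
        np.testing.assert_allclose([fit.beta["a"], fit.beta["b"]],
                                   sm_fit.params, atol=1e-4)
        np.testing.assert_allclose([fit.se["a"], fit.se["b"]],
                                   sm_fit.bse, rtol=1e-3)

    def test_no_contrast_column_dropped(self):
        rng = np.random.default_rng(27)
        X, strata, y = _toy_clogit_instance(rng, 50, 4, 1, np.array([0.5]))
        X2 = np.column_stack([X, np.repeat(rng.normal(size=50), 4)])  # stratum-constant
        with pytest.warns(UserWarning, match="no-contrast"):
            fit = fit_clogit(X2, strata_ids=strata, y=y, names=["a", "flat"],
                             min_strata=1)
        assert fit.dropped == ["flat"]
        assert "flat" not in fit.beta

    def test_complete_separation_flagged(self):
        # covariate that always ranks the used step first diverges
        n, K = 40, 4
        X = np.zeros((n, K, 1))
        X[:, 0, 0] = 1.0
        y = np.zeros((n, K), dtype=int)
        y[:, 0] = 1
        strata = np.repeat(np.arange(n), K)
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_clogit(X.reshape(-1, 1), strata_ids=strata, y=y.ravel(),
                             names=["sep"], min_strata=1)
        assert not fit.converged
        assert np.isinf(fit.se["sep"])

    def test_adding_constant_to_covariate_leaves_fit_unchanged(self):
        rng = np.random.default_rng(28)
        X, strata, y = _toy_clogit_instance(rng, 100, 5, 2, np.array([0.4, -0.2]))
        f1 = fit_clogit(X, strata_ids=strata, y=y, names=["a", "b"], min_strata=1)
        f2 = fit_clogit(X + 57.0, strata_ids=strata, y=y, names=["a", "b"],
                        min_strata=1)
        assert f1.beta["a"] == pytest.approx(f2.beta["a"], abs=1e-6)
        assert f1.beta["b"] == pytest.approx(f2.beta["b"], abs=1e-6)

    def test_estimates_cover_truth_in_repeated_fits(self):
        # simulated-from-the-model data: estimate within 2 se of truth in
        # ~95% of replicates
        rng = np.random.default_rng(29)
        beta_true = np.array([-0.5, 0.3])
        hits = 0
        n_reps = 40
        for _ in range(n_reps):
            X, strata, y = _toy_clogit_instance(rng, 500, 21, 2, beta_true)
            fit = fit_clogit(X, strata_ids=strata, y=y, names=["a", "b"],
                             min_strata=1)
            ok = all(abs(fit.beta[n] - bt) <= 2 * fit.se[n]
                     for n, bt in zip(["a", "b"], beta_true))
            hits += ok
        assert hits >= int(0.85 * n_reps)


class TestUpdateKernel:
    def test_zero_movement_betas_leave_kernel_unchanged(self):
        k = MovementKernel(2.0, 400.0, 0.7)
        fit = IssaFit("a", "s", {"log_sl": 0.0, "sl": 0.0, "cos_ta": 0.0},
                      {}, np.eye(3), ["log_sl", "sl", "cos_ta"], 0.0, 100, True)
        k2 = update_kernel(k, fit)
        assert (k2.gamma_shape, k2.gamma_scale, k2.vm_kappa) == (2.0, 400.0, 0.7)

    def test_log_sl_coefficient_shifts_shape(self):
        k = MovementKernel(2.0, 400.0, 0.7)
        fit = IssaFit("a", "s", {"log_sl": 0.5, "sl": 0.0, "cos_ta": 0.1},
                      {}, np.eye(3), ["log_sl", "sl", "cos_ta"], 0.0, 100, True)
        k2 = update_kernel(k, fit)
        assert k2.gamma_shape == pytest.approx(2.5)
        assert k2.vm_kappa == pytest.approx(0.8)

    def test_invalid_update_raises(self):
        k = MovementKernel(2.0, 400.0, 0.7)
        fit = IssaFit("a", "s", {"log_sl": -2.5, "sl": 0.0, "cos_ta": 0.0},
                      {}, np.eye(3), ["log_sl", "sl", "cos_ta"], 0.0, 100, True)
        with pytest.raises(ValueError, match="invalid kernel update"):
            update_kernel(k, fit)

    def test_update_moves_misspecified_kernel_toward_truth(self):
        # used steps drawn from the true gamma; available steps from a
        # deliberately wrong tentative kernel; the fitted sl/log_sl
        # coefficients correct the tentative kernel toward the truth
        rng = np.random.default_rng(30)
        true = MovementKernel(2.0, 400.0, 0.0)
        tent = MovementKernel(2.6, 300.0, 0.0)
        n, K = 4000, 21
        sl_used = rng.gamma(true.gamma_shape, true.gamma_scale, n)
        sl_avail = rng.gamma(tent.gamma_shape, tent.gamma_scale, (n, K - 1))
        sl = np.column_stack([sl_used, sl_avail])
        X = np.stack([sl, np.log(sl)], axis=-1).reshape(-1, 2)
        y = np.zeros((n, K), dtype=int)
        y[:, 0] = 1
        strata = np.repeat(np.arange(n), K)
        fit = fit_clogit(X, strata_ids=strata, y=y.ravel(), names=["sl", "log_sl"],
                         min_strata=1)
        updated = update_kernel(tent, fit)

        grid = np.linspace(1, 6000, 2000)
        def kl(a, b):
            pa = stats.gamma.pdf(grid, a.gamma_shape, scale=a.gamma_scale)
            pb = stats.gamma.pdf(grid, b.gamma_shape, scale=b.gamma_scale)
            pa /= pa.sum(); pb /= pb.sum()
            return float(np.sum(pa * np.log(pa / pb)))

        assert kl(true, updated) < kl(true, tent)


class TestLogRss:
    def _fit(self):
        vcov = np.array([[0.04, 0.01], [0.01, 0.09]])
        return IssaFit("a", "s", {"u": -0.5, "v": 0.3},
                       {"u": 0.2, "v": 0.3}, vcov, ["u", "v"], 0.0, 100, True)

    def test_identical_profiles_give_zero(self):
        val, se, ci = log_rss(self._fit(), {"u": 1.0, "v": 2.0}, {"u": 1.0, "v": 2.0})
        assert val == 0.0
        assert ci[0] <= 0.0 <= ci[1]

    def test_unit_contrast_returns_coefficient(self):
        val, se, ci = log_rss(self._fit(), {"u": 1.0}, {"u": 0.0})
        assert val == pytest.approx(-0.5)
        assert se == pytest.approx(0.2)
        assert ci[0] == pytest.approx(-0.5 - 1.96 * 0.2, abs=1e-3)

    def test_two_covariate_contrast_matches_quadratic_form(self):
        # d = (1, -2): var = d' V d = 0.04 - 2*2*0.01 + 4*0.09 = 0.36
        val, se, ci = log_rss(self._fit(), {"u": 1.0, "v": 0.0}, {"u": 0.0, "v": 2.0})
        assert val == pytest.approx(-0.5 * 1 + 0.3 * -2)
        assert se == pytest.approx(np.sqrt(0.36))

    def test_missing_term_rejected(self):
        with pytest.raises(KeyError):
            log_rss(self._fit(), {"w": 1.0}, {"w": 0.0})


def test_steps_from_burst_geometry():
    # east, then north: second step has sl 300 and ta +90 degrees
    b = Burst("a", make_fixes([0, 4, 8], [(0, 0), (400, 0), (400, 300)]), 240.0)
    steps = steps_from_burst(b)
    assert steps["sl"].tolist() == [400.0, 300.0]
    assert np.isnan(steps["ta"].iloc[0])
    assert steps["ta"].iloc[1] == pytest.approx(np.pi / 2)
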