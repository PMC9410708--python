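"""Growth model, N/C relaxation closed form, and the regression estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osmoscale import (
    GeneratorConfig,
    gen_homeostasis_population,
    fit_correction_rate,
    fit_growth_rate,
    generations_to_correct,
    nc_trajectory_analytic,
    simulate_growth,
)


class TestSimulateGrowth:
    def test_fixed_point_is_stationary_both_modes(self):
        for mode in ("exponential", "linear"):
            tr = simulate_growth(100.0, 7.5, 0.006, 0.075, np.arange(0, 200, 10.0), mode=mode)
            np.testing.assert_allclose(tr.nc, 0.075, rtol=1e-12)

    def test_nc_converges_to_f0(self):
        t = np.linspace(0, 2000, 50)
        tr = simulate_growth(100.0, 10.0, 0.006, 0.075, t)
        assert tr.nc[-1] == pytest.approx(0.075, abs=1e-4)

    def test_deviation_half_life(self):
        """An N/C deviation halves after ln2/gammaC minutes."""
        gamma = 0.006
        t_half = math.log(2) / gamma  # 115.52 min
        tr = simulate_growth(100.0, 10.0, gamma, 0.075, np.array([0.0, t_half]))
        assert tr.nc[0] == pytest.approx(0.10)
        assert tr.nc[1] == pytest.approx(0.0875, abs=1e-6)

    def test_exponential_nc_matches_analytic_everywhere(self):
        t = np.linspace(0, 500, 40)
        tr = simulate_growth(80.0, 9.0, 0.004, 0.075, t)
        expected = [nc_trajectory_analytic(9.0 / 80.0, 0.075, 0.004, ti) for ti in t]
        np.testing.assert_allclose(tr.nc, expected, rtol=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_growth(100.0, 10.0, -0.1, 0.075, np.arange(3.0))
        with pytest.raises(ValueError):
            simulate_growth(100.0, 150.0, 0.006, 0.075, np.arange(3.0))
        with pytest.raises(ValueError):
            simulate_growth(100.0, 10.0, 0.006, 1.5, np.arange(3.0))


class TestAnalyticSolution:
    def test_boundary_values(self):
        assert nc_trajectory_analytic(0.10, 0.075, 0.006, 0.0) == pytest.approx(0.10)
        assert nc_trajectory_analytic(0.10, 0.075, 0.006, 1e7) == pytest.approx(0.075)

    def test_one_hour_relaxation(self):
        val = nc_trajectory_analytic(0.10, 0.075, 0.006, 60.0)
        assert val == pytest.approx(0.075 + 0.025 * math.exp(-0.36), rel=1e-12)

    def test_agrees_with_numerical_ode_integration(self):
        """RK4 on the coupled volume system matches the closed form over 10 generations."""
        gamma, f0 = 0.006, 0.075
        vc, vn = 100.0, 12.0
        t_end = 10 * math.log(2) / gamma
        n_steps = 20000
        dt = t_end / n_steps

        def rhs(state):
            vc_, vn_ = state
            return np.array([gamma * vc_, f0 * gamma * vc_])

        state = np.array([vc, vn])
        for _ in range(n_steps):
            k1 = rhs(state)
            k2 = rhs(state + dt / 2 * k1)
            k3 = rhs(state + dt / 2 * k2)
            k4 = rhs(state + dt * k3)
            state = state + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        nc_numeric = state[1] / state[0]
        nc_closed = nc_trajectory_analytic(0.12, f0, gamma, t_end)
        assert nc_numeric == pytest.approx(nc_closed, rel=1e-8)

    @given(
        nc0=st.floats(min_value=0.01, max_value=0.5),
        t=st.floats(min_value=0.0, max_value=5000.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_convergence_no_overshoot(self, nc0, t):
        f0, gamma = 0.075, 0.006
        val = nc_trajectory_analytic(nc0, f0, gamma, t)
        lo, hi = min(nc0, f0), max(nc0, f0)
        assert lo - 1e-12 <= val <= hi + 1e-12


class TestGrowthRateEstimator:
    def _noiseless_cohort(self, gamma=0.006, mode="exponential", n=20):
        t = np.arange(0.0, 44.0, 4.0)
        sizes = np.linspace(60.0, 180.0, n)
        return [
            simulate_growth(v0, 0.075 * v0, gamma, 0.075, t, mode=mode, cell_id=f"c{i}")
            for i, v0 in enumerate(sizes)
        ]

    @staticmethod
    def _ols_slope_oracle(t, y):
        """Closed-form OLS slope, the finite-window secant oracle."""
        tc = t - t.mean()
        return float(np.sum(tc * y) / np.sum(tc * tc))

    def test_noiseless_exponential_matches_secant_oracle(self):
        """The estimator equals the closed-form secant slope of e^(gamma t).

        A linear fit to exponential growth over a finite window inflates the
        rate by the window factor (~1 + gamma * t_mean, about 12% for a
        40-min window at gamma = 0.006/min); the estimator must reproduce
        that factor exactly in the noiseless limit.
        """
        gamma = 0.006
        t = np.arange(0.0, 44.0, 4.0)
        s_e = self._ols_slope_oracle(t, np.exp(gamma * t))
        fit = fit_growth_rate(self._noiseless_cohort(gamma))
        assert fit.gammaC == pytest.approx(s_e, rel=1e-10)
        assert gamma < fit.gammaC < 1.15 * gamma

    def test_consistency_in_short_window_limit(self):
        """With gamma * T << 1 the window bias vanishes and gamma is recovered."""
        gamma = 0.006
        t = np.linspace(0.0, 4.0, 11)
        sizes = np.linspace(60.0, 180.0, 20)
        cohort = [
            simulate_growth(v0, 0.075 * v0, gamma, 0.075, t, cell_id=f"c{i}")
            for i, v0 in enumerate(sizes)
        ]
        fit = fit_growth_rate(cohort)
        assert fit.gammaC == pytest.approx(gamma, rel=0.02)

    def test_linear_growth_gives_zero_slope(self):
        """Size-independent growth: dV/dt does not scale with initial volume."""
        cohort = self._noiseless_cohort(mode="linear")
        # in linear mode each cell has rate gamma*V0, still size-dependent;
        # force identical absolute rates instead
        t = np.arange(0.0, 44.0, 4.0)
        k = 0.6  # um^3/min for every cell
        cohort = []
        for i, v0 in enumerate(np.linspace(60.0, 180.0, 20)):
            vc = v0 + k * t
            vn = 0.075 * v0 + 0.075 * k * t
            from osmoscale.growth_homeostasis import GrowthTrajectory

            cohort.append(GrowthTrajectory(cell_id=f"c{i}", times=t, vc=vc, vn=vn))
        fit = fit_growth_rate(cohort)
        assert fit.gammaC == pytest.approx(0.0, abs=1e-12)

    def test_noisy_cohort_within_two_se(self, gen_config):
        trajs = gen_homeostasis_population(gen_config, gammaC=0.006, f0=0.075, n_cells=100)
        fit = fit_growth_rate(trajs)
        assert abs(fit.gammaC - 0.006) <= 2 * fit.stderr

    def test_mitotic_points_excluded_and_minimums_enforced(self):
        cohort = self._noiseless_cohort()
        cohort[0].mitotic[:] = True  # cell with no usable points is dropped
        fit = fit_growth_rate(cohort)
        assert fit.n_cells == len(cohort) - 1
        with pytest.raises(ValueError, match="usable cells"):
            fit_growth_rate(cohort[:5])


class TestCorrectionRateEstimator:
    @staticmethod
    def _ols_slope_oracle(t, y):
        tc = t - t.mean()
        return float(np.sum(tc * y) / np.sum(tc * tc))

    def test_noiseless_cohort_matches_oracle_and_recovers_f0(self):
        """Noiseless cohort: slope equals the secant oracle of the N/C
        relaxation (magnitude slightly below gamma over a finite window)
        and the x-intercept recovers f0 exactly."""
        gamma, f0 = 0.006, 0.075
        t = np.arange(0.0, 44.0, 4.0)
        cohort = [
            simulate_growth(100.0, nc0 * 100.0, gamma, f0, t, cell_id=f"c{i}")
            for i, nc0 in enumerate(np.linspace(0.05, 0.12, 15))
        ]
        fit = fit_correction_rate(cohort)
        s_d = self._ols_slope_oracle(t, np.exp(-gamma * t))  # nc deviation decay
        assert fit.gammaNC == pytest.approx(s_d, rel=1e-8)
        assert -gamma < fit.gammaNC < -0.85 * gamma
        assert fit.f0_hat == pytest.approx(f0, rel=1e-8)

    def test_pom1_like_cohort_slope_and_intercept(self, gen_config):
        trajs = gen_homeostasis_population(gen_config, gammaC=0.006, f0=0.075, n_cells=150)
        fit = fit_correction_rate(trajs)
        assert abs(fit.gammaNC - (-0.006)) <= 2 * fit.stderr_gammaNC
        assert abs(fit.f0_hat - 0.075) <= 2 * fit.stderr_f0

    def test_fixed_point_cohort_rejected_by_spread_check(self):
        t = np.arange(0.0, 44.0, 4.0)
        cohort = [
            simulate_growth(v0, 0.075 * v0, 0.006, 0.075, t, cell_id=f"c{i}")
            for i, v0 in enumerate(np.linspace(60, 180, 15))
        ]
        with pytest.raises(ValueError, match="spread"):
            fit_correction_rate(cohort)

    def test_slower_growth_scales_correction_rate(self):
        """A threefold slower cohort corrects threefold slower."""
        t = np.arange(0.0, 44.0, 4.0)

        def cohort(gamma):
            return [
                simulate_growth(100.0, nc0 * 100.0, gamma, 0.075, t, cell_id=f"c{i}")
                for i, nc0 in enumerate(np.linspace(0.05, 0.12, 15))
            ]

        fast = fit_correction_rate(cohort(0.006))
        slow = fit_correction_rate(cohort(0.002))
        # oracle ratio: both rates carry their own finite-window attenuation
        s_fast = self._ols_slope_oracle(t, np.exp(-0.006 * t))
        s_slow = self._ols_slope_oracle(t, np.exp(-0.002 * t))
        assert fast.gammaNC / slow.gammaNC == pytest.approx(s_fast / s_slow, rel=1e-8)
        assert fast.gammaNC / slow.gammaNC == pytest.approx(3.0, rel=0.2)

    def test_predicted_line_is_parameter_free(self):
        fit_like = fit_correction_rate(
            [
                simulate_growth(100.0, nc0 * 100.0, 0.006, 0.075, np.arange(0, 44, 4.0), cell_id=str(i))
                for i, nc0 in enumerate(np.linspace(0.05, 0.12, 12))
            ]
        )
        grid = np.array([0.05, 0.075, 0.12])
        line = fit_like.predicted_line(0.006, 0.075, grid)
        np.testing.assert_allclose(line, 0.006 * (0.075 - grid), rtol=1e-12)


class TestGenerationsToCorrect:
    def test_fourfold_deviation_takes_two_generations(self):
        t, gens = generations_to_correct(0.115, 0.075, 0.006, tolerance=0.01)
        assert gens == pytest.approx(2.0)
        assert t == pytest.approx(2 * math.log(2) / 0.006, rel=1e-12)

    def test_large_deviation_count(self):
        _, gens = generations_to_correct(0.12, 0.075, 0.006, tolerance=0.005)
        assert gens == pytest.approx(math.log2(9), rel=1e-12)

    def test_within_tolerance_returns_zero(self):
        assert generations_to_correct(0.076, 0.075, 0.006, tolerance=0.01) == (0.0, 0.0)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            generations_to_correct(0.12, 0.075, 0.006, tolerance=0.0)


class TestExponentialVsLinear:
    def test_linear_growth_corrects_more_slowly_for_large_cells(self):
        """At one doubling time, a large cell under linear growth retains more
        of its N/C deviation than under exponential growth."""
        gamma, f0, nc0 = 0.006, 0.075, 0.12
        t_double = math.log(2) / gamma
        t = np.array([0.0, t_double])
        vc0 = 150.0
        exp_tr = simulate_growth(vc0, nc0 * vc0, gamma, f0, t, mode="exponential")
        lin_tr = simulate_growth(vc0, nc0 * vc0, gamma, f0, t, mode="linear")
        dev_exp = abs(exp_tr.nc[-1] - f0)
        dev_lin = abs(lin_tr.nc[-1] - f0)
        assert dev_lin > dev_exp
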