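"""Deterministic model: ODEs, closed-form frequency, half-life predictions."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from genestab.model import (
    ModelParams,
    PopulationState,
    frequency_ode_rhs,
    frequency_trajectory,
    full_ode_rhs,
    half_life,
    half_life_gain,
    half_life_gain_grid,
    integrate_full_model,
)


def logistic(N0, r, K, t):
    return K / (1.0 + (K - N0) / N0 * np.exp(-r * t))


class TestFullODE:
    def test_no_back_mutation(self):
        dE, _ = full_ode_rhs(PopulationState(0, 100), ModelParams(r=0.1, s=0.2, mu=0.05))
        assert dE == 0.0

    def test_vanishes_at_carrying_capacity(self):
        p = ModelParams(r=0.1, s=0.1, mu=0.01, K=1e6)
        dE, dR = full_ode_rhs(PopulationState(4e5, 6e5), p)
        assert dE == pytest.approx(0.0, abs=1e-12)
        assert dR == pytest.approx(0.0, abs=1e-12)

    def test_term_by_term_arithmetic(self):
        # independent spreadsheet-style evaluation:
        # dN_E = 0.1*0.9*1000*0.9995*0.99, dN_R = 0.1*0.9*1000*0.9995*0.01
        p = ModelParams(r=0.1, s=0.1, mu=0.01, K=2e6)
        dE, dR = full_ode_rhs(PopulationState(1000, 0), p)
        assert dE == pytest.approx(89.05545, rel=1e-12)
        assert dR == pytest.approx(0.89955, rel=1e-12)


class TestIntegrateFullModel:
    def test_reduces_to_logistic(self):
        p = ModelParams(r=0.12, s=0.0, mu=0.0, K=1e7)
        sol = integrate_full_model(PopulationState(1e3, 0.0), p, 80.0,
                                   t_eval=np.linspace(1, 80, 20))
        expected = logistic(1e3, 0.12, 1e7, sol.t)
        assert np.allclose(sol.y[0], expected, rtol=1e-6)
        assert np.all(sol.y >= 0)

    def test_matches_closed_form_frequency_at_huge_K(self):
        # K stays >= 1e6 x the population over the whole window
        p = ModelParams(r=0.1, s=0.08, mu=1e-3, K=1e15)
        sol = integrate_full_model(PopulationState(1e4, 0.0), p, 100.0,
                                   t_eval=np.linspace(0, 100, 25))
        freq = sol.y[0] / sol.y.sum(axis=0)
        assert np.allclose(freq, frequency_trajectory(1.0, p, sol.t), atol=1e-6)

    def test_saturation_regime_by_72h(self):
        # logistic oracle: starting from 1e4 at r=0.1, N(72)/K = 1/(1+199*e^-7.2)
        p = ModelParams(r=0.1, s=0.0, mu=0.0, K=2e6)
        sol = integrate_full_model(PopulationState(1e4, 0.0), p, 72.0, t_eval=[72.0])
        expected = logistic(1e4, 0.1, 2e6, 72.0)
        total = sol.y.sum(axis=0)[-1]
        assert total == pytest.approx(expected, rel=1e-6)
        assert total > 0.85 * p.K  # growth has essentially saturated
        assert total < p.K

    def test_bad_time_raises(self):
        with pytest.raises(ValueError):
            integrate_full_model(PopulationState(1, 1, t=10.0), ModelParams(r=0.1, s=0, mu=0), 5.0)


class TestFrequencyODE:
    @pytest.mark.parametrize(
        "p,params,expected",
        [
            (0.0, ModelParams(r=0.1, s=0.1, mu=0.01), 0.0),  # absorbing boundary
            (0.3, ModelParams(r=0.2, s=0.0, mu=0.01), -0.2 * 0.01 * 0.3),  # neutral limit
            # direct arithmetic: -0.1*0.5*(0.001 + 0.05*(1-0.5-0.001))
            (0.5, ModelParams(r=0.1, s=0.05, mu=0.001), -0.0012975),
        ],
    )
    def test_values(self, p, params, expected):
        assert frequency_ode_rhs(p, params) == pytest.approx(expected, rel=1e-12, abs=1e-15)

    def test_nonpositive_on_unit_interval(self):
        params = ModelParams(r=0.3, s=0.15, mu=0.02)
        assert all(frequency_ode_rhs(p, params) <= 0 for p in np.linspace(0, 1, 21))


class TestFrequencyTrajectory:
    def test_initial_condition(self):
        p = ModelParams(r=0.1, s=0.07, mu=1e-3)
        assert frequency_trajectory(0.83, p, 0.0) == pytest.approx(0.83, rel=1e-14)

    def test_no_mutation_pure_culture_stays_pure(self):
        p = ModelParams(r=0.1, s=0.3, mu=0.0)
        for t in [0.0, 10.0, 1e4, 1e9]:
            assert frequency_trajectory(1.0, p, t) == 1.0

    def test_neutral_closed_form(self):
        # s=0 collapses to p0*exp(-r*mu*t)
        p = ModelParams(r=0.1, s=0.0, mu=0.01)
        assert frequency_trajectory(1.0, p, 100.0) == pytest.approx(np.exp(-0.1), rel=1e-12)

    def test_degenerate_parameters_return_p0(self):
        p = ModelParams(r=0.1, s=0.0, mu=0.0)
        assert frequency_trajectory(0.6, p, 500.0) == 0.6

    def test_matches_ode_oracle_on_grid(self):
        """Closed form equals high-accuracy integration of the frequency ODE
        to <= 1e-8 absolute, out to 10x the half-life, over >= 20 regimes."""
        rng = np.random.default_rng(7)
        combos = [
            (r, s, mu)
            for r in (0.05, 0.1, 0.2878)
            for s in (0.0, 0.01, 0.1, 0.2)
            for mu in (1e-5, 1e-3, 0.05)
        ]
        assert len(combos) >= 20
        for r, s, mu in combos:
            params = ModelParams(r=r, s=s, mu=mu)
            t50 = half_life(params)
            t_grid = np.linspace(0.0, 10.0 * t50, 30)
            sol = solve_ivp(
                lambda t, p: [frequency_ode_rhs(p[0], params)],
                (0.0, t_grid[-1]),
                [1.0],
                t_eval=t_grid,
                method="LSODA",
                rtol=1e-12,
                atol=1e-14,
            )
            closed = frequency_trajectory(1.0, params, t_grid)
            assert np.max(np.abs(sol.y[0] - closed)) <= 1e-8, (r, s, mu)
        # also one random p0 < 1 regime
        p0 = rng.uniform(0.6, 1.0)
        params = ModelParams(r=0.1, s=0.05, mu=1e-4)
        sol = solve_ivp(lambda t, p: [frequency_ode_rhs(p[0], params)], (0, 48), [p0],
                        t_eval=[48.0], rtol=1e-12, atol=1e-14)
        assert frequency_trajectory(p0, params, 48.0) == pytest.approx(sol.y[0][-1], abs=1e-9)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        s=st.floats(0.0, 0.5),
        mu=st.floats(0.0, 0.3),
        r=st.floats(0.01, 1.0),
        p0=st.floats(0.0, 1.0),
    )
    def test_monotone_and_bounded(self, s, mu, r, p0):
        params = ModelParams(r=r, s=s, mu=mu)
        t = np.linspace(0.0, 2000.0, 200)
        p = np.asarray(frequency_trajectory(p0, params, t))
        assert np.all((p >= 0.0) & (p <= 1.0))
        assert np.all(np.diff(p) <= 1e-12)


class TestHalfLife:
    def test_neutral_is_ln2_over_r_mu(self):
        assert half_life(ModelParams(r=0.1, s=0.0, mu=0.1)) == pytest.approx(
            np.log(2) / 0.01, rel=1e-12
        )
        # the ~70 h rule of thumb for r*mu = 0.01
        assert half_life(ModelParams(r=0.1, s=0.0, mu=0.1)) == pytest.approx(70.0, abs=1.0)

    @pytest.mark.parametrize(
        "r,mu,s,printed",
        [(0.2878, 0.015, 0.057, 87.0), (0.2878, 0.003, 0.043, 216.0)],
    )
    def test_plasmid_loss_estimates(self, r, mu, s, printed):
        assert half_life(ModelParams(r=r, s=s, mu=mu)) == pytest.approx(printed, rel=0.01)

    def test_consistent_with_trajectory_root(self):
        params = ModelParams(r=0.1, s=0.1, mu=1e-4)
        t50 = half_life(params)
        assert frequency_trajectory(1.0, params, t50) == pytest.approx(0.5, abs=1e-9)
        # bisection oracle on the closed form
        from scipy.optimize import bisect

        root = bisect(lambda t: frequency_trajectory(1.0, params, t) - 0.5, 1.0, 1e5,
                      xtol=1e-9)
        assert t50 == pytest.approx(root, rel=1e-6)

    def test_general_p0(self):
        params = ModelParams(r=0.1, s=0.05, mu=1e-3)
        t50 = half_life(params, p0=0.9)
        assert frequency_trajectory(0.9, params, t50) == pytest.approx(0.5, abs=1e-9)
        assert t50 < half_life(params)
        assert half_life(params, p0=0.5) == 0.0
        assert half_life(params, p0=0.3) == 0.0

    def test_degenerate_cases(self):
        with pytest.raises(ValueError):
            half_life(ModelParams(r=0.1, s=0.0, mu=0.0))
        assert half_life(ModelParams(r=0.1, s=0.1, mu=0.0)) == np.inf


class TestHalfLifeGain:
    base = ModelParams(r=0.1, s=0.1, mu=1e-4)

    def test_identity(self):
        assert half_life_gain(self.base, 1.0, 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_selection_dominated_regime(self):
        # t50 931.50/700.86 h from direct evaluation of the closed form:
        # cutting mutation 10x barely helps when selection dominates
        assert half_life_gain(self.base, k_mu=10.0) == pytest.approx(1.3290862612, rel=1e-9)

    def test_monotone_in_both_factors(self):
        both = half_life_gain(self.base, 10.0, 10.0)
        assert both > half_life_gain(self.base, 10.0, 1.0)
        assert both > half_life_gain(self.base, 1.0, 10.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            half_life_gain(self.base, k_mu=0.5)
        with pytest.raises(ValueError):
            half_life_gain(ModelParams(r=0.1, s=0.0, mu=0.0), 2.0, 2.0)

    def test_grid_is_tidy_and_consistent(self):
        grid = half_life_gain_grid(self.base, k_max=100.0, num=6)
        assert list(grid.columns) == ["k_mu", "k_s", "ratio"]
        assert len(grid) == 36
        assert (grid["ratio"] >= 1.0 - 1e-12).all()
        spot = grid[(grid["k_mu"] == 1.0) & (grid["k_s"] == 1.0)]["ratio"].iloc[0]
        assert spot == pytest.approx(1.0, rel=1e-12)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(r=-0.1, s=0, mu=0), dict(r=0.1, s=1.0, mu=0),
                   dict(r=0.1, s=0, mu=-0.1), dict(r=0.1, s=0, mu=0, K=0)],
    )
    def test_invalid_params_raise(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            PopulationState(-1, 0)
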