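"""Unit tests for the single-cycle load dynamics and its analytic oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from scipy.integrate import quad

from hostcycle import (IntegrationError, LifeCycleTraits, SimulationSettings,
                       WormGrowthParams, closed_form_linear_r0,
                       closed_form_logistic_constW, final_load,
                       final_load_fixed_step, lifecycle_rhs, solve_lifecycle,
                       worm_biomass)
from conftest import draw_traits


class TestWormBiomass:
    def test_linear_form(self, wg):
        assert worm_biomass(0.0, wg) == 10.0
        assert worm_biomass(3.5, wg) == pytest.approx(2498.5)

    def test_constant_when_growth_zero(self):
        wg0 = WormGrowthParams(W0=10.0, g=0.0)
        assert worm_biomass(17.3, wg0) == 10.0

    def test_negative_time_rejected(self, wg):
        with pytest.raises(ValueError):
            worm_biomass(-0.1, wg)


class TestRhs:
    def test_immigration_only_at_zero_load(self, wg):
        t = LifeCycleTraits(r=2.0, delta=3.0, f=1e4, K=1e5)
        assert lifecycle_rhs(1.0, 0.0, t, wg) == pytest.approx(
            1e4 * worm_biomass(1.0, wg))

    def test_pure_removal_at_capacity(self, wg):
        t = LifeCycleTraits(r=2.0, delta=3.0, f=0.0, K=1e5)
        n_cap = 1e5 * worm_biomass(2.0, wg)
        assert lifecycle_rhs(2.0, n_cap, t, wg) == pytest.approx(-3.0 * n_cap)

    @given(t=st.floats(0, 3.5), n=st.floats(0, 1e9),
           r=st.floats(0.1, 17.8), delta=st.floats(0.3, 1e4),
           f=st.floats(1e3, 10 ** 7.5), K=st.floats(1e4, 10 ** 6.25))
    @hyp_settings(max_examples=50, deadline=None)
    def test_term_by_term_sum(self, t, n, r, delta, f, K):
        """RHS equals the independently summed immigration, growth, removal terms."""
        wg = WormGrowthParams()
        traits = LifeCycleTraits(r=r, delta=delta, f=f, K=K)
        W = 711.0 * t + 10.0
        expected = f * W + r * n * (1 - n / (K * W)) - delta * n
        assert lifecycle_rhs(t, n, traits, wg) == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_rejected(self, wg):
        t = LifeCycleTraits(r=1, delta=1, f=1e4, K=1e5)
        with pytest.raises(ValueError):
            lifecycle_rhs(0.5, math.nan, t, wg)


class TestClosedFormLinearR0:
    def test_requires_r_zero(self, wg, settings):
        with pytest.raises(ValueError):
            closed_form_linear_r0(
                LifeCycleTraits(r=1, delta=1, f=1e4, K=1e5), wg, settings)

    def test_pure_decay_without_immigration(self, wg):
        t = LifeCycleTraits(r=0, delta=2.0, f=0.0, K=1e5)
        s = SimulationSettings(n0=500.0)
        assert closed_form_linear_r0(t, wg, s) == pytest.approx(
            500.0 * math.exp(-2.0 * 3.5))

    def test_quasi_steady_state_large_delta(self, wg):
        """With strong removal the load tracks f*W(t)/delta."""
        t = LifeCycleTraits(r=0, delta=5e3, f=1e4, K=1e5)
        s = SimulationSettings()
        expected = 1e4 * worm_biomass(3.5, wg) / 5e3
        assert closed_form_linear_r0(t, wg, s) == pytest.approx(expected, rel=1e-3)

    def test_against_integrating_factor_quadrature(self, wg):
        """Independent oracle: n(t_f) = e^{-d t_f} [n0 + int_0^{t_f} f W(u) e^{d u} du]."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            d = 10.0 ** rng.uniform(-0.5, 2.0)
            f = 10.0 ** rng.uniform(3, 7.5)
            n0 = rng.uniform(0, 1e4)
            t = LifeCycleTraits(r=0, delta=d, f=f, K=1e5)
            s = SimulationSettings(n0=n0)
            integral, _ = quad(lambda u: f * worm_biomass(u, wg) * math.exp(d * u),
                               0, 3.5, limit=200)
            expected = math.exp(-d * 3.5) * (n0 + integral)
            assert closed_form_linear_r0(t, wg, s) == pytest.approx(expected, rel=1e-9)

    def test_delta_zero_branch(self, wg):
        t = LifeCycleTraits(r=0, delta=0.0, f=100.0, K=1e5)
        s = SimulationSettings(n0=5.0)
        expected = 5.0 + 100.0 * (0.5 * 711.0 * 3.5 ** 2 + 10.0 * 3.5)
        assert closed_form_linear_r0(t, wg, s) == pytest.approx(expected, rel=1e-12)


class TestClosedFormLogisticConstW:
    wg0 = WormGrowthParams(W0=10.0, g=0.0)

    def test_preconditions(self, wg):
        t = LifeCycleTraits(r=2, delta=1, f=0, K=1e5)
        with pytest.raises(ValueError):
            closed_form_logistic_constW(t, wg, SimulationSettings(n0=1.0))  # g != 0
        with pytest.raises(ValueError):
            closed_form_logistic_constW(
                LifeCycleTraits(r=2, delta=1, f=10, K=1e5), self.wg0,
                SimulationSettings(n0=1.0))  # f != 0
        with pytest.raises(ValueError):
            closed_form_logistic_constW(t, self.wg0, SimulationSettings(n0=0.0))

    def test_textbook_logistic_without_removal(self):
        t = LifeCycleTraits(r=2.0, delta=0.0, f=0, K=1e4)
        s = SimulationSettings(n0=100.0, t_f=2.0)
        KW = 1e4 * 10.0
        expected = KW / (1 + (KW / 100.0 - 1) * math.exp(-2.0 * 2.0))
        assert closed_form_logistic_constW(t, self.wg0, s) == pytest.approx(
            expected, rel=1e-12)

    def test_net_decay_when_removal_dominates(self):
        t = LifeCycleTraits(r=1.0, delta=3.0, f=0, K=1e5)
        n1 = closed_form_logistic_constW(t, self.wg0, SimulationSettings(n0=1e4, t_f=3.5))
        n2 = closed_form_logistic_constW(t, self.wg0, SimulationSettings(n0=1e4, t_f=20.0))
        assert n1 < 1e4
        assert n2 < n1
        assert n2 == pytest.approx(0.0, abs=1e-10)

    def test_equilibrium_at_long_horizon(self):
        t = LifeCycleTraits(r=4.0, delta=1.0, f=0, K=1e5)
        s = SimulationSettings(n0=10.0, t_f=50.0)
        K_eff = 1e5 * 10.0 * (1 - 1.0 / 4.0)
        assert closed_form_logistic_constW(t, self.wg0, s) == pytest.approx(
            K_eff, rel=1e-9)

    def test_critical_rate_branch(self):
        t = LifeCycleTraits(r=2.0, delta=2.0, f=0, K=1e3)
        s = SimulationSettings(n0=100.0, t_f=1.0)
        expected = 100.0 / (1 + 2.0 * 100.0 * 1.0 / 1e4)
        assert closed_form_logistic_constW(t, self.wg0, s) == pytest.approx(
            expected, rel=1e-12)


class TestSolver:
    def test_zero_is_equilibrium_without_immigration(self, wg):
        t = LifeCycleTraits(r=3.0, delta=1.0, f=0.0, K=1e5)
        traj = solve_lifecycle(t, wg, SimulationSettings(n0=0.0))
        assert np.all(traj.n == 0.0)

    def test_trajectory_contract(self, wg, settings):
        t = LifeCycleTraits(r=1.0, delta=1.0, f=1e5, K=1e5)
        traj = solve_lifecycle(t, wg, settings)
        assert traj.times[0] == 0.0
        assert traj.times[-1] == settings.t_f
        assert traj.n[0] == settings.n0
        assert np.all(np.diff(traj.times) > 0)
        assert np.all(traj.n >= 0)
        assert traj.n_f == traj.n[-1]

    def test_matches_linear_oracle(self, wg):
        rng = np.random.default_rng(11)
        for traits in draw_traits(rng, 10, r=0.0):
            s = SimulationSettings(n0=float(rng.uniform(0, 100)))
            num = final_load(traits, wg, s)
            exact = closed_form_linear_r0(traits, wg, s)
            assert num == pytest.approx(exact, rel=1e-6)

    def test_matches_logistic_oracle(self):
        wg0 = WormGrowthParams(W0=10.0, g=0.0)
        rng = np.random.default_rng(13)
        for _ in range(10):
            t = LifeCycleTraits(r=10.0 ** rng.uniform(-1, 1.25),
                                delta=10.0 ** rng.uniform(-0.5, 1.0),
                                f=0.0, K=10.0 ** rng.uniform(4, 6.25))
            # abs_tol far below the decayed endpoint so relative control governs
            s = SimulationSettings(n0=float(10.0 ** rng.uniform(0, 4)),
                                   rel_tol=1e-10, abs_tol=1e-18)
            num = final_load(t, wg0, s)
            exact = closed_form_logistic_constW(t, wg0, s)
            assert num == pytest.approx(exact, rel=1e-6)

    def test_linearity_in_f_when_growth_absent(self, wg):
        """With r = 0 and n0 = 0 the dynamics are linear in f."""
        s = SimulationSettings(rel_tol=1e-11, abs_tol=1e-9)
        base = LifeCycleTraits(r=0.0, delta=3.0, f=2e4, K=1e5)
        n1 = final_load(base, wg, s)
        n3 = final_load(base.replace_axis("f", 6e4), wg, s)
        assert n3 / n1 == pytest.approx(3.0, rel=1e-8)

    def test_fixed_step_agrees_with_adaptive(self, wg, settings):
        t = LifeCycleTraits(r=1.0, delta=1.0, f=1e5, K=1e5)
        adaptive = final_load(t, wg, settings)
        brute = final_load_fixed_step(t, wg, settings, dt=1e-4)
        assert brute == pytest.approx(adaptive, rel=1e-7)

    def test_monotonicity_in_traits(self, wg, settings):
        """n_f falls with removal and rises with immigration and capacity."""
        rng = np.random.default_rng(17)
        for axis, expected_sign in (("delta", -1), ("f", 1), ("K", 1)):
            for base in draw_traits(rng, 5):
                lo = getattr(base, axis)
                hi = lo * 10.0 ** rng.uniform(0.1, 1.0)
                n_lo = final_load(base.replace_axis(axis, lo), wg, settings)
                n_hi = final_load(base.replace_axis(axis, hi), wg, settings)
                if expected_sign > 0:
                    assert n_hi >= n_lo * (1 - 1e-6)
                else:
                    assert n_hi <= n_lo * (1 + 1e-6)


class TestParams:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            WormGrowthParams(W0=0.0)
        with pytest.raises(ValueError):
            LifeCycleTraits(r=1, delta=-1, f=1, K=1)
        with pytest.raises(ValueError):
            LifeCycleTraits(r=1, delta=1, f=1, K=0)
        with pytest.raises(ValueError):
            SimulationSettings(t_f=0.0)
        with pytest.raises(ValueError):
            SimulationSettings(rel_tol=2.0)

    def test_config_roundtrip(self, tmp_path):
        from hostcycle import load_config

        cfg = tmp_path / "model.yaml"
        cfg.write_text(
            "W0: 10\ng: 711\nt_f: 3.5\nn0: 0\n"
            "traits: {r: 1.0, delta: 2.0, f: 1.0e4, K: 1.0e5}\n")
        out = load_config(cfg)
        assert out["wg"].g == 711.0
        assert out["traits"].delta == 2.0

    def test_unknown_config_key_rejected(self, tmp_path):
        from hostcycle import load_config

        cfg = tmp_path / "model.yaml"
        cfg.write_text("W0: 10\nbogus: 3\n")
        with pytest.raises(ValueError, match="bogus"):
            load_config(cfg)
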