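"""Coarse-grained dynamics tests: the slow system equals the
effective-parameter fixed system, the coexistence equilibrium formulas,
and the initial-condition correction."""

import numpy as np
import pytest

from hgtosc import (
    InducedPayoffs,
    ModelParams,
    OscillatorySpec,
    PopulationState,
    coexistence_equilibrium,
    corrected_initial_conditions,
    effective_competition,
    induced_fitness,
    integrate_full,
    integrate_slow,
    rhs_full,
    slow_rhs,
)
from hgtosc.coarse import CoexistenceError, oscillating_corrections

from .conftest import random_params, single_harmonic_spec


class TestInducedFitness:
    def test_zero_payoffs(self):
        assert induced_fitness(InducedPayoffs(0.0, 0.0), (0.3, 12.0)) == (0.0, 0.0)

    def test_monoculture_of_A_feels_no_induced_payoff(self):
        phi_A, _ = induced_fitness(InducedPayoffs(0.5, 0.1), (1.0, 12.0))
        assert phi_A == 0.0

    def test_reference_values(self):
        phi = induced_fitness(InducedPayoffs(0.08, -0.08), (0.5, 20.0))
        assert phi == (pytest.approx(0.8), pytest.approx(0.8))


class TestSlowRhs:
    def test_identical_to_effective_fixed_system(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            params = random_params(rng, gamma=rng.uniform(-0.03, 0.03))
            payoffs = InducedPayoffs(*rng.uniform(-0.2, 0.2, size=2))
            y = [rng.uniform(0.0, 1.0), rng.uniform(0.0, 25.0)]
            eff = effective_competition(params, payoffs)
            assert np.allclose(
                slow_rhs(0.0, y, params, payoffs),
                rhs_full(0.0, y, eff),
                rtol=1e-12,
                atol=1e-12,
            )

    def test_zero_payoffs_reduce_to_full_rhs(self, ref_params):
        y = [0.4, 7.0]
        assert np.allclose(
            slow_rhs(0.0, y, ref_params, InducedPayoffs(0.0, 0.0)),
            rhs_full(0.0, y, ref_params),
        )

    def test_coexistence_equilibrium_is_stationary(self, ref_params):
        eq = coexistence_equilibrium(ref_params, InducedPayoffs(0.08, -0.08))
        dy = slow_rhs(
            0.0, [eq.p_A_star, eq.N_star], ref_params, InducedPayoffs(0.08, -0.08)
        )
        assert np.allclose(dy, 0.0, atol=1e-10)


class TestCoexistenceEquilibrium:
    @pytest.mark.parametrize(
        "payoffs, expected",
        [
            (InducedPayoffs(0.08, -0.08), (5.0 / 7.0, 70.0 / 3.0)),
            (InducedPayoffs(-0.01, -0.08), (0.5224, 17.1795)),
            (InducedPayoffs(0.11, -0.11), (0.19 / 0.308, 31.1111)),
        ],
    )
    def test_reference_values(self, ref_params, payoffs, expected):
        eq = coexistence_equilibrium(ref_params, payoffs)
        assert eq.p_A_star == pytest.approx(expected[0], abs=1e-4)
        assert eq.N_star == pytest.approx(expected[1], abs=1e-3)

    def test_converges_under_slow_integration(self, ref_params):
        payoffs = InducedPayoffs(0.08, -0.08)
        eq = coexistence_equilibrium(ref_params, payoffs)
        traj = integrate_slow(ref_params, payoffs, PopulationState(0.5, 10.0), 400.0)
        assert traj.final_state.p_A == pytest.approx(eq.p_A_star, abs=1e-6)
        assert traj.final_state.N == pytest.approx(eq.N_star, rel=1e-6)

    def test_xi_zero_recovers_fixed_environment_abundance(self, ref_params):
        eq = coexistence_equilibrium(ref_params, InducedPayoffs(0.0, -0.08))
        assert eq.N_star == pytest.approx(ref_params.r_A / ref_params.a_11, rel=1e-12)

    def test_divergent_denominator_raises(self, ref_params):
        with pytest.raises(CoexistenceError, match="N/A"):
            coexistence_equilibrium(ref_params, InducedPayoffs(0.2, -0.3))

    def test_violated_conditions_raise(self, ref_params):
        with pytest.raises(CoexistenceError, match="kappa"):
            coexistence_equilibrium(ref_params, InducedPayoffs(0.08, 0.02))

    def test_unequal_competition_rejected(self):
        params = ModelParams(1.8, 1.0, 0.1, 0.05, 0.1, 0.1)
        with pytest.raises(ValueError, match="equal competition"):
            coexistence_equilibrium(params, InducedPayoffs(0.08, -0.08))


class TestInitialConditionCorrection:
    def test_zero_amplitude_is_identity(self, ref_params):
        osc = OscillatorySpec(omega=5.0)
        state = corrected_initial_conditions(0.37, 8.5, ref_params, osc)
        assert state.p_A == pytest.approx(0.37, abs=1e-12)
        assert state.N == pytest.approx(8.5, abs=1e-12)

    def test_corrections_have_zero_mean_in_tau(self, ref_params, blue_spec):
        pi_1, v_1 = oscillating_corrections(ref_params, blue_spec)
        tau = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)
        assert np.mean(pi_1(0.4, 12.0, tau)) == pytest.approx(0.0, abs=1e-10)
        assert np.mean(v_1(0.4, 12.0, tau)) == pytest.approx(0.0, abs=1e-10)

    def test_correction_scales_as_inverse_omega(self, ref_params, blue_spec):
        s1 = corrected_initial_conditions(0.5, 10.0, ref_params, blue_spec.with_omega(50.0))
        s2 = corrected_initial_conditions(0.5, 10.0, ref_params, blue_spec.with_omega(100.0))
        ratio = (s1.p_A - 0.5) / (s2.p_A - 0.5)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_fixed_point_satisfies_defining_equations(self, ref_params, blue_spec):
        state = corrected_initial_conditions(0.5, 10.0, ref_params, blue_spec)
        pi_1, v_1 = oscillating_corrections(ref_params, blue_spec)
        w = blue_spec.omega
        assert state.p_A + pi_1(state.p_A, state.N, 0.0) / w == pytest.approx(0.5, abs=1e-9)
        assert state.N + v_1(state.p_A, state.N, 0.0) / w == pytest.approx(10.0, abs=1e-9)

    def test_pairing_improves_early_time_tracking(self, ref_params, blue_spec):
        """The slow trajectory from the corrected start tracks the
        period-averaged full trajectory better than the naive pairing."""
        from hgtosc import compute_induced_payoffs

        payoffs = compute_induced_payoffs(blue_spec)
        full = integrate_full(ref_params, blue_spec, PopulationState(0.5, 10.0), 8.0)
        T = blue_spec.period
        centers = np.linspace(T, 5.0, 60)

        def period_avg(t):
            g = np.linspace(t - T / 2, t + T / 2, 101)
            return np.trapezoid(np.interp(g, full.times, full.p_A), g) / T

        target = np.array([period_avg(t) for t in centers])
        errs = {}
        corrected = corrected_initial_conditions(0.5, 10.0, ref_params, blue_spec)
        for label, ic in [("corrected", corrected), ("naive", PopulationState(0.5, 10.0))]:
            slow = integrate_slow(
                ref_params, payoffs, ic, 8.0, t_eval=np.linspace(0, 8, 1601)
            )
            ps = np.interp(centers, slow.times, slow.p_A)
            errs[label] = np.mean(np.abs(ps - target))
        assert errs["corrected"] < errs["naive"]

    def test_invalid_inputs_rejected(self, ref_params, blue_spec):
        with pytest.raises(ValueError):
            corrected_initial_conditions(1.4, 10.0, ref_params, blue_spec)
        with pytest.raises(ValueError):
            corrected_initial_conditions(0.5, 0.0, ref_params, blue_spec)


class TestSlowIntegration:
    def test_divergence_detected_in_na_regime(self, ref_params):
        traj = integrate_slow(
            ref_params, InducedPayoffs(0.2, -0.3), PopulationState(0.5, 18.0), 300.0
        )
        assert traj.diverged

    def test_rate_mode_flag(self, ref_params):
        traj = integrate_slow(
            ref_params, InducedPayoffs(0.01, -0.05), PopulationState(0.5, 10.0), 10.0
        )
        assert traj.rate_mode == "coarse_grained"
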