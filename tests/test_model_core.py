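"""Mass-action right-hand sides against the closed-form steady states."""

import numpy as np
import pytest

from mirella import (
    TranslationState,
    DegradationState,
    ModelStateError,
    free_ribosomes,
    translation_rhs,
    degradation_rhs,
    effective_degradation_rate,
    demand_coefficients,
    steady_state,
    integrate_to_steady_state,
)
from mirella.model_core import _degradation_rhs_arr
from scipy.integrate import solve_ivp

from conftest import random_translation_params


class TestFreeRibosomes:
    def test_empty_cell_returns_full_pool(self, tparams):
        assert free_ribosomes(TranslationState(), tparams) == tparams.r_total

    def test_unit_demand_per_gene(self, tparams):
        # one kappa-unit of each mRNA splits the pool three ways
        s = TranslationState(m_T=tparams.kappa_T, m_C=tparams.kappa_C, m_Q=123.0)
        p = tparams.replace(sigma=0)
        assert free_ribosomes(s, p) == pytest.approx(tparams.r_total / 3)

    def test_sigma_gates_complex_sequestration(self, tparams):
        s = TranslationState(m_Q=tparams.kappa_T)
        r5 = free_ribosomes(s, tparams.replace(sigma=0))
        r3 = free_ribosomes(s, tparams.replace(sigma=1))
        assert r5 == tparams.r_total
        assert r3 == pytest.approx(tparams.r_total / 2)

    def test_non_finite_state_rejected(self, tparams):
        with pytest.raises(ModelStateError):
            free_ribosomes(TranslationState(m_T=np.nan), tparams)

    def test_matches_demand_form_at_steady_state(self, tparams):
        p = tparams.replace(eta_plus=5.0, sigma=1)
        state = integrate_to_steady_state(p)
        rho = demand_coefficients(p)
        expected = p.r_total / (1 + rho.rho_T + p.sigma * rho.rho_TQ + rho.rho_C)
        assert free_ribosomes(state, p) == pytest.approx(expected, rel=1e-6)


class TestTranslationRHS:
    def test_zero_state_is_pure_production(self, tparams):
        d = translation_rhs(TranslationState(), tparams)
        assert (d.m_T, d.m_Q, d.m_C, d.q, d.p_T, d.p_C) == (
            tparams.n_T * tparams.alpha_T, 0.0,
            tparams.n_C * tparams.alpha_C, tparams.alpha_Q, 0.0, 0.0)

    def test_no_mirna_control_decouples(self, tparams):
        # without binding the complex never forms and the two genes are
        # independent birth-death processes
        p = tparams.replace(eta_plus=0.0)
        state = integrate_to_steady_state(p)
        assert state.m_Q == pytest.approx(0.0, abs=1e-12)
        assert state.m_T == pytest.approx(p.n_T * p.alpha_T / p.beta_T, rel=1e-6)
        assert state.m_C == pytest.approx(p.n_C * p.alpha_C / p.beta_C, rel=1e-6)

    def test_rhs_vanishes_at_analytic_steady_state(self, tparams):
        p = tparams.replace(eta_plus=2.0, sigma=1)
        ss = steady_state(p)
        state = TranslationState(m_T=ss.m_T_bar, m_Q=ss.m_Q_bar, m_C=ss.m_C_bar,
                                 q=ss.q_bar, p_T=ss.p_T_bar, p_C=ss.p_C_bar)
        d = translation_rhs(state, p).to_array()
        scale = max(p.n_T * p.alpha_T, p.n_C * p.alpha_C, p.alpha_Q)
        assert np.max(np.abs(d)) < 1e-8 * scale

    def test_consistency_random_parameter_sets(self):
        """Numerically integrated steady state reproduces the closed forms.

        Random positive parameter draws, log-uniform across decades; the
        analytic protein/free-ribosome/mRNA levels must match integration
        to relative tolerance 1e-5, and free miRNA must equal its
        production/decay balance (miRNA recycling).
        """
        rng = np.random.default_rng(20230313)
        for _ in range(25):
            p = random_translation_params(rng)
            ss = steady_state(p)
            state = integrate_to_steady_state(p)
            assert state.p_T == pytest.approx(ss.p_T_bar, rel=1e-5)
            assert state.p_C == pytest.approx(ss.p_C_bar, rel=1e-5)
            assert state.m_T == pytest.approx(ss.m_T_bar, rel=1e-5)
            assert state.m_Q == pytest.approx(ss.m_Q_bar, rel=1e-5, abs=1e-12)
            assert state.q == pytest.approx(p.alpha_Q / p.beta_Q, rel=1e-5)
            assert free_ribosomes(state, p) == pytest.approx(ss.r_bar, rel=1e-5)

    def test_trajectories_stay_nonnegative(self, tparams):
        from mirella.model_core import _translation_rhs_arr
        p = tparams.replace(eta_plus=10.0, sigma=0)
        sol = solve_ivp(lambda t, y: _translation_rhs_arr(t, y, p),
                        (0, 200.0), np.zeros(6), method="Radau",
                        rtol=1e-6, atol=1e-9)
        assert sol.success
        assert np.all(sol.y >= -1e-9)

    def test_sigma_irrelevant_without_mirna(self, tparams):
        p0 = tparams.replace(eta_plus=0.0, sigma=0)
        p1 = tparams.replace(eta_plus=0.0, sigma=1)
        s0 = integrate_to_steady_state(p0)
        s1 = integrate_to_steady_state(p1)
        assert s0.p_T == pytest.approx(s1.p_T, rel=1e-9)
        assert s0.p_C == pytest.approx(s1.p_C, rel=1e-9)


class TestDegradationRHS:
    def test_rnase_conservation_along_trajectory(self, dparams):
        p = dparams.replace(eta_plus=4.0)
        sol = solve_ivp(lambda t, y: _degradation_rhs_arr(t, y, p, True),
                        (0, 500.0), np.zeros(7), method="Radau",
                        rtol=1e-6, atol=1e-9)
        assert sol.success
        bound = sol.y[4] + sol.y[5] + sol.y[6]
        z = p.z_total - bound
        assert np.all(z + bound == pytest.approx(p.z_total, rel=1e-9))
        assert np.all(z >= -1e-9)

    def test_overfull_pool_rejected(self, dparams):
        s = DegradationState(s_TF=dparams.z_total, s_E=1.0)
        with pytest.raises(ModelStateError):
            degradation_rhs(s, dparams)

    def test_excess_enzyme_limit_single_exponential(self, dparams):
        """With RNase in vast excess the endogenous (mRNA, complex) pair is a
        linear two-state system at constant free enzyme; its decay is the slow
        eigenvalue of that system (~ assoc*z*cat/(dissoc+cat) when binding is
        slow compared to complex turnover)."""
        p = dparams.replace(z_total=1e6, betaE_assoc=1e-6,
                            betaT_assoc=1e-6, betaTQ_assoc=1e-6)
        ss = integrate_to_steady_state(p)
        y0 = ss.to_array()
        a = p.betaE_assoc * p.z_total
        A = np.array([[-a, p.betaE_dissoc],
                      [a, -(p.betaE_dissoc + p.betaE_cat)]])
        rate = -np.max(np.linalg.eigvals(A).real)
        naive = a * p.betaE_cat / (p.betaE_dissoc + p.betaE_cat)
        assert rate == pytest.approx(naive, rel=0.1)
        # compare from t = 0.5 h, after the fast binding mode has decayed
        t_eval = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
        sol = solve_ivp(lambda t, y: _degradation_rhs_arr(t, y, p, False),
                        (0, 4.0), y0, method="Radau", rtol=1e-8, atol=1e-12,
                        t_eval=t_eval)
        total_E = sol.y[2] + sol.y[6]
        expected = total_E[0] * np.exp(-rate * (t_eval - t_eval[0]))
        assert total_E == pytest.approx(expected, rel=2e-3)

    def test_no_coupling_without_mirna_binding(self, dparams):
        """At eta+ = 0 the endogenous gene only sees the miTarget through
        basal RNase occupancy; with the basal association switched off the
        (m_E, s_E) trajectory is identical whether the miTarget block is
        present or absent."""
        tiny = 1e-12
        p_with = dparams.replace(eta_plus=0.0, betaT_assoc=tiny, betaTQ_assoc=tiny)
        p_without = p_with.replace(alpha_T=tiny)
        t_eval = np.linspace(0, 50, 11)
        out = []
        for p in (p_with, p_without):
            sol = solve_ivp(lambda t, y: _degradation_rhs_arr(t, y, p, True),
                            (0, 50.0), np.zeros(7), method="Radau",
                            rtol=1e-8, atol=1e-12, t_eval=t_eval)
            out.append(np.vstack([sol.y[2], sol.y[6]]))
        assert out[0] == pytest.approx(out[1], rel=1e-6, abs=1e-12)

    def test_mirna_independent_params_inert_at_zero_binding(self, dparams):
        # at eta+ = 0 no complex ever forms, so the boosted association and
        # slow completion constants must not influence the trajectory
        p_a = dparams.replace(eta_plus=0.0, betaTQ_assoc=0.2, betaTQ_cat=0.8)
        p_b = dparams.replace(eta_plus=0.0, betaTQ_assoc=5.0, betaTQ_cat=5.0)
        sa = integrate_to_steady_state(p_a)
        sb = integrate_to_steady_state(p_b)
        assert sa.to_array() == pytest.approx(sb.to_array(), rel=1e-8, abs=1e-12)


class TestEffectiveDegradationRate:
    def test_undefined_on_empty_pool(self, dparams):
        with pytest.raises(ModelStateError):
            effective_degradation_rate(DegradationState(), dparams, "endogenous")

    def test_unknown_species_rejected(self, dparams):
        with pytest.raises(ValueError):
            effective_degradation_rate(DegradationState(m_E=1), dparams, "rRNA")

    def test_constant_in_excess_enzyme_limit(self, dparams):
        p = dparams.replace(z_total=1e6, betaE_assoc=1e-6,
                            betaT_assoc=1e-6, betaTQ_assoc=1e-6)
        ss = integrate_to_steady_state(p)
        t_eval = np.linspace(0, 4.0, 9)
        sol = solve_ivp(lambda t, y: _degradation_rhs_arr(t, y, p, False),
                        (0, 4.0), ss.to_array(), method="Radau",
                        rtol=1e-8, atol=1e-12, t_eval=t_eval)
        rates = [effective_degradation_rate(DegradationState.from_array(sol.y[:, i]),
                                            p, "endogenous")
                 for i in range(len(t_eval))]
        # constant once the fast binding transient (timescale ~1/20 h) is over
        assert np.ptp(rates[1:]) < 1e-3 * np.mean(rates[1:])

    def test_queueing_depresses_then_releases_endogenous_rate(self, dparams):
        """During the queueing phase the endogenous effective decay rate is
        below the no-miRNA control; after the miTarget pool is exhausted it
        recovers toward (and past) the control value."""
        def rates(eta, times):
            p = dparams.replace(eta_plus=eta)
            ss = integrate_to_steady_state(p)
            sol = solve_ivp(lambda t, y: _degradation_rhs_arr(t, y, p, False),
                            (0, times[-1]), ss.to_array(), method="Radau",
                            rtol=1e-8, atol=1e-12, t_eval=times)
            return np.array([
                effective_degradation_rate(
                    DegradationState.from_array(sol.y[:, i]), p, "endogenous")
                for i in range(len(times))])

        times = np.array([0.0, 0.5, 1.0, 2.0, 10.0, 15.0])
        control = rates(0.0, times)
        queued = rates(8.0, times)
        assert np.all(queued[:4] < control[:4])       # phase 1: suppressed
        assert queued[-1] > 2.0 * queued[1]           # recovery after exhaustion
        assert queued[-1] > 0.9 * control[-1]
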