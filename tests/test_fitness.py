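"""Invasion fitness: monodromy, Floquet exponents, closed-form oracles."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.linalg import expm

import evocycles as ec


class TestMutantRHS:
    def test_linearity_zero_state(self, fig2b):
        d = ec.mutant_rhs("seasonal", fig2b.epi, fig2b.tradeoff, 0.3, 0.2,
                          np.zeros(2), np.array([3.0, 1.5]))
        assert np.allclose(d, 0.0)

    def test_gamma0_matches_printed_growth_term(self, fig2b):
        """With gamma = 0 the S_m rate is (a(bm) - qN - b - bm I*) S_m."""
        p = replace(fig2b.epi, gamma=0.0, amp=0.0)
        res = np.array([4.0, 2.0])
        bm = 0.25
        d = ec.mutant_rhs("seasonal", p, fig2b.tradeoff, bm, 0.0, np.array([1.0, 0.0]), res)
        a_m = ec.birth_rate(fig2b.tradeoff, bm)
        assert d[0] == pytest.approx(a_m - p.q0 * 6.0 - p.b - bm * 2.0)
        assert d[1] == pytest.approx(bm * 2.0)

    def test_free_living_uses_propagule_pool(self, fig4):
        res = np.array([2.0, 1.0, 30.0])
        d = ec.mutant_rhs("free_living", fig4.epi, fig4.tradeoff, 0.1, 0.0,
                          np.array([1.0, 0.0]), res)
        # infection term beta_m * P * S_m, not beta_m * I * S_m
        assert d[1] == pytest.approx(0.1 * 30.0 * 1.0)


class TestMonodromy:
    def test_equilibrium_matches_matrix_exponential(self, baseline_params):
        """On a constant resident, C = exp(J T) exactly."""
        cyc, _ = ec.compute_attractor("baseline", baseline_params)
        assert cyc.kind == "equilibrium"
        bm = 0.3
        m = ec.monodromy_matrix("baseline", baseline_params, None, bm, cyc)
        S, I = ec.analytic_equilibrium(baseline_params)
        J = ec.mutant_jacobian_equilibrium(baseline_params, None, bm, N=S + I, F=I)
        assert np.allclose(m.C, expm(J * cyc.period), rtol=1e-6, atol=1e-8)
        assert m.exponent == pytest.approx(float(np.max(np.linalg.eigvals(J).real)), abs=1e-8)

    def test_basis_invariance(self, fig2b, fig2b_attractor):
        m1 = ec.monodromy_matrix(fig2b.variant, fig2b.epi, fig2b.tradeoff, 0.3, fig2b_attractor)
        B = np.array([[0.7, -0.3], [0.2, 1.1]])
        m2 = ec.monodromy_matrix(fig2b.variant, fig2b.epi, fig2b.tradeoff, 0.3,
                                 fig2b_attractor, init_basis=B)
        assert np.max(np.abs(np.sort_complex(m1.multipliers)
                             - np.sort_complex(m2.multipliers))) < 1e-8

    def test_phase_invariance(self, fig2b, fig2b_attractor):
        m1 = ec.monodromy_matrix(fig2b.variant, fig2b.epi, fig2b.tradeoff, 0.3, fig2b_attractor)
        m2 = ec.monodromy_matrix(fig2b.variant, fig2b.epi, fig2b.tradeoff, 0.3,
                                 fig2b_attractor.rolled(137))
        assert abs(m1.exponent - m2.exponent) < 1e-6

    def test_dominant_multiplier_real_positive(self, fig2b, fig2b_attractor):
        m = ec.monodromy_matrix(fig2b.variant, fig2b.epi, fig2b.tradeoff, 0.35, fig2b_attractor)
        rho = m.multipliers[np.argmax(np.abs(m.multipliers))]
        assert abs(rho.imag) < 1e-9
        assert rho.real > 0
        assert np.sign(m.exponent) == np.sign(rho.real - 1.0)

    def test_envelope_property(self, fig2b, fig2b_attractor):
        """Mutant growth over k periods is bounded by const * rho_max^k."""
        for bm in (0.15, 0.25):
            m = ec.monodromy_matrix(fig2b.variant, fig2b.epi, fig2b.tradeoff, bm,
                                    fig2b_attractor)
            rho = np.max(np.abs(m.multipliers))
            Ck = np.eye(2)
            for k in range(1, 6):
                Ck = m.C @ Ck
                assert np.linalg.norm(Ck) <= 2.0 * rho**k
                assert np.linalg.norm(Ck) >= 0.2 * rho**k


class TestClosedFormOracles:
    def test_ngm_neutrality(self, baseline_params):
        for br in (0.2, 0.3, 0.45):
            s = ec.ngm_fitness_equilibrium(baseline_params.with_beta(br), None, br, br)
            assert abs(s) < 1e-12

    def test_ngm_sign_matches_eigenvalue_on_grid(self, baseline_params, fig2b):
        """NGM closed form is sign-equivalent to the mutant Jacobian eigenvalue."""
        tr = fig2b.tradeoff
        grid = np.linspace(0.17, 0.5, 20)
        for br in grid:
            S, I = ec.analytic_equilibrium(ec.effective_params(baseline_params, tr, br))
            for bm in grid:
                s_ngm = ec.ngm_fitness_equilibrium(baseline_params.with_beta(br), tr, bm, br)
                s_eig = ec.eigenvalue_fitness_equilibrium(baseline_params, tr, bm, N=S + I, F=I)
                if abs(s_ngm) > 1e-10:
                    assert np.sign(s_ngm) == np.sign(s_eig)

    def test_gamma0_ngm_reduces_to_simple_growth_sign(self, baseline_params, fig2b):
        p = replace(baseline_params, gamma=0.0)
        tr = fig2b.tradeoff
        for br, bm in [(0.25, 0.2), (0.25, 0.3), (0.3, 0.29), (0.2, 0.35)]:
            s_ngm = ec.ngm_fitness_equilibrium(p.with_beta(br), tr, bm, br)
            s_lin = ec.simple_growth_fitness(p.with_beta(br), tr, bm, br)
            if abs(s_lin) > 1e-10:
                assert np.sign(s_ngm) == np.sign(s_lin)

    def test_average_growth_equals_floquet_gamma0(self, fig2b, gamma0_attractor):
        """For an unstructured mutant both fitness routes are exact and equal."""
        p, cyc = gamma0_attractor
        for bm in (0.15, 0.2, 0.3):
            s_avg = ec.average_growth_fitness("seasonal", p.with_beta(0.2),
                                              fig2b.tradeoff, bm, cyc)
            s_flq = ec.invasion_fitness("seasonal", p, fig2b.tradeoff, bm, 0.2,
                                        attractor=cyc, method="floquet")
            assert abs(s_avg - s_flq.value) < 1e-5

    def test_average_growth_rejects_gamma_nonzero(self, fig2b, fig2b_attractor):
        with pytest.raises(ValueError):
            ec.average_growth_fitness("seasonal", fig2b.epi, fig2b.tradeoff, 0.3,
                                      fig2b_attractor)


class TestInvasionFitnessDispatch:
    def test_neutrality_across_presets(self, fig2b, fig2b_attractor, fig4, fig4_attractor,
                                       baseline_params):
        f1 = ec.invasion_fitness(fig2b.variant, fig2b.epi, fig2b.tradeoff, 0.2, 0.2,
                                 attractor=fig2b_attractor)
        f2 = ec.invasion_fitness(fig4.variant, fig4.epi, fig4.tradeoff, 0.1, 0.1,
                                 attractor=fig4_attractor)
        f3 = ec.invasion_fitness("baseline", baseline_params, None, 0.2, 0.2)
        for f in (f1, f2, f3):
            assert abs(f.value) < 1e-4

    def test_methods_dispatch_by_attractor_kind(self, fig2b, fig2b_attractor, baseline_params):
        assert ec.invasion_fitness(fig2b.variant, fig2b.epi, fig2b.tradeoff, 0.3, 0.2,
                                   attractor=fig2b_attractor).method == "floquet"
        assert ec.invasion_fitness("baseline", baseline_params, None, 0.3,
                                   0.2).method == "ngm_equilibrium"

    def test_amp_to_zero_continuity(self, fig2b, baseline_params):
        """Floquet fitness at vanishing amplitude matches the equilibrium limit."""
        tr = fig2b.tradeoff
        p_eps = replace(fig2b.epi, amp=1e-6)
        cyc, _ = ec.compute_attractor("seasonal", p_eps, tr)
        S, I = ec.analytic_equilibrium(ec.effective_params(baseline_params, tr, 0.2))
        for bm in (0.25, 0.3):
            f = ec.invasion_fitness("seasonal", p_eps, tr, bm, 0.2,
                                    attractor=cyc, method="floquet")
            lam = ec.eigenvalue_fitness_equilibrium(baseline_params, tr, bm, N=S + I, F=I)
            assert abs(f.value - lam) < 1e-4
            s_ngm = ec.ngm_fitness_equilibrium(baseline_params, tr, bm, 0.2)
            assert np.sign(f.value) == np.sign(s_ngm)

    def test_disease_free_resident_rejected(self, baseline_params):
        with pytest.raises(ec.NotOnAttractorError):
            ec.invasion_fitness("baseline", baseline_params, None, 0.2, 0.1)
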