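"""Selection gradients, PIPs, singular strategies, sweeps."""

from dataclasses import replace

import numpy as np
import pytest

import evocycles as ec


@pytest.fixture(scope="module")
def amp0(fig2b):
    """Non-seasonal version of the worked seasonal example."""
    return replace(fig2b.epi, amp=0.0)


class TestSelectionGradient:
    def test_negative_above_singular_point(self, amp0, fig2b):
        g = ec.selection_gradient("seasonal", amp0, fig2b.tradeoff, 0.4)
        assert g < 0

    def test_step_robustness(self, amp0, fig2b):
        """Halving the step changes the gradient by < 5% away from the root."""
        g1 = ec.selection_gradient("seasonal", amp0, fig2b.tradeoff, 0.35, step=1e-3)
        g2 = ec.selection_gradient("seasonal", amp0, fig2b.tradeoff, 0.35, step=5e-4)
        assert abs(g1 - g2) / abs(g1) < 0.05

    def test_vanishes_at_singular_point(self, amp0, fig2b):
        s = ec.find_singular_strategy("seasonal", amp0, fig2b.tradeoff, (0.05, 0.5))
        assert abs(s.gradient) < 1e-3


class TestFindSingularStrategy:
    def test_nonseasonal_singular_point_at_caption_value(self, amp0, fig2b):
        """tau1 = 1.58 puts the non-seasonal singular point at beta = 0.2."""
        s = ec.find_singular_strategy("seasonal", amp0, fig2b.tradeoff, (0.05, 0.5))
        assert s.beta_star == pytest.approx(0.2, abs=0.005)

    def test_bracket_choice_invariance(self, amp0, fig2b):
        s1 = ec.find_singular_strategy("seasonal", amp0, fig2b.tradeoff, (0.05, 0.5))
        s2 = ec.find_singular_strategy("seasonal", amp0, fig2b.tradeoff, (0.18, 0.35))
        assert abs(s1.beta_star - s2.beta_star) < 2e-4

    def test_no_sign_change_rejected(self, amp0, fig2b):
        with pytest.raises(ValueError, match="singular"):
            ec.find_singular_strategy("seasonal", amp0, fig2b.tradeoff, (0.3, 0.5))


class TestClassification:
    def test_amp0_matches_symbolic_curvatures(self, amp0, fig2b):
        """Finite-difference classification agrees with symbolic derivatives
        of the closed-form equilibrium fitness."""
        sympy = pytest.importorskip("sympy")
        for tau2 in (-3.0, 3.0):
            tr = replace(fig2b.tradeoff, tau2=tau2)
            s = ec.find_singular_strategy("seasonal", amp0, tr, (0.05, 0.5))
            c = ec.classify_singular_strategy("seasonal", amp0, tr, s.beta_star)

            bm, br = sympy.symbols("bm br", positive=True)
            a0q, q, b, al, g = 10.0, amp0.q0, amp0.b, amp0.alpha, amp0.gamma
            a = tr.a_ref - (tr.tau1**2 / tr.tau2) * (1 - sympy.exp((bm - tr.beta_ref) * tr.tau2 / tr.tau1))
            a_r = a.subs(bm, br)
            S = (b + al + g) / br
            I = (a_r - q * S - b) * S / ((q + br) * S - g)
            D = b + bm * I
            s_expr = (a - q * (S + I)) / D + g * bm * I / (D * (al + b + g)) - 1
            d2 = float(sympy.diff(s_expr, bm, 2).subs({bm: s.beta_star, br: s.beta_star}))
            dg = sympy.diff(s_expr, bm).subs(bm, br)
            conv = float(sympy.diff(dg, br).subs(br, s.beta_star))
            assert np.sign(c.evol_curvature) == np.sign(d2)
            assert c.evol_curvature == pytest.approx(d2, rel=0.05)
            assert np.sign(c.conv_slope) == np.sign(conv)

    def test_seasonal_css_vs_branching_flip(self, fig2b, fig2c):
        """Trade-off curvature flips the seasonal singular point CSS -> branching."""
        ctx_b = ec.ResidentContext(fig2b.variant, fig2b.epi, fig2b.tradeoff)
        s_b = ec.find_singular_strategy(fig2b.variant, fig2b.epi, fig2b.tradeoff,
                                        (0.05, 0.5), context=ctx_b)
        c_b = ec.classify_singular_strategy(fig2b.variant, fig2b.epi, fig2b.tradeoff,
                                            s_b.beta_star, context=ctx_b)
        assert c_b.label == "CSS"
        assert c_b.converg_stable and c_b.evol_stable

        ctx_c = ec.ResidentContext(fig2c.variant, fig2c.epi, fig2c.tradeoff)
        s_c = ec.find_singular_strategy(fig2c.variant, fig2c.epi, fig2c.tradeoff,
                                        (0.05, 0.5), context=ctx_c)
        c_c = ec.classify_singular_strategy(fig2c.variant, fig2c.epi, fig2c.tradeoff,
                                            s_c.beta_star, context=ctx_c)
        assert c_c.label == "branching"
        assert c_c.converg_stable and not c_c.evol_stable


@pytest.fixture(scope="module")
def pip2c(fig2c):
    return ec.pairwise_invasion_plot(fig2c.variant, fig2c.epi, fig2c.tradeoff,
                                     (0.15, 0.35), n=21, zero_tolerance=1e-5)


class TestPIP:
    def test_diagonal_neutral(self, pip2c):
        d = np.diagonal(pip2c.fitness_matrix)
        ok = ~np.isnan(d)
        assert np.all(np.abs(d[ok]) < 1e-5)

    def test_branching_vertical_line_positive(self, fig2c):
        """On the vertical through the branching point, fitness is positive
        above and below the singular resident (any nearby mutant invades)."""
        ctx = ec.ResidentContext(fig2c.variant, fig2c.epi, fig2c.tradeoff)
        s = ec.find_singular_strategy(fig2c.variant, fig2c.epi, fig2c.tradeoff,
                                      (0.15, 0.35), context=ctx)
        for delta in (0.005, 0.01, 0.02):
            assert ctx.fitness(s.beta_star + delta, s.beta_star) > 0
            assert ctx.fitness(s.beta_star - delta, s.beta_star) > 0

    def test_css_vertical_line_negative(self, fig2b):
        """On the vertical through the CSS, fitness is negative above and
        below the singular resident (uninvadable strategy)."""
        ctx = ec.ResidentContext(fig2b.variant, fig2b.epi, fig2b.tradeoff)
        s = ec.find_singular_strategy(fig2b.variant, fig2b.epi, fig2b.tradeoff,
                                      (0.15, 0.35), context=ctx)
        for delta in (0.005, 0.01, 0.02):
            assert ctx.fitness(s.beta_star + delta, s.beta_star) < 0
            assert ctx.fitness(s.beta_star - delta, s.beta_star) < 0

    def test_disease_free_columns_flagged(self, fig2c):
        pip = ec.pairwise_invasion_plot(fig2c.variant, fig2c.epi, fig2c.tradeoff,
                                        (0.05, 0.3), n=20)
        assert len(pip.failed_columns) > 0
        for j in pip.failed_columns:
            assert np.all(np.isnan(pip.fitness_matrix[:, j]))

    def test_small_grid_rejected(self, fig2c):
        with pytest.raises(ValueError):
            ec.pairwise_invasion_plot(fig2c.variant, fig2c.epi, fig2c.tradeoff,
                                      (0.15, 0.35), n=10)


class TestSweep:
    def test_amp0_matches_equilibrium_pipeline(self, amp0, fig2b):
        """At zero amplitude the sweep agrees with the pure closed-form route."""
        df = ec.css_parameter_sweep("seasonal", amp0, fig2b.tradeoff, "amp", [0.0],
                                    (0.05, 0.5))
        # independent oracle: brentq on the closed-form NGM gradient
        from scipy.optimize import brentq

        def grad(br, h=1e-6):
            p = amp0.with_beta(br)
            return (ec.ngm_fitness_equilibrium(p, fig2b.tradeoff, br + h, br)
                    - ec.ngm_fitness_equilibrium(p, fig2b.tradeoff, br - h, br)) / (2 * h)

        beta_oracle = brentq(grad, 0.18, 0.35, xtol=1e-10)
        assert abs(df["beta_star"].iloc[0] - beta_oracle) < 1e-3

    def test_lost_css_flagged_and_sweep_continues(self, fig2b):
        # tau1 far too small: no interior singular point anywhere
        tr = replace(fig2b.tradeoff, tau1=0.1)
        p = replace(fig2b.epi, amp=0.0)
        df = ec.css_parameter_sweep("seasonal", p, tr, "amp", [0.0, 0.0], (0.05, 0.5))
        assert list(df["kind"]) == ["lost", "lost"]
        assert len(df) == 2


class TestCalibration:
    def test_reproduces_printed_tau1_at_default_competition(self, amp0, fig2b):
        tr = ec.calibrate_tradeoff(amp0, fig2b.tradeoff)
        assert tr.tau1 == pytest.approx(1.58, abs=0.005)

    def test_pins_singular_point_at_reference(self, amp0, fig2b):
        p = replace(amp0, q0=0.1)
        tr = ec.calibrate_tradeoff(p, fig2b.tradeoff)
        s = ec.find_singular_strategy("seasonal", p, tr, (0.05, 0.5))
        assert s.beta_star == pytest.approx(0.2, abs=0.005)
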