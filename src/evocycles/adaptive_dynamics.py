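"""Selection gradients, pairwise invasion plots, singular strategies, sweeps.

Evolution proceeds by small trait substitutions up the local fitness
gradient; a singular strategy is a trait value where the selection
gradient vanishes.  Its character is read off two curvatures:

* evolutionary stability — d2 s / d beta_m^2 < 0 at the singular point
  (no nearby mutant can invade);
* convergence stability — d/d beta_r of the selection gradient < 0
  (nearby residents evolve toward the point).

Both flags together give a continuously stable strategy (CSS);
convergence-stable but invadable points are evolutionary branching
points, where disruptive selection splits the population in two.
All derivatives are central finite differences of invasion fitness,
which is itself computed from the resident attractor (closed-form at
equilibria, Floquet exponents on cycles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .attractor import CycleAttractor, SolverOptions, compute_attractor, NotOnAttractorError
from .fitness import invasion_fitness
from .params import EpiParams, TradeoffParams

__all__ = [
    "PIPGrid",
    "SingularStrategy",
    "ResidentContext",
    "selection_gradient",
    "pairwise_invasion_plot",
    "find_singular_strategy",
    "classify_singular_strategy",
    "css_parameter_sweep",
    "calibrate_tradeoff",
]


def calibrate_tradeoff(p: EpiParams, tr: TradeoffParams) -> TradeoffParams:
    """Trade-off gradient that puts the non-seasonal singular point at beta_ref.

    At an endemic equilibrium of the constant-environment model the
    selection gradient vanishes exactly when the marginal birth benefit
    of raised transmission balances the marginal infection cost:

        a'(beta*) = I* (b + alpha) / (b + alpha + gamma),

    obtained by perturbing the neutral (zero) eigenvalue of the mutant
    Jacobian in beta_m.  Since a(beta_ref) = a_ref independently of
    tau1, setting tau1 to this value pins the non-seasonal singular
    strategy at beta_ref for any competition/virulence/recovery setting
    — the construction behind comparing sweeps across panels that keep
    the same reference trait.  (The printed tau1 = 1.58 is this value
    at the default q0 = 0.5.)
    """
    from .models import analytic_equilibrium, effective_params

    _, I_star = analytic_equilibrium(effective_params(p, tr, tr.beta_ref))
    from dataclasses import replace

    return replace(tr, tau1=float(I_star * (p.b + p.alpha) / (p.b + p.alpha + p.gamma)))


@dataclass
class PIPGrid:
    """Sign chart of invasion fitness over a (resident, mutant) trait grid."""

    trait_values: np.ndarray
    sign_matrix: np.ndarray  # [i_mutant, j_resident]: -1, 0, +1; nan = resident failed
    fitness_matrix: np.ndarray
    zero_tolerance: float
    failed_columns: list[int] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per (beta_r, beta_m) pair."""
        br, bm = np.meshgrid(self.trait_values, self.trait_values)
        return pd.DataFrame({
            "beta_r": br.ravel(),
            "beta_m": bm.ravel(),
            "fitness": self.fitness_matrix.ravel(),
            "sign": self.sign_matrix.ravel(),
        })


@dataclass
class SingularStrategy:
    """A located singular trait value with stability classification."""

    beta_star: float
    converg_stable: bool | None = None
    evol_stable: bool | None = None
    label: str = "unclassified"
    gradient: float | None = None
    evol_curvature: float | None = None
    conv_slope: float | None = None
    curvature_step: float | None = None


class ResidentContext:
    """Caches resident attractors (warm-started) for one parameter set.

    Repeated fitness evaluations in gradients, bisection and sweeps
    revisit nearby resident traits; this context memoizes attractors per
    resident trait and seeds each new integration from the last end
    state, which shortcuts the ecological transient.
    """

    def __init__(self, variant, p: EpiParams, tr: TradeoffParams | None, *,
                 solver: SolverOptions = SolverOptions(), method: str | None = None,
                 attractor_kwargs: dict | None = None, warm_burn_in: float = 100.0):
        self.variant = variant
        self.p = p
        self.tr = tr
        self.solver = solver
        self.method = method
        self.attractor_kwargs = dict(attractor_kwargs or {})
        self.warm_burn_in = warm_burn_in
        self._cache: dict[float, CycleAttractor] = {}
        self._last_state = None

    def attractor(self, beta_r: float) -> CycleAttractor:
        key = float(beta_r)
        if key not in self._cache:
            kw = dict(self.attractor_kwargs)
            if self._last_state is not None and "warm_start" not in kw:
                kw["warm_start"] = self._last_state
                # a short burn-in suffices from a nearby attractor; the
                # closure check extends it automatically if not
                if self.warm_burn_in is not None:
                    kw["burn_in"] = self.warm_burn_in
            cyc, trace = compute_attractor(self.variant, self.p.with_beta(key), self.tr,
                                           solver=self.solver, **kw)
            self._cache[key] = cyc
            self._last_state = trace.end_state
        return self._cache[key]

    def fitness(self, beta_m: float, beta_r: float) -> float:
        return invasion_fitness(self.variant, self.p, self.tr, beta_m, beta_r,
                                attractor=self.attractor(beta_r), method=self.method,
                                solver=self.solver).value

    def gradient(self, beta_r: float, h: float = 1e-3) -> float:
        return (self.fitness(beta_r + h, beta_r) - self.fitness(beta_r - h, beta_r)) / (2.0 * h)


def selection_gradient(variant, p, tr, beta_r, *, step: float = 1e-3,
                       context: ResidentContext | None = None, **ctx_kwargs) -> float:
    """Central-difference selection gradient d s(beta_m, beta_r)/d beta_m at beta_m = beta_r."""
    if step <= 0:
        raise ValueError("step must be positive")
    ctx = context or ResidentContext(variant, p, tr, **ctx_kwargs)
    return ctx.gradient(beta_r, step)


def pairwise_invasion_plot(variant, p, tr, trait_range, n: int = 41, *,
                           zero_tolerance: float = 1e-5,
                           context: ResidentContext | None = None,
                           **ctx_kwargs) -> PIPGrid:
    """Sign of invasion fitness on an n x n (resident, mutant) grid.

    Resident attractors are recomputed per column, warm-started from the
    previous column.  Columns whose resident is disease-free (or whose
    attractor fails) are flagged rather than silently zeroed.
    """
    if n < 20:
        raise ValueError("PIP grid must have n >= 20")
    lo, hi = trait_range
    grid = np.linspace(lo, hi, n)
    ctx = context or ResidentContext(variant, p, tr, **ctx_kwargs)
    fit = np.full((n, n), np.nan)
    failed = []
    for j, br in enumerate(grid):
        try:
            ctx.attractor(br)
        except (NotOnAttractorError, RuntimeError, ValueError) as err:
            warnings.warn(f"PIP column beta_r={br:.4g} failed: {err}")
            failed.append(j)
            continue
        for i, bm in enumerate(grid):
            fit[i, j] = ctx.fitness(bm, br)
    sign = np.where(np.abs(fit) <= zero_tolerance, 0.0, np.sign(fit))
    return PIPGrid(trait_values=grid, sign_matrix=sign, fitness_matrix=fit,
                   zero_tolerance=zero_tolerance, failed_columns=failed)


def find_singular_strategy(variant, p, tr, bracket, *, xtol: float = 1e-4,
                           step: float = 1e-3,
                           context: ResidentContext | None = None,
                           **ctx_kwargs) -> SingularStrategy:
    """Locate a zero of the selection gradient inside ``bracket``.

    The gradient must change sign across the bracket; the root is
    bracketed down to ``xtol`` (trait units).  A bracket end at which
    the resident parasite cannot persist (disease-free attractor, where
    invasion fitness is undefined) is slid inward to the endemic
    region.  Classification flags are left unset — see
    :func:`classify_singular_strategy`.
    """
    from .models import DiseaseFreeError

    lo, hi = float(bracket[0]), float(bracket[1])
    ctx = context or ResidentContext(variant, p, tr, **ctx_kwargs)

    def grad_or_none(b):
        try:
            return ctx.gradient(b, step)
        except (NotOnAttractorError, DiseaseFreeError):
            return None

    fractions = np.linspace(0.0, 1.0, 17)
    g_lo = g_hi = None
    for f in fractions:
        b = lo + f * (hi - lo)
        g_lo = grad_or_none(b)
        if g_lo is not None:
            lo = b
            break
    for f in fractions:
        b = hi - f * (hi - lo)
        g_hi = grad_or_none(b)
        if g_hi is not None:
            hi = b
            break
    if g_lo is None or g_hi is None or not lo < hi:
        raise ValueError("no endemic resident anywhere in the bracket: "
                         "singular strategy undefined")
    if np.sign(g_lo) == np.sign(g_hi):
        raise ValueError(
            f"no interior singular point: selection gradient has the same sign "
            f"({g_lo:.3g}, {g_hi:.3g}) at both bracket ends ({lo}, {hi})")
    beta_star = brentq(lambda b: ctx.gradient(b, step), lo, hi, xtol=xtol)
    return SingularStrategy(beta_star=float(beta_star),
                            gradient=ctx.gradient(beta_star, step))


def classify_singular_strategy(variant, p, tr, beta_star, *, step: float = 5e-3,
                               gradient_step: float = 1e-3,
                               curvature_floor: float = 1e-3,
                               context: ResidentContext | None = None,
                               **ctx_kwargs) -> SingularStrategy:
    """Stability flags and label for a located singular strategy.

    Evolutionary stability: finite-difference curvature of s in beta_m
    at the singular resident; convergence stability: finite-difference
    slope of the selection gradient across beta_r.  Curvatures with
    magnitude below ``curvature_floor`` are reported as indeterminate
    rather than guessed.
    """
    ctx = context or ResidentContext(variant, p, tr, **ctx_kwargs)
    b, h = float(beta_star), step
    s0 = ctx.fitness(b, b)
    s_up = ctx.fitness(b + h, b)
    s_dn = ctx.fitness(b - h, b)
    evol_curv = (s_up - 2.0 * s0 + s_dn) / h**2
    conv_slope = (ctx.gradient(b + h, gradient_step) - ctx.gradient(b - h, gradient_step)) / (2.0 * h)

    if abs(evol_curv) < curvature_floor or abs(conv_slope) < curvature_floor:
        return SingularStrategy(beta_star=b, label="indeterminate",
                                evol_curvature=float(evol_curv),
                                conv_slope=float(conv_slope), curvature_step=h)
    evol = bool(evol_curv < 0)
    conv = bool(conv_slope < 0)
    label = {(True, True): "CSS", (True, False): "branching",
             (False, True): "garden_of_eden", (False, False): "repeller"}[(conv, evol)]
    return SingularStrategy(beta_star=b, converg_stable=conv, evol_stable=evol,
                            label=label, evol_curvature=float(evol_curv),
                            conv_slope=float(conv_slope), curvature_step=h)


def css_parameter_sweep(variant, p, tr, parameter, values, bracket, *,
                        xtol: float = 1e-4, classify: bool = False,
                        bracket_width: float | None = None,
                        solver: SolverOptions = SolverOptions(),
                        attractor_kwargs: dict | None = None,
                        **ctx_kwargs) -> pd.DataFrame:
    """Track a singular strategy across a parameter sweep by continuation.

    For each value of ``parameter`` the previous singular trait seeds a
    local bracket (re-expanded toward the original bracket if the
    gradient does not change sign), and the previous resident end state
    warm-starts the integration.  The resident attractor's kind, period
    and multiplicity at the located trait are recorded alongside.  A
    lost root flags the row and the sweep continues.
    """
    from dataclasses import replace

    lo0, hi0 = float(bracket[0]), float(bracket[1])
    width0 = bracket_width if bracket_width is not None else 0.25 * (hi0 - lo0)
    rows = []
    prev_star = None
    for v in values:
        p_v = replace(p, **{parameter: float(v)})
        ctx = ResidentContext(variant, p_v, tr, solver=solver,
                              attractor_kwargs=attractor_kwargs, **ctx_kwargs)
        brackets = [(lo0, hi0)] if prev_star is None else [
            (max(lo0, prev_star - width0), min(hi0, prev_star + width0)), (lo0, hi0)]
        strategy = None
        err_msg = ""
        for lo, hi in brackets:
            try:
                strategy = find_singular_strategy(variant, p_v, tr, (lo, hi),
                                                  xtol=xtol, context=ctx)
                break
            except (ValueError, NotOnAttractorError, RuntimeError) as err:
                err_msg = str(err)
        if strategy is None:
            rows.append({parameter: v, "beta_star": np.nan, "kind": "lost",
                         "period": np.nan, "multiplicity": 0, "label": "lost",
                         "note": err_msg})
            continue
        att = ctx.attractor(strategy.beta_star)
        label = "unclassified"
        if classify:
            label = classify_singular_strategy(variant, p_v, tr, strategy.beta_star,
                                               context=ctx).label
        rows.append({parameter: v, "beta_star": strategy.beta_star, "kind": att.kind,
                     "period": att.period if att.kind == "cycle" else np.nan,
                     "multiplicity": att.multiplicity, "label": label, "note": ""})
        prev_star = strategy.beta_star
    return pd.DataFrame(rows)
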