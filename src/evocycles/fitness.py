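"""Mutant invasion fitness on equilibria and limit cycles.

A rare mutant host with trait ``beta_m`` experiences the resident
attractor as an external, time-periodic environment.  Its linearized
dynamics (S_m, I_m) form a linear time-varying system; invasion fitness
is the dominant Floquet exponent of that system,

    mu = ln(rho_max) / T,

where rho_max is the largest eigenvalue (Floquet multiplier) of the
monodromy matrix C mapping the mutant state across one attractor
period T.  C is built by co-integrating the resident equations with the
mutant linearization from two linearly independent mutant initial
conditions ([1,0] and [0,1] by default) and collecting the end states
as columns.  The mutant can invade iff mu > 0 (rho_max > 1).

Two closed-form special cases serve as cross-checks and as the
dispatch target for equilibrium residents:

* ``ngm_fitness_equilibrium`` — the next-generation invasion number
  minus one for a constant resident (per-generation scale, sign
  equivalent to the dominant eigenvalue of the mutant Jacobian);
* ``average_growth_fitness`` — the period-averaged per-capita growth
  rate of an unstructured mutant (recovery gamma = 0), which equals
  the Floquet exponent exactly for that scalar case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .attractor import CycleAttractor, SolverOptions, compute_attractor, NotOnAttractorError
from .models import (TWO_PI, analytic_equilibrium, birth_rate, effective_params,
                     log_rhs, resident_rhs)
from .params import EpiParams, TradeoffParams, n_resident_states

__all__ = [
    "MonodromyResult",
    "InvasionFitness",
    "mutant_rhs",
    "monodromy_matrix",
    "invasion_fitness",
    "ngm_fitness_equilibrium",
    "simple_growth_fitness",
    "average_growth_fitness",
    "mutant_jacobian_equilibrium",
    "eigenvalue_fitness_equilibrium",
]


@dataclass
class MonodromyResult:
    """Monodromy matrix of the mutant subsystem over one attractor period."""

    C: np.ndarray  # (2, 2)
    multipliers: np.ndarray  # eigenvalues rho_i of C
    exponent: float  # dominant Floquet exponent, per unit time
    period_used: float
    resident_drift: float  # relative gap between resident start/end states
    dominant_complex: bool = False


@dataclass
class InvasionFitness:
    beta_m: float
    beta_r: float
    value: float
    method: str  # "floquet" | "ngm_equilibrium" | "average_growth" | "simple_growth"


def _mutant_birth(variant: str, p: EpiParams, tr: TradeoffParams | None, beta_m: float, t):
    a = birth_rate(tr, beta_m) if tr is not None else p.a0
    if variant == "seasonal_births":
        return a * (1.0 + p.amp * np.sin(TWO_PI * t))
    return a


def _env(variant: str, p: EpiParams, t, resident_state):
    """(q(t), total density N, force-of-infection density F) from the resident."""
    if variant == "seasonal":
        q = p.q0 * (1.0 + p.amp * np.sin(TWO_PI * t))
    else:
        q = p.q0
    S, I = resident_state[0], resident_state[1]
    F = resident_state[2] if variant == "free_living" else I
    return q, S + I, F


def mutant_rhs(
    variant: str,
    p: EpiParams,
    tr: TradeoffParams | None,
    beta_m: float,
    t: float,
    m_state: np.ndarray,
    resident_state: np.ndarray,
) -> np.ndarray:
    """Linearized rare-mutant dynamics on the resident background.

    dS_m/dt = (a(beta_m, t) - q(t) N*(t)) S_m - b S_m - beta_m F*(t) S_m + gamma I_m
    dI_m/dt = beta_m F*(t) S_m - (b + alpha + gamma) I_m

    where N* = S* + I* is the resident crowding term and F* is the
    infectious density the mutant meets (I* for direct transmission,
    P* for the free-living variant; rare-mutant shedding into the
    shared propagule pool is negligible, keeping the system 2-D).
    Mutant-mutant terms are absent: the system is linear in (S_m, I_m).
    """
    q, N, F = _env(variant, p, t, np.asarray(resident_state, dtype=float))
    a_m = _mutant_birth(variant, p, tr, beta_m, t)
    Sm, Im = m_state[0], m_state[1]
    dSm = (a_m - q * N) * Sm - p.b * Sm - beta_m * F * Sm + p.gamma * Im
    dIm = beta_m * F * Sm - (p.b + p.alpha + p.gamma) * Im
    return np.array([dSm, dIm])


def monodromy_matrix(
    variant: str,
    p: EpiParams,
    tr: TradeoffParams | None,
    beta_m: float,
    attractor: CycleAttractor,
    *,
    init_basis: np.ndarray | None = None,
    solver: SolverOptions = SolverOptions(),
    drift_tol: float = 1e-2,
) -> MonodromyResult:
    """Monodromy matrix C of the mutant subsystem over one attractor period.

    The resident equations are co-integrated with the mutant
    linearization (the stored attractor supplies only the phase-0 state
    and the period), avoiding interpolation error in stiff regions.
    Columns of C are the mutant end states of the runs started from the
    columns of ``init_basis`` (identity by default); for a non-identity
    basis B the monodromy is recovered as M B^-1, so the multipliers are
    basis independent.
    """
    if attractor.variant != variant:
        raise ValueError(f"attractor was computed for variant {attractor.variant!r}, not {variant!r}")
    p_eff = effective_params(p, tr)  # resident trait p.beta with trade-off applied
    k = n_resident_states(variant)
    B = np.eye(2) if init_basis is None else np.asarray(init_basis, dtype=float)
    if B.shape != (2, 2) or abs(np.linalg.det(B)) < 1e-12:
        raise ValueError("init_basis must be a nonsingular 2x2 matrix")
    use_log = solver.log_for(variant)
    T = attractor.period
    t0 = attractor.phase0_time
    res0 = attractor.phase0_state
    y0 = np.concatenate([np.log(res0) if use_log else res0, B[:, 0], B[:, 1]])

    def rhs(t, y):
        res = y[:k]
        if use_log:
            dres = log_rhs(variant, p_eff, t, res)
            res_lin = np.exp(res)
        else:
            dres = resident_rhs(variant, p_eff, t, res)
            res_lin = res
        dm1 = mutant_rhs(variant, p_eff, tr, beta_m, t, y[k:k + 2], res_lin)
        dm2 = mutant_rhs(variant, p_eff, tr, beta_m, t, y[k + 2:], res_lin)
        return np.concatenate([dres, dm1, dm2])

    sol = solve_ivp(rhs, (t0, t0 + T), y0, method=solver.method,
                    rtol=solver.rtol, atol=solver.atol)
    if not sol.success:
        raise RuntimeError(f"monodromy integration failed: {sol.message}")
    yT = sol.y[:, -1]
    res_T = np.exp(yT[:k]) if use_log else yT[:k]
    drift = float(np.linalg.norm(res_T - res0) / max(np.linalg.norm(res0), 1e-300))
    if attractor.kind == "cycle" and drift > drift_tol:
        raise NotOnAttractorError(
            f"resident drifted off the stored cycle during the monodromy period "
            f"(relative drift {drift:.2e}): attractor not converged")
    M = np.column_stack([yT[k:k + 2], yT[k + 2:]])
    C = M if init_basis is None else M @ np.linalg.inv(B)
    rho = np.linalg.eigvals(C)
    i_max = int(np.argmax(np.abs(rho)))
    rho_max = rho[i_max]
    dominant_complex = bool(abs(rho_max.imag) > 1e-9 * max(1.0, abs(rho_max)))
    if dominant_complex:
        warnings.warn("dominant Floquet multiplier has a nonzero imaginary part; "
                      "using ln|rho|/T (positivity assumption violated?)")
    exponent = float(np.log(abs(rho_max)) / T)
    return MonodromyResult(C=C, multipliers=rho, exponent=exponent, period_used=T,
                           resident_drift=drift, dominant_complex=dominant_complex)


def mutant_jacobian_equilibrium(
    p: EpiParams,
    tr: TradeoffParams | None,
    beta_m: float,
    *,
    N: float,
    F: float,
) -> np.ndarray:
    """Constant mutant Jacobian given resident crowding N and infectious density F."""
    a_m = birth_rate(tr, beta_m) if tr is not None else p.a0
    return np.array([
        [a_m - p.q0 * N - p.b - beta_m * F, p.gamma],
        [beta_m * F, -(p.b + p.alpha + p.gamma)],
    ])


def eigenvalue_fitness_equilibrium(p, tr, beta_m, *, N, F) -> float:
    """Dominant eigenvalue of the constant mutant Jacobian (growth-rate scale)."""
    ev = np.linalg.eigvals(mutant_jacobian_equilibrium(p, tr, beta_m, N=N, F=F))
    return float(np.max(ev.real))


def _equilibrium_env(variant, p, tr, beta_r, attractor=None):
    """(N, F) for a constant resident with trait beta_r."""
    p_r = effective_params(p, tr, beta_r)
    if variant in ("baseline", "seasonal", "seasonal_births") and (variant == "baseline" or p.amp == 0.0):
        S, I = analytic_equilibrium(p_r)
        return S + I, I
    if attractor is None or attractor.kind != "equilibrium":
        raise ValueError("equilibrium fitness needs an equilibrium attractor for this variant")
    st = attractor.states[-1]
    F = st[2] if variant == "free_living" else st[1]
    return float(st[0] + st[1]), float(F)


def ngm_fitness_equilibrium(
    p: EpiParams,
    tr: TradeoffParams | None,
    beta_m: float,
    beta_r: float | None = None,
    *,
    variant: str = "baseline",
    attractor: CycleAttractor | None = None,
) -> float:
    """Next-generation invasion fitness at a constant resident state.

    s = (a(beta_m) - q N*) / (b + beta_m F*)
        + gamma beta_m F* / ((b + beta_m F*)(alpha + b + gamma)) - 1

    The first term is the expected lifetime reproduction of a mutant
    susceptible; the second is its probability of being infected and
    recovering back into the susceptible class.  s > 0 iff the dominant
    eigenvalue of the mutant Jacobian is positive (per-generation
    scale).  F* is I* for direct transmission and P* for the
    free-living variant.
    """
    beta_r = p.beta if beta_r is None else beta_r
    N, F = _equilibrium_env(variant, p, tr, beta_r, attractor)
    a_m = birth_rate(tr, beta_m) if tr is not None else p.a0
    D = p.b + beta_m * F
    return float((a_m - p.q0 * N) / D
                 + p.gamma * beta_m * F / (D * (p.alpha + p.b + p.gamma)) - 1.0)


def simple_growth_fitness(
    p: EpiParams,
    tr: TradeoffParams | None,
    beta_m: float,
    beta_r: float | None = None,
    *,
    variant: str = "baseline",
    attractor: CycleAttractor | None = None,
) -> float:
    """Unstructured-mutant growth rate for gamma = 0 at a constant resident:
    s = a(beta_m) - q (S* + I*) - b - beta_m F*."""
    if p.gamma != 0.0:
        raise ValueError("simple growth-rate fitness requires gamma = 0 (unstructured mutant)")
    beta_r = p.beta if beta_r is None else beta_r
    N, F = _equilibrium_env(variant, p, tr, beta_r, attractor)
    a_m = birth_rate(tr, beta_m) if tr is not None else p.a0
    return float(a_m - p.q0 * N - p.b - beta_m * F)


def average_growth_fitness(
    variant: str,
    p: EpiParams,
    tr: TradeoffParams | None,
    beta_m: float,
    attractor: CycleAttractor,
    *,
    solver: SolverOptions = SolverOptions(),
) -> float:
    """Period-averaged growth rate of an unstructured mutant (gamma = 0):

        r = (1/T) int_0^T [ a(beta_m, t) - q(t)(S*(t) + I*(t)) - beta_m F*(t) ] dt - b.

    The integrand is accumulated alongside a co-integration of the
    resident over one stored period; for this scalar linear case the
    value equals the Floquet exponent exactly (up to solver tolerance).
    """
    if p.gamma != 0.0:
        raise ValueError("average growth-rate fitness requires gamma = 0 (unstructured mutant)")
    p_eff = effective_params(p, tr)
    k = n_resident_states(variant)
    use_log = solver.log_for(variant)
    t0, T = attractor.phase0_time, attractor.period
    res0 = attractor.phase0_state
    y0 = np.concatenate([np.log(res0) if use_log else res0, [0.0]])

    def rhs(t, y):
        res = y[:k]
        if use_log:
            dres = log_rhs(variant, p_eff, t, res)
            res_lin = np.exp(res)
        else:
            dres = resident_rhs(variant, p_eff, t, res)
            res_lin = res
        q, N, F = _env(variant, p_eff, t, res_lin)
        a_m = _mutant_birth(variant, p_eff, tr, beta_m, t)
        return np.concatenate([dres, [a_m - q * N - beta_m * F]])

    sol = solve_ivp(rhs, (t0, t0 + T), y0, method=solver.method,
                    rtol=solver.rtol, atol=solver.atol)
    if not sol.success:
        raise RuntimeError(f"average-growth integration failed: {sol.message}")
    return float(sol.y[-1, -1] / T - p.b)


def invasion_fitness(
    variant: str,
    p: EpiParams,
    tr: TradeoffParams | None,
    beta_m: float,
    beta_r: float | None = None,
    *,
    attractor: CycleAttractor | None = None,
    method: str | None = None,
    solver: SolverOptions = SolverOptions(),
    attractor_kwargs: dict | None = None,
) -> InvasionFitness:
    """Invasion fitness s(beta_m, beta_r) with automatic method dispatch.

    The resident attractor (computed on demand) decides the method:
    equilibrium residents use the next-generation closed form, cyclic
    residents the Floquet exponent of the monodromy matrix.  Pass
    ``method`` to override (e.g. "floquet" on an equilibrium, which
    integrates the degenerate constant cycle and returns the dominant
    Jacobian eigenvalue).  A mutant equal to the resident is neutral:
    s(beta, beta) = 0 up to solver tolerance.
    """
    beta_r = float(p.beta if beta_r is None else beta_r)
    p_r = p.with_beta(beta_r)
    if attractor is None:
        attractor, _ = compute_attractor(variant, p_r, tr, solver=solver,
                                         **(attractor_kwargs or {}))
    if method is None:
        method = "ngm_equilibrium" if attractor.kind == "equilibrium" else "floquet"
    if method == "floquet":
        res = monodromy_matrix(variant, p_r, tr, beta_m, attractor, solver=solver)
        value = res.exponent
    elif method == "ngm_equilibrium":
        value = ngm_fitness_equilibrium(p_r, tr, beta_m, beta_r, variant=variant,
                                        attractor=attractor)
    elif method == "average_growth":
        value = average_growth_fitness(variant, p_r, tr, beta_m, attractor, solver=solver)
    elif method == "simple_growth":
        value = simple_growth_fitness(p_r, tr, beta_m, beta_r, variant=variant,
                                      attractor=attractor)
    else:
        raise ValueError(f"unknown fitness method {method!r}")
    return InvasionFitness(beta_m=float(beta_m), beta_r=beta_r, value=float(value), method=method)
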