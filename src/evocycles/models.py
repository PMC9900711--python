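"""Right-hand sides and closed-form ecology of the resident models.

Resident dynamics (direct-transmission variants)::

    dS/dt = (a(t) - q(t) (S + I)) S - b S - beta S I + gamma I
    dI/dt = beta S I - (b + alpha + gamma) I

with ``q(t) = q0 (1 + amp sin 2 pi t)`` for the seasonally forced
competition variant and ``a(t) = a0 (1 + amp sin 2 pi t)`` for the
seasonally forced birth variant.

Free-living variant (transmission through environmental propagules P)::

    dS/dt = (a - q (S + I)) S - b S - beta S P + gamma I
    dI/dt = beta S P - (b + alpha + gamma) I
    dP/dt = theta I - decay P

The free-living system is frequently stiff enough that even implicit
solvers stall in linear coordinates; a log-transformed right-hand side
(X = ln S, Y = ln I, Z = ln P) is provided for all variants so the same
remedy is uniformly available.
"""

from __future__ import annotations

import numpy as np

from .params import EpiParams, TradeoffParams, n_resident_states

__all__ = [
    "birth_rate",
    "birth_rate_derivatives",
    "seasonal_competition",
    "resident_rhs",
    "log_rhs",
    "analytic_equilibrium",
    "basic_reproduction_number",
    "effective_params",
    "DiseaseFreeError",
    "HostNonviableError",
]

TWO_PI = 2.0 * np.pi


class DiseaseFreeError(ValueError):
    """The parasite cannot persist (R0 <= 1): endemic equilibrium invalid."""


class HostNonviableError(ValueError):
    """The host population itself cannot persist (a0 <= b)."""


def birth_rate(tr: TradeoffParams, beta) -> float:
    """Host birth rate a(beta) under the defence trade-off.

    a(beta) = a_ref - (tau1^2/tau2) (1 - exp((beta - beta_ref) tau2/tau1)).
    """
    z = (np.asarray(beta, dtype=float) - tr.beta_ref) * tr.tau2 / tr.tau1
    out = tr.a_ref - (tr.tau1**2 / tr.tau2) * (1.0 - np.exp(z))
    return out if out.ndim else float(out)


def birth_rate_derivatives(tr: TradeoffParams, beta: float) -> tuple[float, float]:
    """(a'(beta), a''(beta)); at beta_ref these are exactly (tau1, tau2)."""
    e = np.exp((beta - tr.beta_ref) * tr.tau2 / tr.tau1)
    return tr.tau1 * e, tr.tau2 * e


def seasonal_competition(q0: float, amp: float, t) -> float:
    """Seasonally forced competition coefficient q(t) = q0 (1 + amp sin 2 pi t)."""
    return q0 * (1.0 + amp * np.sin(TWO_PI * np.asarray(t, dtype=float)))


def effective_params(p: EpiParams, tr: TradeoffParams | None, beta: float | None = None) -> EpiParams:
    """Resident parameters with the trade-off applied.

    Returns a copy of ``p`` whose birth rate is a(beta) and whose
    transmission is ``beta`` (defaults to ``p.beta``).  With ``tr=None``
    the trait change only swaps ``beta``.
    """
    from dataclasses import replace

    b = p.beta if beta is None else float(beta)
    if tr is None:
        return p.with_beta(b)
    return replace(p, beta=b, a0=float(birth_rate(tr, b)))


def _rates(variant: str, p: EpiParams, t):
    """Time-resolved (a, q) for the variant at time t."""
    if variant == "seasonal":
        return p.a0, seasonal_competition(p.q0, p.amp, t)
    if variant == "seasonal_births":
        return p.a0 * (1.0 + p.amp * np.sin(TWO_PI * t)), p.q0
    return p.a0, p.q0


def resident_rhs(variant: str, p: EpiParams, t: float, state: np.ndarray) -> np.ndarray:
    """Time derivatives of the resident densities.

    ``state`` is (S, I) for the 2-state variants and (S, I, P) for
    ``free_living``; raises ``ValueError`` on a dimension mismatch.
    """
    state = np.asarray(state, dtype=float)
    k = n_resident_states(variant)
    if state.shape[-1] != k:
        raise ValueError(f"variant {variant!r} expects {k} state variables, got {state.shape[-1]}")
    a, q = _rates(variant, p, t)
    if variant == "free_living":
        S, I, P = state[..., 0], state[..., 1], state[..., 2]
        foi = p.beta * P
        dP = p.theta * I - p.decay * P
    else:
        S, I = state[..., 0], state[..., 1]
        foi = p.beta * I
    dS = (a - q * (S + I)) * S - p.b * S - foi * S + p.gamma * I
    dI = foi * S - (p.b + p.alpha + p.gamma) * I
    if variant == "free_living":
        return np.stack([dS, dI, dP], axis=-1)
    return np.stack([dS, dI], axis=-1)


def log_rhs(variant: str, p: EpiParams, t: float, logstate: np.ndarray) -> np.ndarray:
    """Derivatives of the log-densities X = ln S, Y = ln I (, Z = ln P).

    For the free-living variant::

        dX/dt = a - q (e^X + e^Y) - b - beta e^Z + gamma e^(Y-X)
        dY/dt = beta e^(X+Z-Y) - (b + alpha + gamma)
        dZ/dt = theta e^(Y-Z) - decay

    The 2-state variants drop Z and use beta e^Y as the force of
    infection.  Exponentiating a log-space trajectory reproduces the
    linear-space trajectory exactly (change of variables).
    """
    logstate = np.asarray(logstate, dtype=float)
    k = n_resident_states(variant)
    if logstate.shape[-1] != k:
        raise ValueError(f"variant {variant!r} expects {k} log-state variables, got {logstate.shape[-1]}")
    a, q = _rates(variant, p, t)
    if variant == "free_living":
        X, Y, Z = logstate[..., 0], logstate[..., 1], logstate[..., 2]
        dX = a - q * (np.exp(X) + np.exp(Y)) - p.b - p.beta * np.exp(Z) + p.gamma * np.exp(Y - X)
        dY = p.beta * np.exp(X + Z - Y) - (p.b + p.alpha + p.gamma)
        dZ = p.theta * np.exp(Y - Z) - p.decay
        return np.stack([dX, dY, dZ], axis=-1)
    X, Y = logstate[..., 0], logstate[..., 1]
    dX = a - q * (np.exp(X) + np.exp(Y)) - p.b - p.beta * np.exp(Y) + p.gamma * np.exp(Y - X)
    dY = p.beta * np.exp(X) - (p.b + p.alpha + p.gamma)
    return np.stack([dX, dY], axis=-1)


def analytic_equilibrium(p: EpiParams) -> tuple[float, float]:
    """Endemic equilibrium (S*, I*) of the baseline (constant) model.

    S* = (b + alpha + gamma)/beta and, from dS/dt = 0,
    I* = (a0 - q S* - b) S* / ((q + beta) S* - gamma).

    Raises :class:`DiseaseFreeError` when R0 <= 1 (no endemic state).
    """
    if basic_reproduction_number(p) <= 1.0:
        raise DiseaseFreeError("R0 <= 1: the parasite dies out; resident attractor is disease-free")
    S = (p.b + p.alpha + p.gamma) / p.beta
    I = (p.a0 - p.q0 * S - p.b) * S / ((p.q0 + p.beta) * S - p.gamma)
    return float(S), float(I)


def basic_reproduction_number(p: EpiParams, variant: str = "baseline") -> float:
    """Parasite basic reproduction number R0 at the disease-free equilibrium.

    The disease-free host density is S_dfe = (a0 - b)/q0 (positive root of
    (a - q S) S = b S).  Direct-transmission variants give
    R0 = beta S_dfe / (b + alpha + gamma); the free-living variant picks
    up the propagule loop, multiplying by theta/decay.
    """
    if p.a0 <= p.b:
        raise HostNonviableError(f"host population not viable: a0={p.a0} <= b={p.b}")
    S_dfe = (p.a0 - p.b) / p.q0
    r0 = p.beta * S_dfe / (p.b + p.alpha + p.gamma)
    if variant == "free_living":
        if p.decay <= 0:
            raise ValueError("free_living variant needs decay > 0 for a finite R0")
        r0 *= p.theta / p.decay
    return float(r0)
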