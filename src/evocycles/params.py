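"""Parameter containers for the host-parasite model family.

Three model variants share one parameter set:

``baseline``
    Density-dependent SIS host-parasite model with crowding, virulence
    and recovery; constant environment, endemic equilibrium.
``seasonal``
    Same model with the competition coefficient forced sinusoidally,
    q(t) = q0 (1 + amp sin 2*pi*t); the attractor is an annual limit
    cycle (or an integer multiple of it after period doubling).
``seasonal_births``
    The classic alternative in which the birth rate is forced instead,
    a(t) = a0 (1 + amp sin 2*pi*t).
``free_living``
    Transmission via free-living parasite propagules P shed by infected
    hosts; limit cycles arise intrinsically, with no external forcing.

The host trait under selection is the transmission coefficient ``beta``
(lower beta = better-defended host), paid for through a reduced birth
rate via :class:`TradeoffParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Literal

__all__ = [
    "EpiParams",
    "TradeoffParams",
    "Variant",
    "VARIANTS",
    "n_resident_states",
    "is_forced",
]

Variant = Literal["baseline", "seasonal", "seasonal_births", "free_living"]
VARIANTS: tuple[str, ...] = ("baseline", "seasonal", "seasonal_births", "free_living")

#: number of resident state variables per variant ((S, I) or (S, I, P))
_N_STATES = {"baseline": 2, "seasonal": 2, "seasonal_births": 2, "free_living": 3}

#: variants with external sinusoidal forcing of period 1
_FORCED = frozenset({"seasonal", "seasonal_births"})


def n_resident_states(variant: str) -> int:
    """Dimension of the resident state vector for ``variant``."""
    try:
        return _N_STATES[variant]
    except KeyError:
        raise ValueError(f"unknown model variant {variant!r}; expected one of {VARIANTS}") from None


def is_forced(variant: str) -> bool:
    """True for variants with external seasonal forcing (period-1 clock)."""
    n_resident_states(variant)
    return variant in _FORCED


@dataclass(frozen=True)
class EpiParams:
    """Ecological and epidemiological rate constants.

    Parameters
    ----------
    a0 : float
        Baseline host birth rate (per unit time).
    q0 : float
        Baseline competition (crowding) coefficient (per density per time).
    b : float
        Natural mortality rate (per time).
    alpha : float
        Virulence: parasite-induced additional mortality (per time).
    gamma : float
        Recovery rate of infected hosts (per time).
    beta : float
        Resident transmission coefficient (per density per time).
    amp : float
        Seasonal forcing amplitude, in [0, 1]; only used by the forced
        variants.
    theta : float
        Shedding rate of free-living stages by infected hosts (per time);
        free-living variant only.
    decay : float
        Decay rate of free-living stages in the environment (per time);
        free-living variant only.
    """

    a0: float
    q0: float
    b: float
    alpha: float
    gamma: float = 0.0
    beta: float = 0.0
    amp: float = 0.0
    theta: float = 0.0
    decay: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a0", "q0", "b", "alpha", "gamma", "beta", "theta", "decay"):
            v = getattr(self, name)
            if not (v >= 0.0):
                raise ValueError(f"EpiParams.{name} must be >= 0, got {v}")
        if not (0.0 <= self.amp <= 1.0):
            raise ValueError(f"EpiParams.amp must lie in [0, 1], got {self.amp}")

    def with_beta(self, beta: float) -> "EpiParams":
        """Copy with the resident trait replaced."""
        return replace(self, beta=float(beta))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EpiParams":
        return cls(**d)


@dataclass(frozen=True)
class TradeoffParams:
    """Birth-rate-vs-transmission trade-off.

    The cost of host defence (low ``beta``) is a lowered birth rate:

        a(beta) = a_ref - (tau1**2 / tau2) * (1 - exp((beta - beta_ref) * tau2 / tau1))

    so that a(beta_ref) = a_ref, a'(beta_ref) = tau1 (> 0: cheaper
    defence means fewer births) and a''(beta_ref) = tau2, whose sign
    sets the local curvature (accelerating vs decelerating costs) and
    hence the evolutionary stability of singular strategies.
    """

    a_ref: float
    beta_ref: float
    tau1: float
    tau2: float

    def __post_init__(self) -> None:
        if not (self.tau1 > 0.0):
            raise ValueError(f"TradeoffParams.tau1 must be > 0, got {self.tau1}")
        if self.tau2 == 0.0:
            raise ValueError("TradeoffParams.tau2 must be nonzero (linear trade-off not supported)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TradeoffParams":
        return cls(**d)
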