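"""Direct multi-strain simulation of the trait-substitution process.

An independent check on the invasion analysis: host strains live on a
fixed trait lattice, compete through shared crowding (and, for the
free-living variant, a shared propagule pool), and evolve by repeated
rounds of ecological dynamics plus mutation.  Each epoch the dynamics
run for a fixed time, strains below a threshold density are removed,
and a mutant adjacent to the current dominant strain is seeded at low
density.  Recording the extant strains per mutation step traces the
evolutionary trajectory, which should home in on (and, at a branching
point, split around) the singular strategies located analytically.

Dominance is judged by each strain's total density averaged over the
final stretch of the epoch rather than a point value: on a cycle, a fit
strain can transiently sit at a trough exactly when the census happens,
and point sampling would cull it.  For the forced variants the epoch
length is kept an integer multiple of the forcing period for the same
reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .attractor import SolverOptions
from .models import TWO_PI, birth_rate, seasonal_competition
from .params import EpiParams, TradeoffParams, is_forced

__all__ = ["StrainLattice", "EvoTrajectory", "multistrain_rhs", "evolve"]


@dataclass
class StrainLattice:
    """Host strains on a trait lattice sharing one environment.

    ``S``/``I`` hold per-strain densities (exactly 0 for extinct
    strains); ``P`` is the shared free-living propagule pool (unused by
    the direct-transmission variants).
    """

    beta_values: np.ndarray
    S: np.ndarray
    I: np.ndarray
    P: float = 0.0

    def __post_init__(self):
        self.beta_values = np.asarray(self.beta_values, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if np.any(self.S < 0) or np.any(self.I < 0) or self.P < 0:
            raise ValueError("densities must be non-negative")

    @property
    def total(self) -> np.ndarray:
        return self.S + self.I

    @property
    def extant(self) -> np.ndarray:
        return self.total > 0

    @classmethod
    def single_strain(cls, beta_values, start_index: int, density: float = 1.0,
                      p0: float = 0.0) -> "StrainLattice":
        n = len(beta_values)
        S = np.zeros(n)
        I = np.zeros(n)
        S[start_index] = density
        I[start_index] = density
        return cls(np.asarray(beta_values, float), S, I, p0)


@dataclass
class EvoTrajectory:
    """Per-mutation-step record of the multi-strain state."""

    beta_values: np.ndarray
    steps: list[dict] = field(default_factory=list)
    all_extinct: bool = False

    def dominant_trait(self) -> float:
        return self.steps[-1]["dominant_beta"]

    def trait_density(self) -> np.ndarray:
        """(n_steps, n_strains) array of mean total density per strain."""
        return np.array([s["mean_total"] for s in self.steps])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            for j in np.nonzero(s["mean_total"] > 0)[0]:
                rows.append({"step": s["step"], "beta": self.beta_values[j],
                             "density": s["mean_total"][j]})
        return pd.DataFrame(rows, columns=["step", "beta", "density"])


def multistrain_rhs(variant: str, p: EpiParams, tr: TradeoffParams | None,
                    t: float, y: np.ndarray, beta_values: np.ndarray) -> np.ndarray:
    """Derivatives of the stacked multi-strain state.

    ``y`` is [S_1..S_n, I_1..I_n] plus a trailing P for the free-living
    variant.  Each strain has its own birth rate a(beta_i); crowding
    q(t) * sum_j (S_j + I_j) and the force of infection (total infected
    density, or the shared pool P) are shared.  With one extant strain
    this reduces exactly to the resident dynamics.
    """
    n = len(beta_values)
    S = y[:n]
    I = y[n:2 * n]
    a = birth_rate(tr, beta_values) if tr is not None else np.full(n, p.a0)
    if variant == "seasonal":
        q = seasonal_competition(p.q0, p.amp, t)
    else:
        q = p.q0
    if variant == "seasonal_births":
        a = a * (1.0 + p.amp * np.sin(TWO_PI * t))
    N = np.sum(S) + np.sum(I)
    if variant == "free_living":
        P = y[2 * n]
        foi = beta_values * P
    else:
        foi = beta_values * np.sum(I)
    dS = (a - q * N) * S - p.b * S - foi * S + p.gamma * I
    dI = foi * S - (p.b + p.alpha + p.gamma) * I
    if variant == "free_living":
        dP = p.theta * np.sum(I) - p.decay * P
        return np.concatenate([dS, dI, [dP]])
    return np.concatenate([dS, dI])


def _epoch(variant, p, tr, lattice: StrainLattice, epoch_length, avg_window,
           solver: SolverOptions):
    """Integrate one epoch on the active strain subset; return mean totals."""
    active = np.nonzero(lattice.extant)[0]
    betas = lattice.beta_values[active]
    y0 = np.concatenate([lattice.S[active], lattice.I[active]]
                        + ([[lattice.P]] if variant == "free_living" else []))
    t_eval = np.linspace(epoch_length - avg_window, epoch_length, 201)
    sol = solve_ivp(lambda t, y: multistrain_rhs(variant, p, tr, t, y, betas),
                    (0.0, epoch_length), y0, method=solver.method,
                    rtol=solver.rtol, atol=solver.atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"multi-strain integration failed: {sol.message}")
    m = len(active)
    S_end = np.maximum(sol.y[:m, -1], 0.0)
    I_end = np.maximum(sol.y[m:2 * m, -1], 0.0)
    mean_total = np.maximum(sol.y[:m] + sol.y[m:2 * m], 0.0).mean(axis=1)
    S = np.zeros_like(lattice.S)
    I = np.zeros_like(lattice.I)
    S[active], I[active] = S_end, I_end
    mt = np.zeros_like(lattice.S)
    mt[active] = mean_total
    P = float(sol.y[2 * m, -1]) if variant == "free_living" else 0.0
    return StrainLattice(lattice.beta_values, S, I, max(P, 0.0)), mt


def evolve(variant: str, p: EpiParams, tr: TradeoffParams | None,
           trait_range, *, n_strains: int = 61, start_beta: float | None = None,
           n_steps: int = 100, epoch_length: float = 50.0,
           extinction_threshold: float = 1e-5, mutant_seed_density: float = 1e-3,
           seed: int = 0, avg_window: float | None = None,
           solver: SolverOptions = SolverOptions(method="LSODA", rtol=1e-8, atol=1e-10,
                                                 use_log=False)) -> EvoTrajectory:
    """Trait-substitution simulation on a lattice of ``n_strains`` strains.

    Each of ``n_steps`` mutation steps: run the ecological dynamics for
    ``epoch_length`` (an integer multiple of the forcing period for
    forced variants), zero out strains whose period-averaged total
    density fell below ``extinction_threshold``, then seed a mutant
    adjacent to the dominant strain (direction random, seeded RNG) at
    ``mutant_seed_density``.  Terminates early (flagged) if every strain
    goes extinct.
    """
    if is_forced(variant) and abs(epoch_length - round(epoch_length)) > 1e-12:
        raise ValueError("epoch_length must be an integer multiple of the forcing period (1)")
    rng = np.random.default_rng(seed)
    betas = np.linspace(trait_range[0], trait_range[1], n_strains)
    if start_beta is None:
        start = n_strains // 2
    else:
        start = int(np.argmin(np.abs(betas - start_beta)))
    if avg_window is None:
        avg_window = 1.0 if is_forced(variant) else min(10.0, epoch_length / 2)
    p0 = 1.0 if variant == "free_living" else 0.0
    lattice = StrainLattice.single_strain(betas, start, density=1.0, p0=p0)
    traj = EvoTrajectory(beta_values=betas)

    for step in range(n_steps):
        lattice, mean_total = _epoch(variant, p, tr, lattice, epoch_length,
                                     avg_window, solver)
        cull = mean_total < extinction_threshold
        lattice.S[cull] = 0.0
        lattice.I[cull] = 0.0
        mean_total[cull] = 0.0
        if not np.any(mean_total > 0):
            traj.all_extinct = True
            traj.steps.append({"step": step, "mean_total": mean_total,
                               "dominant_beta": np.nan, "mutant_index": -1})
            break
        dom = int(np.argmax(mean_total))
        direction = int(rng.choice([-1, 1]))
        mut = dom + direction
        if mut < 0 or mut >= n_strains:
            mut = dom - direction  # single interior neighbour at the lattice edge
        lattice.S[mut] += mutant_seed_density
        traj.steps.append({"step": step, "mean_total": mean_total,
                           "dominant_beta": float(betas[dom]), "mutant_index": mut})
    return traj
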