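"""Resident dynamics: integration to the attractor and period detection.

The invasion analysis needs the resident population settled on its
long-run attractor before a mutant is introduced.  This module runs the
resident ODEs with a stiff-capable solver (the free-living variant in
log coordinates), classifies the attractor as
an equilibrium or a limit cycle, estimates the cycle period from
inter-peak intervals of the infected density, and resamples one full
period onto a uniform grid anchored at an I-peak.

For the externally forced variants the period is snapped to an integer
multiple of the forcing period (1 time unit), with the multiple
(multiplicity) diagnosed from the repeat pattern of successive peak
heights — forced systems are prone to period-doubling, so the period
must be checked rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .models import effective_params, log_rhs, resident_rhs
from .params import EpiParams, TradeoffParams, is_forced, n_resident_states

__all__ = [
    "AttractorTrace",
    "CycleAttractor",
    "PeriodInfo",
    "SolverOptions",
    "integrate_to_attractor",
    "detect_period",
    "resample_cycle",
    "compute_attractor",
    "PeriodDetectionError",
    "NotOnAttractorError",
]

#: densities below this are treated as extinct compartments
DENSITY_FLOOR = 1e-8


class PeriodDetectionError(RuntimeError):
    """Period could not be determined from the sampled trajectory."""


class NotOnAttractorError(RuntimeError):
    """The sampled trajectory has not converged to a closed attractor."""


@dataclass(frozen=True)
class SolverOptions:
    """ODE solver settings shared across the pipeline.

    The forced and free-living systems are stiff, so the default is
    LSODA (automatic stiff/non-stiff switching); Radau is available via
    ``method``.  ``use_log`` switches the resident integration to log
    coordinates (defaults to True for the free-living variant).
    """

    method: str = "LSODA"
    rtol: float = 1e-10
    atol: float = 1e-12
    use_log: bool | None = None

    def log_for(self, variant: str) -> bool:
        return (variant == "free_living") if self.use_log is None else self.use_log


@dataclass
class AttractorTrace:
    """Raw output of a burn-in integration: end state plus a dense tail window."""

    variant: str
    p: EpiParams  # effective (trade-off applied) resident parameters
    end_state: np.ndarray  # densities at t = t_end
    times: np.ndarray  # dense sample times of the trailing window
    states: np.ndarray  # (len(times), k) densities on the window
    disease_free: bool = False
    host_extinct: bool = False
    solver_message: str = ""


@dataclass
class PeriodInfo:
    kind: str  # "equilibrium" | "cycle"
    period: float | None
    multiplicity: int
    peak_times: np.ndarray | None = None
    peak_heights: np.ndarray | None = None


@dataclass
class CycleAttractor:
    """One canonical period of the resident attractor.

    ``times`` span exactly one period (closed grid: the last point is
    one period after the first, so first and last states agree within
    the closure tolerance); cycles are stored starting at a peak of the
    infected density.  An equilibrium is stored as a degenerate
    constant cycle of nominal period 1 so that downstream code needs no
    special case.
    """

    variant: str
    times: np.ndarray
    states: np.ndarray
    period: float
    kind: str  # "equilibrium" | "cycle"
    multiplicity: int = 1
    closure_gap: float = 0.0

    @property
    def phase0_time(self) -> float:
        return float(self.times[0])

    @property
    def phase0_state(self) -> np.ndarray:
        return self.states[0]

    def rolled(self, i: int) -> "CycleAttractor":
        """The same cycle re-anchored at sample ``i`` (phase-invariance checks)."""
        n = len(self.times) - 1  # last point duplicates the first
        i = int(i) % n
        times = np.concatenate([self.times[i:-1], self.times[:i + 1] + self.period])
        states = np.concatenate([self.states[i:-1], self.states[:i + 1]], axis=0)
        return CycleAttractor(self.variant, times, states, self.period, self.kind,
                              self.multiplicity, self.closure_gap)

    def to_dataframe(self):
        import pandas as pd

        cols = ["S", "I", "P"][: self.states.shape[1]]
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "t", self.times)
        return df


def _default_initial(variant: str) -> np.ndarray:
    return np.ones(n_resident_states(variant))


def integrate_to_attractor(
    variant: str,
    p: EpiParams,
    tr: TradeoffParams | None = None,
    burn_in: float = 500.0,
    warm_start: np.ndarray | None = None,
    *,
    window: float = 60.0,
    samples_per_unit: int = 200,
    solver: SolverOptions = SolverOptions(),
) -> AttractorTrace:
    """Run the resident dynamics past transients and keep a dense tail.

    Integrates from ``warm_start`` (default interior point (1, 1[, 1]))
    for ``burn_in`` time units, recording a densely sampled window of
    the final ``window`` time units for period detection.  Warm starts
    from a previous run's ``end_state`` shortcut the transient when
    looping over nearby parameter values.
    """
    if burn_in <= 0:
        raise ValueError("burn_in must be positive")
    p_eff = effective_params(p, tr)
    y0 = np.asarray(warm_start, dtype=float) if warm_start is not None else _default_initial(variant)
    if warm_start is not None and np.any(y0 <= 0):
        raise ValueError("warm_start densities must be strictly positive")
    window = min(window, burn_in)
    use_log = solver.log_for(variant)
    if use_log:
        rhs = lambda t, y: log_rhs(variant, p_eff, t, y)
        y0 = np.log(np.maximum(y0, 1e-300))
    else:
        rhs = lambda t, y: resident_rhs(variant, p_eff, t, y)

    t_eval = np.linspace(burn_in - window, burn_in, int(round(window * samples_per_unit)) + 1)
    sol = solve_ivp(rhs, (0.0, burn_in), y0, method=solver.method,
                    rtol=solver.rtol, atol=solver.atol, t_eval=t_eval, dense_output=False)
    if not sol.success:
        raise RuntimeError(f"resident integration failed: {sol.message}")
    states = sol.y.T
    if use_log:
        states = np.exp(states)
    end_state = states[-1]
    return AttractorTrace(
        variant=variant,
        p=p_eff,
        end_state=end_state,
        times=sol.t,
        states=states,
        disease_free=bool(end_state[1] < DENSITY_FLOOR),
        host_extinct=bool(end_state[0] < DENSITY_FLOOR),
        solver_message=sol.message or "",
    )


def _refine_peak_times(t: np.ndarray, x: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sub-sample peak locations by fitting a parabola through 3 points."""
    times, heights = [], []
    for i in idx:
        if i == 0 or i == len(t) - 1:
            times.append(t[i]); heights.append(x[i])
            continue
        y0, y1, y2 = x[i - 1], x[i], x[i + 1]
        denom = y0 - 2.0 * y1 + y2
        delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        delta = float(np.clip(delta, -1.0, 1.0))
        dt = t[i + 1] - t[i] if delta >= 0 else t[i] - t[i - 1]
        times.append(t[i] + delta * dt)
        heights.append(y1 - 0.25 * (y0 - y2) * delta)
    return np.asarray(times), np.asarray(heights)


def _height_multiplicity(heights: np.ndarray, tol: float, max_mult: int = 4) -> int:
    """Smallest m such that the peak-height sequence is m-periodic."""
    rng = np.ptp(heights)
    scale = max(rng, abs(float(np.mean(heights))), 1e-300)
    for m in range(1, max_mult + 1):
        if len(heights) <= m:
            break
        if np.all(np.abs(heights[m:] - heights[:-m]) / scale <= tol):
            return m
    return 1


def detect_period(
    variant: str,
    trace: AttractorTrace,
    *,
    eq_tol: float = 1e-6,
    eq_window: float = 50.0,
    peak_prominence: float = 1e-3,
    peak_tol: float = 1e-3,
    cv_threshold: float = 0.2,
) -> PeriodInfo:
    """Classify the attractor and estimate the cycle period.

    Equilibrium: every state's relative variation over the trailing
    ``eq_window`` time units is below ``eq_tol``.  Otherwise the period
    is the mean interval between peaks of the infected density (peak
    times refined by parabolic interpolation); for the forced variants
    it is then snapped to an integer multiple of the forcing period,
    with the multiple read off the repeat pattern of peak heights.
    """
    t, y = trace.times, trace.states
    mask = t >= t[-1] - eq_window
    tw, yw = t[mask], y[mask]
    scale = np.maximum(np.abs(yw).max(axis=0), 1e-300)
    rel_var = np.ptp(yw, axis=0) / scale
    if np.all(rel_var < eq_tol):
        return PeriodInfo(kind="equilibrium", period=None, multiplicity=1)

    infected = y[:, 1]
    rng = float(np.ptp(infected))
    idx, _ = find_peaks(infected, prominence=peak_prominence * rng)
    if len(idx) < 3:
        raise PeriodDetectionError(
            f"window too short: only {len(idx)} peaks found in {t[-1] - t[0]:.1f} time units")
    pk_t, pk_h = _refine_peak_times(t, infected, idx)
    intervals = np.diff(pk_t)
    cv = float(np.std(intervals) / np.mean(intervals))
    mult = _height_multiplicity(pk_h, peak_tol)
    if cv > cv_threshold and mult == 1:
        raise PeriodDetectionError(
            f"no fixed period: inter-peak intervals too irregular (CV = {cv:.3f})")

    # average over whole groups of `mult` peaks for an unbiased estimate
    n_groups = (len(pk_t) - 1) // mult
    base = (pk_t[n_groups * mult] - pk_t[0]) / n_groups / mult
    period = base * mult
    if is_forced(variant):
        snapped = max(1, int(round(period)))
        period = float(snapped)
        mult = snapped
    return PeriodInfo(kind="cycle", period=float(period), multiplicity=mult,
                      peak_times=pk_t, peak_heights=pk_h)


def resample_cycle(
    trace: AttractorTrace,
    info: PeriodInfo,
    *,
    n_samples: int = 400,
    closure_tol: float = 1e-3,
) -> CycleAttractor:
    """Interpolate one period onto a uniform grid anchored at an I-peak.

    Equilibria pass through as degenerate constant cycles of nominal
    period 1.  Raises :class:`NotOnAttractorError` when the cycle fails
    to close within ``closure_tol`` (relative), i.e. the burn-in was too
    short.
    """
    t, y = trace.times, trace.states
    if info.kind == "equilibrium":
        const = y[-1]
        times = np.linspace(t[-1], t[-1] + 1.0, n_samples + 1)
        states = np.tile(const, (n_samples + 1, 1))
        return CycleAttractor(trace.variant, times, states, 1.0, "equilibrium", 1, 0.0)

    T = info.period
    # latest I-peak with a full period of samples after it
    starts = info.peak_times[info.peak_times + T <= t[-1] + 1e-12]
    if len(starts) == 0:
        raise NotOnAttractorError("sampled window shorter than one period after the first peak")
    t0 = float(starts[-1])
    spline = CubicSpline(t, y, axis=0)
    grid = np.linspace(t0, min(t0 + T, t[-1]), n_samples + 1)
    states = spline(grid)
    gap = float(np.linalg.norm(states[-1] - states[0]) / max(np.linalg.norm(states[0]), 1e-300))
    if gap > closure_tol:
        raise NotOnAttractorError(
            f"not converged to attractor: closure gap {gap:.2e} > {closure_tol:.0e}")
    return CycleAttractor(trace.variant, grid, states, float(T), "cycle",
                          info.multiplicity, gap)


def compute_attractor(
    variant: str,
    p: EpiParams,
    tr: TradeoffParams | None = None,
    *,
    burn_in: float = 500.0,
    max_burn_in: float = 8000.0,
    warm_start: np.ndarray | None = None,
    window: float = 60.0,
    samples_per_unit: int = 200,
    n_samples: int = 400,
    closure_tol: float = 1e-3,
    solver: SolverOptions = SolverOptions(),
    detect_kwargs: dict | None = None,
) -> tuple[CycleAttractor, AttractorTrace]:
    """End-to-end resident pipeline: integrate, classify, resample.

    Doubles the burn-in (warm-starting from the previous end state) when
    the cycle has not closed, and widens the sampling window when too
    few peaks fall inside it.  Raises on disease-free or host-extinct
    residents — invasion fitness is undefined without a parasite.
    """
    detect_kwargs = detect_kwargs or {}
    bi, win, ws = burn_in, window, warm_start
    while True:
        trace = integrate_to_attractor(variant, p, tr, bi, ws, window=win,
                                       samples_per_unit=samples_per_unit, solver=solver)
        if trace.host_extinct:
            raise NotOnAttractorError("host population went extinct")
        if trace.disease_free:
            raise NotOnAttractorError("resident attractor is disease-free (parasite died out)")
        try:
            info = detect_period(variant, trace, **detect_kwargs)
            cyc = resample_cycle(trace, info, n_samples=n_samples, closure_tol=closure_tol)
            return cyc, trace
        except PeriodDetectionError as err:
            if "window too short" in str(err) and win < 4 * window:
                win *= 2
                ws = trace.end_state
                continue
            raise
        except NotOnAttractorError:
            if bi >= max_burn_in:
                raise
            ws = trace.end_state
            bi = min(2 * bi, max_burn_in)
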