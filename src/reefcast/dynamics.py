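"""Hybrid coral-cover dynamics: logistic growth punctuated by acute mortality.

Between thermal-stress events, percent coral cover P follows a logistic
growth law depressed by background temperature,

    dP/dt = r * P * (1 - P/K) - gamma * T(t) * P,

where r is the intrinsic rate of increase (yr^-1), K the carrying capacity
(% cover) and gamma the temperature-impact coefficient.  During an event of
intensity eps starting at t_k, growth is suspended and cover decays
exponentially,

    P(t) = P(t_k) * exp(f(eps) * (t - t_k)),   f(eps) = -eps**3,

for the event's duration (weeks, converted to years inside the solver).
The exponent uses elapsed time since onset, not absolute calendar time, so
mortality from a given (eps, duration) pair is the same in any year.

With T held constant the growth law has the closed-form solution

    P(t) = (r - gamma*T) * P0 /
           [ (r/K) * P0 * (1 - exp(-(r-gamma*T)*t)) + (r-gamma*T)*exp(-(r-gamma*T)*t) ]

with equilibria P1 = 0 and P2 = (K/r)*(r - gamma*T); P2 is positive and
stable iff gamma*T/r < 1, and collides with P1 at gamma*T/r = 1 (a
transcritical bifurcation separating persistence from collapse).

The integrator is fixed-step classical RK4 at dt = 1/52 yr so that event
windows align with the weekly grid; a step partially covered by an event
applies the exact exponential decay over the covered fraction and RK4
growth over the remainder.  A small cover floor (default 0.1 %) keeps
extinction non-absorbing, standing in for external larval supply; set
``p_floor=0`` for a strictly closed population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError, SingularityError
from .events import EventSchedule
from .temperature import TemperatureModel, sst_at

__all__ = [
    "ModelParams",
    "Trajectory",
    "Equilibria",
    "growth_rhs",
    "apply_event",
    "closed_form_cover",
    "equilibria",
    "simulate_trajectory",
    "simulate_paths",
    "WEEKS_PER_YEAR",
]

WEEKS_PER_YEAR = 52.0


@dataclass(frozen=True)
class ModelParams:
    """Coral population parameters.

    r : intrinsic rate of increase (yr^-1); K : carrying capacity (% cover);
    gamma : temperature-impact coefficient (degC^-1 yr^-1); p0 : initial
    cover (%); p_floor : minimum cover (%), the refuge below which the
    population cannot fall.
    """

    r: float
    K: float
    gamma: float = 0.0
    p0: float = 10.0
    p_floor: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.K <= 100.0):
            raise InvalidInputError(f"K must be in (0, 100], got {self.K}")
        if not (0.0 <= self.p0 <= self.K):
            raise InvalidInputError(f"p0 must be in [0, K], got {self.p0}")
        if self.r < 0.0:
            raise InvalidInputError("r must be non-negative")
        if self.gamma < 0.0:
            raise InvalidInputError("gamma must be non-negative")
        if not (0.0 <= self.p_floor < self.K):
            raise InvalidInputError("p_floor must be in [0, K)")


def growth_rhs(p, params: ModelParams, T):
    """Instantaneous growth rate dP/dt (% cover / yr) of the inter-event law."""
    p = np.asarray(p, dtype=float)
    out = params.r * p * (1.0 - p / params.K) - params.gamma * np.asarray(T) * p
    return float(out) if out.ndim == 0 else out


def apply_event(p_start: float, eps: float, elapsed: float, params: ModelParams) -> float:
    """Cover after ``elapsed`` years of an event of intensity ``eps``.

    Exponential decay at rate eps**3, floored at ``params.p_floor``.
    """
    if elapsed < 0:
        raise InvalidInputError("elapsed time must be non-negative")
    if eps < 0:
        raise InvalidInputError("eps must be non-negative")
    return max(params.p_floor, p_start * math.exp(-(eps**3) * elapsed))


def closed_form_cover(t, params: ModelParams, T: float):
    """Closed-form cover under constant temperature (no events).

    Valid for t >= 0.  Handles the degenerate net-rate-zero case
    (r == gamma*T) by its continuous limit P0 / ((r/K)*P0*t + 1); raises
    :class:`SingularityError` if the denominator vanishes.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidInputError("t must be non-negative")
    rho = params.r - params.gamma * T
    p0 = params.p0
    if abs(rho) < 1e-12:
        out = p0 / ((params.r / params.K) * p0 * t_arr + 1.0)
    else:
        decay = np.exp(-rho * t_arr)
        denom = (params.r / params.K) * p0 * (1.0 - decay) + rho * decay
        if np.any(np.abs(denom) < 1e-300) or np.any(denom == 0):
            raise SingularityError("closed-form denominator vanished")
        out = rho * p0 / denom
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Equilibria:
    """Fixed points of the constant-temperature growth law."""

    p1: float
    p2: float
    p1_stable: bool
    p2_stable: bool
    bifurcation: bool
    stress_ratio: float  # gamma*T / r

    def as_dict(self) -> dict:
        return {
            "P1": self.p1,
            "P2": self.p2,
            "P1_stable": self.p1_stable,
            "P2_stable": self.p2_stable,
            "bifurcation": self.bifurcation,
            "stress_ratio": self.stress_ratio,
        }


def equilibria(params: ModelParams, T: float, tol: float = 1e-6) -> Equilibria:
    """Equilibria P1 = 0 and P2 = (K/r)(r - gamma*T) with stability flags.

    P2 is stable (and positive) iff gamma*T/r < 1; the two fixed points
    exchange stability at gamma*T/r = 1, flagged as a bifurcation when the
    stress ratio is within ``tol`` of unity.
    """
    if params.r <= 0:
        raise InvalidInputError("equilibrium analysis needs r > 0")
    ratio = params.gamma * T / params.r
    p2 = (params.K / params.r) * (params.r - params.gamma * T)
    return Equilibria(
        p1=0.0,
        p2=p2,
        p1_stable=ratio > 1.0,
        p2_stable=ratio < 1.0,
        bifurcation=abs(ratio - 1.0) <= tol,
        stress_ratio=ratio,
    )


@dataclass(frozen=True)
class Trajectory:
    """A simulated cover path: times (fractional years), cover (%), event flags."""

    times: np.ndarray
    cover: np.ndarray
    in_event: np.ndarray
    schedule: EventSchedule

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("trajectory times must be strictly increasing")

    def at(self, t: float) -> float:
        """Cover at time ``t`` (linear interpolation between grid points)."""
        return float(np.interp(t, self.times, self.cover))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.times, "cover_pct": self.cover, "in_event": self.in_event.astype(int)}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _temperature_fn(
    temp: TemperatureModel, mode: str
) -> Callable[[np.ndarray], np.ndarray]:
    if mode == "instantaneous":
        return lambda t: sst_at(temp, t)
    if mode == "annual_mean":
        # piecewise-constant at each calendar year's mean: trend at mid-year + offset
        return lambda t: temp.lam * (np.floor(np.asarray(t, dtype=float)) + 0.5 - temp.t0) + temp.a3
    raise ConfigurationError(f"unknown temperature mode {mode!r}")


def _event_step_arrays(
    schedules: Sequence[EventSchedule],
    t_start: float,
    n_steps: int,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(run, step) event decay log-factors and in-event overlap times.

    ``decay_log[k, i]`` is f(eps) * (time of step i covered by an event) for
    run k; ``overlap[k, i]`` is that covered time (years).  Events with
    eps == 0 are no-ops and contribute nothing.
    """
    n_runs = len(schedules)
    decay_log = np.zeros((n_runs, n_steps))
    overlap = np.zeros((n_runs, n_steps))
    for k, sched in enumerate(schedules):
        for ev in sched.events:
            if ev.eps == 0.0:
                continue  # zero-intensity anomaly: no effect
            s, e = ev.t_start, ev.t_end
            i0 = max(0, int(np.floor((s - t_start) / dt)))
            i1 = min(n_steps - 1, int(np.floor((e - t_start) / dt + 1e-12)))
            for i in range(i0, i1 + 1):
                lo = t_start + i * dt
                ov = min(lo + dt, e) - max(lo, s)
                if ov > 0:
                    overlap[k, i] += ov
                    decay_log[k, i] -= ev.eps**3 * ov
    return decay_log, overlap


def simulate_paths(
    params: ModelParams,
    temp: TemperatureModel,
    schedules: Sequence[EventSchedule],
    r_per_year: np.ndarray | None = None,
    dt: float = 1.0 / 52.0,
    temperature_mode: str = "instantaneous",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized hybrid integration of many runs on a shared time grid.

    All schedules must share one horizon.  ``r_per_year``, if given, has
    shape (n_runs, n_years) and supplies the intrinsic rate for each run and
    calendar year (the stochastic-r mode); otherwise ``params.r`` is used
    throughout.  Returns ``(times, cover, in_event)`` where ``cover`` and
    ``in_event`` have shape (n_runs, n_times).

    The step rule: over each dt, apply the exact exponential event decay for
    the portion of the step covered by an event, then one RK4 growth step
    over the uncovered remainder; finally clamp to [p_floor, 100].
    """
    if dt > 1.0 / 52.0 + 1e-12:
        raise ConfigurationError("dt must be at most one week (1/52 yr)")
    horizons = {s.horizon for s in schedules}
    if len(horizons) != 1:
        raise ConfigurationError(f"schedules span {len(horizons)} different horizons")
    (t0, t1), = horizons
    n_steps = int(round((t1 - t0) / dt))
    if abs(t0 + n_steps * dt - t1) > 1e-9:
        raise ConfigurationError("horizon length must be an integer number of steps")
    n_runs = len(schedules)
    times = t0 + dt * np.arange(n_steps + 1)

    decay_log, overlap = _event_step_arrays(schedules, t0, n_steps, dt)
    temp_fn = _temperature_fn(temp, temperature_mode)

    if r_per_year is not None:
        r_per_year = np.asarray(r_per_year, dtype=float)
        n_years = int(np.ceil(t1 - t0))
        if r_per_year.shape != (n_runs, n_years):
            raise ConfigurationError(
                f"r_per_year must have shape ({n_runs}, {n_years}), got {r_per_year.shape}"
            )
        year_idx = np.minimum((times[:-1] - t0).astype(int), n_years - 1)

    K, gamma, floor = params.K, params.gamma, params.p_floor
    p = np.full(n_runs, float(params.p0))
    cover = np.empty((n_runs, n_steps + 1))
    cover[:, 0] = p
    for i in range(n_steps):
        r = r_per_year[:, year_idx[i]] if r_per_year is not None else params.r
        # event phase: exact exponential decay over the covered fraction
        ov = overlap[:, i]
        p = p * np.exp(decay_log[:, i])
        # growth phase: RK4 over the uncovered remainder of the step
        h = dt - ov
        ta = times[i] + ov  # growth resumes when the event window ends
        T1 = temp_fn(ta)
        Tm = temp_fn(ta + 0.5 * h)
        T2 = temp_fn(ta + h)
        k1 = r * p * (1.0 - p / K) - gamma * T1 * p
        p2_ = p + 0.5 * h * k1
        k2 = r * p2_ * (1.0 - p2_ / K) - gamma * Tm * p2_
        p3_ = p + 0.5 * h * k2
        k3 = r * p3_ * (1.0 - p3_ / K) - gamma * Tm * p3_
        p4_ = p + h * k3
        k4 = r * p4_ * (1.0 - p4_ / K) - gamma * T2 * p4_
        p = p + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        p = np.clip(p, floor, 100.0)
        cover[:, i + 1] = p

    in_event = np.zeros((n_runs, n_steps + 1), dtype=bool)
    in_event[:, :-1] = overlap > 0
    return times, cover, in_event


def simulate_trajectory(
    params: ModelParams,
    temp: TemperatureModel,
    schedule: EventSchedule,
    r_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    dt: float = 1.0 / 52.0,
    rng: np.random.Generator | None = None,
    temperature_mode: str = "instantaneous",
    r_redraw: str = "yearly",
) -> Trajectory:
    """Integrate one hybrid trajectory over the schedule's horizon.

    If ``r_sampler`` is given (callable ``(rng, n) -> n draws``), the
    intrinsic rate is redrawn at each calendar-year boundary (the default),
    or at every integration step with ``r_redraw='per_step'`` — the latter
    makes the dynamics resolution-dependent and exists for comparison only.
    """
    t0, t1 = schedule.horizon
    if r_sampler is not None:
        if rng is None:
            raise ConfigurationError("r_sampler requires an rng for reproducibility")
        if r_redraw == "yearly":
            n_years = int(np.ceil(t1 - t0))
            r_year = np.asarray(r_sampler(rng, n_years), dtype=float)[None, :]
        elif r_redraw == "per_step":
            n_steps = int(round((t1 - t0) / dt))
            r_year = None
            # draw one value per step and treat each step as its own "year"
            draws = np.asarray(r_sampler(rng, n_steps), dtype=float)
        else:
            raise ConfigurationError(f"unknown r_redraw mode {r_redraw!r}")
    else:
        r_year = None

    if r_sampler is not None and r_redraw == "per_step":
        # run step-wise by mapping each step to a distinct pseudo-year
        n_steps = int(round((t1 - t0) / dt))
        times = t0 + dt * np.arange(n_steps + 1)
        cover = np.empty(n_steps + 1)
        in_ev = np.zeros(n_steps + 1, dtype=bool)
        p = params.p0
        decay_log, overlap = _event_step_arrays([schedule], t0, n_steps, dt)
        temp_fn = _temperature_fn(temp, temperature_mode)
        cover[0] = p
        for i in range(n_steps):
            stepped = replace(params, r=float(draws[i]), p0=min(float(p), params.K))
            p = p * math.exp(decay_log[0, i])
            h = dt - overlap[0, i]
            ta = times[i] + overlap[0, i]
            k1 = growth_rhs(p, stepped, temp_fn(ta))
            k2 = growth_rhs(p + 0.5 * h * k1, stepped, temp_fn(ta + 0.5 * h))
            k3 = growth_rhs(p + 0.5 * h * k2, stepped, temp_fn(ta + 0.5 * h))
            k4 = growth_rhs(p + h * k3, stepped, temp_fn(ta + h))
            p = float(np.clip(p + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), params.p_floor, 100.0))
            cover[i + 1] = p
            in_ev[i] = overlap[0, i] > 0
        return Trajectory(times=times, cover=cover, in_event=in_ev, schedule=schedule)

    times, cover, in_event = simulate_paths(
        params, temp, [schedule], r_per_year=r_year, dt=dt, temperature_mode=temperature_mode
    )
    return Trajectory(times=times, cover=cover[0], in_event=in_event[0], schedule=schedule)
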