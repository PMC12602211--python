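"""Strategy simulation and the above-recovery energy ledger.

A :class:`Strategy` assigns one target speed per course segment; riders hold
constant power within a segment (acceleration is not simulated, a known
model simplification — the kinetic-energy mismatch between consecutive
segments is reported as a diagnostic but not charged).

Per segment the net work drawn from the finite budget is

    W_i = max(P_i - P_recover, 0) * t_i

i.e. riding at or below recovery power is free but never refills the budget
(an optional linear recharge mode exists for experimentation, default off).
Corner segments are traversed without pedalling: power is forced to zero
and no above-recovery work is charged there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cornering import apply_corner_limits
from .course import Course
from .errors import ValidationError
from .physics import (
    Environment,
    ForceBreakdown,
    Rider,
    force_breakdown,
    recovery_speed,
    required_power,
)

#: Absolute slack (J) when comparing spent work against the budget and
#: (m/s) when checking speeds against bounds; absorbs root-finder noise.
BUDGET_TOL_J = 1e-3
BOUND_TOL = 1e-9


@dataclass(frozen=True)
class Strategy:
    """Per-segment target speeds (m/s) — the optimizer's chromosome."""

    speeds: np.ndarray

    def __post_init__(self) -> None:
        speeds = np.asarray(self.speeds, dtype=float)
        object.__setattr__(self, "speeds", speeds)
        if speeds.ndim != 1 or speeds.size == 0:
            raise ValidationError("strategy speeds must be a non-empty 1-D array")
        if np.any(speeds <= 0):
            raise ValidationError("strategy speeds must be > 0")

    def __len__(self) -> int:
        return int(self.speeds.size)


@dataclass(frozen=True)
class SimulationResult:
    """Per-segment times/powers/work plus totals and feasibility flags."""

    times: np.ndarray
    powers: np.ndarray
    works: np.ndarray
    forces: tuple[ForceBreakdown, ...]
    total_time: float
    total_work: float
    remaining_budget: float
    within_bounds: bool
    within_budget: bool
    #: 0.5*m*(v_{i+1}^2 - v_i^2) between consecutive segments — the
    #: acceleration energy the constant-speed model does not charge.
    kinetic_energy_steps: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def feasible(self) -> bool:
        return self.within_bounds and self.within_budget


def segment_net_work(power: float, p_recover: float, t: float) -> float:
    """Work drawn from the budget over ``t`` seconds at pedal power
    ``power``: max(power - p_recover, 0) * t."""
    if t < 0:
        raise ValidationError(f"time must be >= 0, got {t}")
    return max(power - p_recover, 0.0) * t


def speed_bounds(course: Course, rider: Rider, env: Environment) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment (lower, upper) speed bounds.

    Lower bound: the recovery speed (coasting speed on descents).
    Upper bound: the class maximum, tightened by corner safe speeds.
    """
    lower = np.array([recovery_speed(rider, env, seg) for seg in course])
    upper = apply_corner_limits(course, env, rider)
    return lower, upper


def simulate(
    strategy: Strategy,
    course: Course,
    rider: Rider,
    env: Environment,
    recharge_rate: float = 0.0,
) -> SimulationResult:
    """Ride ``course`` at the strategy's per-segment speeds.

    ``recharge_rate`` (W), if positive, lets the budget ledger recover at
    that rate during sub-recovery segments, floored at fully recovered.
    """
    n = len(course)
    if len(strategy) != n:
        raise ValidationError(
            f"strategy has {len(strategy)} speeds but the course has {n} segments"
        )
    speeds = strategy.speeds
    times = np.empty(n)
    powers = np.empty(n)
    works = np.empty(n)
    forces = []
    for i, seg in enumerate(course):
        v = float(speeds[i])
        fb = force_breakdown(rider, env, seg, v)
        forces.append(fb)
        times[i] = seg.length / v
        if seg.corner is not None:
            powers[i] = 0.0  # no pedalling while cornering
            works[i] = 0.0
        else:
            powers[i] = required_power(fb.total, v)
            works[i] = segment_net_work(powers[i], rider.recovery_power, times[i])

    if recharge_rate > 0.0:
        ledger = 0.0
        for i in range(n):
            ledger += works[i]
            if works[i] == 0.0:
                ledger = max(ledger - recharge_rate * times[i], 0.0)
        total_work = ledger
    else:
        total_work = float(works.sum())

    lower, upper = speed_bounds(course, rider, env)
    within_bounds = bool(
        np.all(speeds >= lower - BOUND_TOL) and np.all(speeds <= upper + BOUND_TOL)
    )
    kinetic = 0.5 * rider.mass * np.diff(speeds**2) if n > 1 else np.empty(0)
    return SimulationResult(
        times=times,
        powers=powers,
        works=works,
        forces=tuple(forces),
        total_time=float(times.sum()),
        total_work=total_work,
        remaining_budget=rider.energy_budget - total_work,
        within_bounds=within_bounds,
        within_budget=total_work <= rider.energy_budget + BUDGET_TOL_J,
        kinetic_energy_steps=kinetic,
    )


# ---------------------------------------------------------------------------
# vectorized evaluation (used by the optimizer and the brute-force oracle)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CourseArrays:
    """Precomputed per-segment constants for batch strategy evaluation."""

    lengths: np.ndarray
    wind_along: np.ndarray  # V_wind * cos(D_wind - D_seg), per segment
    resist_const: np.ndarray  # mu*m*g*cos(gamma) + m*g*sin(gamma)
    drag_factor: float  # 0.5 * C * rho * S
    corner_mask: np.ndarray
    recovery_power: float
    energy_budget: float


def course_arrays(course: Course, rider: Rider, env: Environment) -> CourseArrays:
    headings = np.array([seg.heading for seg in course])
    grades = np.array([seg.grade_angle for seg in course])
    mg = rider.mass * env.gravity
    return CourseArrays(
        lengths=np.array([seg.length for seg in course]),
        wind_along=env.wind_speed * np.cos(np.radians(env.wind_direction - headings)),
        resist_const=env.rolling_coeff * mg * np.cos(grades) + mg * np.sin(grades),
        drag_factor=0.5 * rider.drag_area * env.air_density,
        corner_mask=np.array([seg.corner is not None for seg in course]),
        recovery_power=rider.recovery_power,
        energy_budget=rider.energy_budget,
    )


def batch_time_work(arrays: CourseArrays, speeds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total time (s) and budget work (J) for a batch of speed vectors.

    ``speeds`` has shape (..., n_segments); returns arrays of shape (...).
    Mirrors :func:`simulate` with the default (no-recharge) ledger.
    """
    v_rel = speeds - arrays.wind_along
    f_c = arrays.drag_factor * v_rel * np.abs(v_rel) + arrays.resist_const
    power = np.maximum(f_c * speeds, 0.0)
    power = np.where(arrays.corner_mask, 0.0, power)
    times = arrays.lengths / speeds
    works = np.maximum(power - arrays.recovery_power, 0.0) * times
    return times.sum(axis=-1), works.sum(axis=-1)


# ---------------------------------------------------------------------------
# constant-power baseline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaselineResult:
    strategy: Strategy
    power: float
    total_work: float
    #: True when even riding every segment at its speed cap cannot spend
    #: the full budget; the returned strategy is then the capped one.
    capped: bool


def _strategy_at_power(
    power: float, course: Course, rider: Rider, env: Environment, upper: np.ndarray
) -> Strategy:
    from .physics import speed_at_power  # local import avoids cycle at module load

    speeds = np.array(
        [
            min(speed_at_power(power, rider, env, seg), upper[i])
            for i, seg in enumerate(course)
        ]
    )
    return Strategy(speeds=speeds)


def constant_power_baseline(
    course: Course,
    rider: Rider,
    env: Environment,
    p_target: float | None = None,
    work_tol: float = 1.0,
) -> BaselineResult:
    """Strategy riding every segment at one target power (speed-capped).

    With ``p_target=None`` the power that exhausts the energy budget is
    found by bisection to within ``work_tol`` joules of the budget. If the
    budget cannot be spent even with every segment at its cap, the capped
    strategy is returned with ``capped=True``.
    """
    _, upper = speed_bounds(course, rider, env)
    if p_target is not None:
        if p_target < rider.recovery_power:
            raise ValidationError("p_target must be >= recovery_power")
        strat = _strategy_at_power(p_target, course, rider, env, upper)
        res = simulate(strat, course, rider, env)
        return BaselineResult(strategy=strat, power=p_target, total_work=res.total_work, capped=False)

    def spent(power: float) -> tuple[Strategy, float]:
        strat = _strategy_at_power(power, course, rider, env, upper)
        return strat, simulate(strat, course, rider, env).total_work

    lo = rider.recovery_power  # W(lo) ~ 0 <= budget: always a feasible bracket
    strat_lo, w_lo = spent(lo)
    if rider.energy_budget <= work_tol:
        return BaselineResult(strategy=strat_lo, power=lo, total_work=w_lo, capped=False)

    hi = max(2.0 * lo, lo + 100.0)
    strat_hi, w_hi = spent(hi)
    while w_hi < rider.energy_budget - work_tol:
        if np.all(strat_hi.speeds >= upper - BOUND_TOL):
            return BaselineResult(strategy=strat_hi, power=hi, total_work=w_hi, capped=True)
        hi *= 2.0
        strat_hi, w_hi = spent(hi)

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        strat_mid, w_mid = spent(mid)
        if abs(w_mid - rider.energy_budget) <= work_tol:
            return BaselineResult(strategy=strat_mid, power=mid, total_work=w_mid, capped=False)
        if w_mid < rider.energy_budget:
            lo = mid
        else:
            hi = mid
    strat_mid, w_mid = spent(0.5 * (lo + hi))
    return BaselineResult(
        strategy=strat_mid, power=0.5 * (lo + hi), total_work=w_mid, capped=False
    )
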