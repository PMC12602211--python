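"""Force balance and power-speed relations for a road cyclist.

The total drive force at speed ``v`` on a segment with grade angle ``gamma``
is

    F_c = 1/2 C rho S V_rel |V_rel|  +  mu m g cos(gamma)  +  m g sin(gamma)  +  m a

with the relative wind speed ``V_rel = v - V_wind cos(alpha)``, where
``alpha`` is the angle between the segment heading and the direction the
wind blows toward. The drag term is written ``V_rel |V_rel|`` rather than
``V_rel^2`` so a tailwind faster than the rider pushes forward instead of
(unphysically) backward; the two agree whenever ``V_rel >= 0``.

Pedal power equals drive force times speed, clamped at zero: the rider
cannot absorb energy through the pedals on a gravity-assisted descent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .course import Segment
from .errors import NumericalError, ValidationError

#: Rolling-resistance coefficient range of rubber on asphalt by surface
#: condition; the default coefficient is the midpoint of the range.
ROLLING_COEFF_RANGE = {"dry": (0.010, 0.018), "wet": (0.0022, 0.005)}

#: Sliding (grip) friction coefficient of rubber on asphalt by surface
#: condition, used for the cornering speed limit.
SLIDING_COEFF = {"dry": 0.9, "wet": 0.4}

#: Hard ceiling for speed root-finding (m/s); ~144 km/h.
SPEED_CEILING = 40.0


def _range_midpoint(surface: str) -> float:
    lo, hi = ROLLING_COEFF_RANGE[surface]
    return (lo + hi) / 2.0


@dataclass(frozen=True)
class Environment:
    """Ambient conditions.

    ``wind_direction`` is the direction the wind blows *toward*, in degrees
    clockwise from north — the same convention as segment headings, so a
    wind at 180 deg is a pure headwind for a rider heading 0 deg.
    ``rolling_coeff`` and ``sliding_coeff`` default from ``surface``.
    """

    air_density: float = 1.225
    gravity: float = 9.81
    wind_speed: float = 0.0
    wind_direction: float = 0.0
    surface: str = "dry"
    rolling_coeff: float | None = None
    sliding_coeff: float | None = None

    def __post_init__(self) -> None:
        if self.surface not in ROLLING_COEFF_RANGE:
            raise ValidationError(f"surface must be 'dry' or 'wet', got {self.surface!r}")
        if not self.air_density > 0:
            raise ValidationError(f"air_density must be > 0, got {self.air_density}")
        if not self.gravity > 0:
            raise ValidationError(f"gravity must be > 0, got {self.gravity}")
        if self.wind_speed < 0:
            raise ValidationError(f"wind_speed must be >= 0, got {self.wind_speed}")
        if self.rolling_coeff is None:
            object.__setattr__(self, "rolling_coeff", _range_midpoint(self.surface))
        elif self.rolling_coeff < 0:
            raise ValidationError(f"rolling_coeff must be >= 0, got {self.rolling_coeff}")
        if self.sliding_coeff is None:
            object.__setattr__(self, "sliding_coeff", SLIDING_COEFF[self.surface])
        elif self.sliding_coeff < 0:
            raise ValidationError(f"sliding_coeff must be >= 0, got {self.sliding_coeff}")


@dataclass(frozen=True)
class Rider:
    """Rider and equipment parameters.

    The numeric defaults are documented placeholders for a generic elite
    male rider (the speed bounds are the elite averages/maxima); every run
    echoes the effective values so results are reconstructible.

    ``recovery_power`` is the power sustainable indefinitely via aerobic
    metabolism; ``energy_budget`` is the finite amount of work above
    recovery power available for the whole race.
    """

    mass: float = 75.0
    drag_coeff: float = 1.0
    frontal_area: float = 0.25
    recovery_power: float = 300.0
    energy_budget: float = 20_000.0
    v_max_flat: float = 20.83
    v_max_descent: float = 25.0

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValidationError(f"mass must be > 0, got {self.mass}")
        if not self.drag_coeff * self.frontal_area > 0:
            raise ValidationError("drag area C*S must be > 0")
        if not self.recovery_power > 0:
            raise ValidationError(f"recovery_power must be > 0, got {self.recovery_power}")
        if self.energy_budget < 0:
            raise ValidationError(f"energy_budget must be >= 0, got {self.energy_budget}")
        if self.v_max_flat > self.v_max_descent:
            raise ValidationError("v_max_flat must not exceed v_max_descent")

    @property
    def drag_area(self) -> float:
        """C*S in m^2."""
        return self.drag_coeff * self.frontal_area


@dataclass(frozen=True)
class ForceBreakdown:
    """Per-component drive forces (N); ``total`` is their sum."""

    f_air: float
    f_gravity: float
    f_rolling: float
    f_accel: float

    @property
    def total(self) -> float:
        return self.f_air + self.f_gravity + self.f_rolling + self.f_accel


def relative_wind_speed(v_people: float, v_wind: float, alpha_deg: float) -> float:
    """Rider speed minus the along-track wind component; may be negative
    when a tailwind outruns the rider."""
    if v_people < 0:
        raise ValidationError(f"v_people must be >= 0, got {v_people}")
    if v_wind < 0:
        raise ValidationError(f"v_wind must be >= 0, got {v_wind}")
    return v_people - v_wind * math.cos(math.radians(alpha_deg))


def wind_angle(env: Environment, segment: Segment) -> float:
    """Angle between the segment heading and the wind-toward direction."""
    return env.wind_direction - segment.heading


def force_breakdown(
    rider: Rider, env: Environment, segment: Segment, v: float, a: float = 0.0
) -> ForceBreakdown:
    """Drive-force components at speed ``v`` and acceleration ``a``."""
    if v < 0:
        raise ValidationError(f"speed must be >= 0, got {v}")
    v_rel = relative_wind_speed(v, env.wind_speed, wind_angle(env, segment))
    f_air = 0.5 * rider.drag_area * env.air_density * v_rel * abs(v_rel)
    f_rolling = env.rolling_coeff * rider.mass * env.gravity * math.cos(segment.grade_angle)
    f_gravity = rider.mass * env.gravity * math.sin(segment.grade_angle)
    f_accel = rider.mass * a
    return ForceBreakdown(f_air=f_air, f_gravity=f_gravity, f_rolling=f_rolling, f_accel=f_accel)


def required_power(f_c: float, v: float) -> float:
    """Pedal power to sustain speed ``v`` against drive force ``f_c``,
    clamped at zero (no energy recovery through the pedals)."""
    if v < 0:
        raise ValidationError(f"speed must be >= 0, got {v}")
    return max(f_c * v, 0.0)


def _total_force(rider: Rider, env: Environment, segment: Segment, v: float) -> float:
    return force_breakdown(rider, env, segment, v).total


def coasting_speed(
    rider: Rider, env: Environment, segment: Segment, ceiling: float = SPEED_CEILING
) -> float:
    """Zero-pedal equilibrium speed: the root of F_c(v) = 0.

    Returns 0 when resistive forces dominate from standstill (flat or
    uphill without a strong tailwind); otherwise the terminal speed at
    which gravity/tailwind assistance balances drag and rolling friction.
    """
    if _total_force(rider, env, segment, 0.0) >= 0:
        return 0.0
    if _total_force(rider, env, segment, ceiling) < 0:
        raise NumericalError(
            f"no coasting equilibrium below the {ceiling} m/s ceiling on this segment"
        )
    return float(brentq(lambda v: _total_force(rider, env, segment, v), 0.0, ceiling))


def speed_at_power(
    power: float,
    rider: Rider,
    env: Environment,
    segment: Segment,
    ceiling: float = SPEED_CEILING,
) -> float:
    """Invert the power-speed relation: the steady speed at pedal power
    ``power`` on this segment (acceleration zero).

    For ``power = 0`` this is the coasting speed (zero on flat/uphill, the
    terminal speed on a descent). F_c(v)*v is strictly increasing above the
    coasting speed, so the root is unique.
    """
    if power < 0:
        raise ValidationError(f"power must be >= 0, got {power}")
    v0 = coasting_speed(rider, env, segment, ceiling=ceiling)
    if power == 0:
        return v0

    def h(v: float) -> float:
        return _total_force(rider, env, segment, v) * v - power

    if h(ceiling) < 0:
        raise NumericalError(
            f"power {power} W has no equilibrium speed below the {ceiling} m/s ceiling"
        )
    return float(brentq(h, v0, ceiling))


def recovery_speed(rider: Rider, env: Environment, segment: Segment) -> float:
    """Speed sustainable at exactly the recovery power on this segment;
    the lower speed bound used by the optimizer.

    On descents pedalling adds nothing useful, so the lower bound is the
    zero-power coasting speed instead.
    """
    if segment.is_descent:
        return coasting_speed(rider, env, segment)
    return speed_at_power(rider.recovery_power, rider, env, segment)
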