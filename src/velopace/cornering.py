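"""Cornering geometry and friction-limited safe speeds.

The fastest line through a corner uses the largest circle that fits in the
intersection: with inner-bend radius ``r``, road width ``d`` and
intersection angle ``theta`` the effective turn radius is

    R = r + d * (1 - sin(theta / 2)).

Balancing the centripetal demand against the grip limit ``mu_sli * m * g``
(mass cancels) gives the safe corner speed V_mb = sqrt(mu_sli * g * R).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .course import CornerSpec, Course
from .physics import Environment, Rider


@dataclass(frozen=True)
class CornerLimit:
    effective_radius: float
    safe_speed: float


def max_turn_radius(corner: CornerSpec) -> float:
    """Effective radius of the widest arc through the corner (m)."""
    theta = math.radians(corner.intersection_angle)
    return corner.inner_radius + corner.road_width * (1.0 - math.sin(theta / 2.0))


def safe_corner_speed(corner: CornerSpec, env: Environment) -> float:
    """Maximum speed (m/s) through the corner without exceeding grip."""
    return math.sqrt(env.sliding_coeff * env.gravity * max_turn_radius(corner))


def corner_limit(corner: CornerSpec, env: Environment) -> CornerLimit:
    radius = max_turn_radius(corner)
    return CornerLimit(
        effective_radius=radius,
        safe_speed=math.sqrt(env.sliding_coeff * env.gravity * radius),
    )


def apply_corner_limits(course: Course, env: Environment, rider: Rider) -> np.ndarray:
    """Per-segment speed caps (m/s).

    Descents are capped at the rider's descent maximum, flat and uphill
    segments at the elite flat maximum; a segment with a corner is further
    capped at its safe corner speed. Caps never increase when the surface
    switches from dry to wet (the sliding coefficient drops).
    """
    caps = np.empty(len(course))
    for i, seg in enumerate(course):
        cap = rider.v_max_descent if seg.is_descent else rider.v_max_flat
        if seg.corner is not None:
            cap = min(cap, safe_corner_speed(seg.corner, env))
        caps[i] = cap
    return caps
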