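"""Course representation, table I/O, profile segmentation and test fixtures.

A :class:`Course` is an ordered list of :class:`Segment` objects, each with a
length, a grade angle, a compass heading and optionally a :class:`CornerSpec`
describing a corner (inner radius, road width, intersection angle).

Courses are stored on disk as plain CSV with one row per segment and the
columns ``length_m, grade_pct, heading_deg`` plus the optional corner columns
``corner_r_m, corner_d_m, corner_theta_deg`` (blank cells mean "no corner").
Grade is a percent in files and converted to an angle internally so that
``sin``/``cos`` of the grade are exact in the force balance.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import CourseFormatError, ValidationError

REQUIRED_COLUMNS = ("length_m", "grade_pct", "heading_deg")
CORNER_COLUMNS = ("corner_r_m", "corner_d_m", "corner_theta_deg")

#: Standard athletics track: total lap length (m), curve radius (m) and the
#: summed length of the two curves (m). The curve length is a measured value
#: for the riding line and is deliberately kept independent of the radius
#: (2*pi*36.5 = 229.34 m does not equal 231.22 m).
TRACK_400M_LENGTH = 400.0
TRACK_400M_CURVE_RADIUS = 36.5
TRACK_400M_CURVE_LENGTH = 231.22

#: Bridge test course: length (m) and elevation gain (m).
BRIDGE_LENGTH = 1500.0
BRIDGE_ELEVATION = 14.8


@dataclass(frozen=True)
class CornerSpec:
    """Geometry of a corner: inner-bend radius, road width and the
    intersection angle of the two roads (180 degrees = straight through)."""

    inner_radius: float
    road_width: float = 0.0
    intersection_angle: float = 180.0

    def __post_init__(self) -> None:
        if not self.inner_radius > 0:
            raise ValidationError(f"corner inner_radius must be > 0, got {self.inner_radius}")
        if self.road_width < 0:
            raise ValidationError(f"corner road_width must be >= 0, got {self.road_width}")
        if not 0 < self.intersection_angle <= 180:
            raise ValidationError(
                f"corner intersection_angle must be in (0, 180], got {self.intersection_angle}"
            )


@dataclass(frozen=True)
class Segment:
    """One constant-grade, constant-heading stretch of road.

    ``grade_angle`` is in radians; ``heading`` in degrees clockwise from
    north (the same convention as wind direction: the direction of travel).
    """

    length: float
    grade_angle: float = 0.0
    heading: float = 0.0
    corner: CornerSpec | None = None

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValidationError(f"segment length must be > 0, got {self.length}")
        if not abs(self.grade_angle) < math.pi / 2:
            raise ValidationError(f"grade angle must satisfy |gamma| < pi/2, got {self.grade_angle}")
        if not 0 <= self.heading < 360:
            raise ValidationError(f"heading must be in [0, 360), got {self.heading}")

    @property
    def grade_pct(self) -> float:
        """Grade as rise-over-run percent, 100*tan(gamma)."""
        return 100.0 * math.tan(self.grade_angle)

    @property
    def ascent(self) -> float:
        """Elevation change over the segment in metres (negative downhill)."""
        return self.length * math.sin(self.grade_angle)

    @property
    def is_descent(self) -> bool:
        return self.grade_angle < 0


@dataclass(frozen=True)
class Course:
    segments: tuple[Segment, ...]
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValidationError("a course must contain at least one segment")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    @property
    def total_length(self) -> float:
        return sum(seg.length for seg in self.segments)

    @property
    def total_ascent(self) -> float:
        """Sum of positive elevation gains (m)."""
        return sum(max(seg.ascent, 0.0) for seg in self.segments)


@dataclass(frozen=True)
class RawProfilePoint:
    """A sampled point of a raw course profile: cumulative along-track
    distance (m), elevation (m) and travel heading at the point (degrees)."""

    distance: float
    elevation: float
    heading: float = 0.0


@dataclass(frozen=True)
class CourseStats:
    total_length_m: float
    total_ascent_m: float
    mean_grade_pct: float


def course_stats(course: Course) -> CourseStats:
    """Summary totals; mean grade is 100 * total ascent / total length."""
    length = course.total_length
    ascent = course.total_ascent
    return CourseStats(
        total_length_m=length,
        total_ascent_m=ascent,
        mean_grade_pct=100.0 * ascent / length,
    )


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------


def read_course_table(path: str | Path) -> Course:
    """Read a course from its CSV table representation.

    Corner fields are only honoured when all three corner columns are
    present and non-blank for a row.
    """
    path = Path(path)
    if not path.exists():
        raise CourseFormatError(f"course table not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CourseFormatError(f"course table {path} is missing required columns: {missing}")
    has_corners = all(c in df.columns for c in CORNER_COLUMNS)
    segments = []
    for i, row in df.iterrows():
        length = float(row["length_m"])
        if not length > 0:
            raise ValidationError(f"row {i}: length_m must be > 0, got {length}")
        corner = None
        if has_corners and all(pd.notna(row[c]) for c in CORNER_COLUMNS):
            corner = CornerSpec(
                inner_radius=float(row["corner_r_m"]),
                road_width=float(row["corner_d_m"]),
                intersection_angle=float(row["corner_theta_deg"]),
            )
        try:
            segments.append(
                Segment(
                    length=length,
                    grade_angle=math.atan(float(row["grade_pct"]) / 100.0),
                    heading=float(row["heading_deg"]) % 360.0,
                    corner=corner,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return Course(segments=tuple(segments), name=path.stem)


def write_course_table(course: Course, path: str | Path) -> None:
    """Write a course as CSV; exact float round-trip via %.17g formatting."""
    rows = []
    for seg in course:
        row = {
            "length_m": seg.length,
            "grade_pct": seg.grade_pct,
            "heading_deg": seg.heading,
            "corner_r_m": seg.corner.inner_radius if seg.corner else None,
            "corner_d_m": seg.corner.road_width if seg.corner else None,
            "corner_theta_deg": seg.corner.intersection_angle if seg.corner else None,
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# profile segmentation
# ---------------------------------------------------------------------------


def _circular_diff_deg(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def segment_profile(
    points: Sequence[RawProfilePoint],
    flat_grade_threshold: float = 0.005,
    straight_heading_threshold: float = 5.0,
) -> Course:
    """Collapse a sampled profile into constant-grade, constant-heading
    segments.

    Consecutive sampling intervals are merged while the interval grade stays
    within ``flat_grade_threshold`` (a fraction, e.g. 0.005 = 0.5 %) of the
    accumulated run grade and the heading stays within
    ``straight_heading_threshold`` degrees of the run heading. Merge passes
    repeat until a fixed point, which makes the operation idempotent: small
    undulations become one flat segment and a hill becomes a single ramp
    joining its foot and crest.
    """
    if len(points) < 2:
        raise ValidationError("segment_profile requires at least 2 profile points")
    if flat_grade_threshold < 0 or straight_heading_threshold < 0:
        raise ValidationError("segmentation thresholds must be >= 0")
    dists = [p.distance for p in points]
    if any(d1 - d0 <= 0 for d0, d1 in zip(dists, dists[1:])):
        raise ValidationError("profile point distances must be strictly increasing")

    # (length, rise, heading) per sampling interval; heading taken at entry.
    items: list[tuple[float, float, float]] = []
    for p0, p1 in zip(points, points[1:]):
        items.append((p1.distance - p0.distance, p1.elevation - p0.elevation, p0.heading))

    def merge_pass(runs: list[tuple[float, float, float]]) -> list[tuple[float, float, float]]:
        out = [runs[0]]
        for length, rise, heading in runs[1:]:
            run_len, run_rise, run_heading = out[-1]
            same_grade = abs(rise / length - run_rise / run_len) <= flat_grade_threshold
            same_heading = _circular_diff_deg(heading, run_heading) <= straight_heading_threshold
            if same_grade and same_heading:
                out[-1] = (run_len + length, run_rise + rise, run_heading)
            else:
                out.append((length, rise, heading))
        return out

    runs = items
    while True:
        merged = merge_pass(runs)
        if merged == runs:
            break
        runs = merged

    segments = tuple(
        Segment(length=length, grade_angle=math.atan(rise / length), heading=heading % 360.0)
        for length, rise, heading in runs
    )
    return Course(segments=segments, name="segmented")


def course_to_profile(course: Course) -> list[RawProfilePoint]:
    """Reconstruct a per-segment sampled profile (inverse of segmentation)."""
    points = [RawProfilePoint(0.0, 0.0, course.segments[0].heading)]
    dist = 0.0
    elev = 0.0
    for i, seg in enumerate(course):
        dist += seg.length
        elev += seg.length * math.tan(seg.grade_angle)
        heading = course.segments[min(i + 1, len(course) - 1)].heading
        points.append(RawProfilePoint(dist, elev, heading))
    return points


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_track_400m(
    total_length: float = TRACK_400M_LENGTH,
    curve_radius: float = TRACK_400M_CURVE_RADIUS,
    curve_length: float = TRACK_400M_CURVE_LENGTH,
) -> Course:
    """Standard 400 m athletics track: two straights and two curves.

    The two curves share ``curve_length`` equally and carry a corner spec
    with the given radius (zero road width, 180 degree intersection, so the
    effective turn radius equals the curve radius); the straights split the
    remaining distance equally.
    """
    if not 0 < curve_length < total_length:
        raise ValidationError("curve_length must be in (0, total_length)")
    straight = (total_length - curve_length) / 2.0
    curve = curve_length / 2.0
    corner = CornerSpec(inner_radius=curve_radius, road_width=0.0, intersection_angle=180.0)
    segments = (
        Segment(length=straight, heading=0.0),
        Segment(length=curve, heading=90.0, corner=corner),
        Segment(length=straight, heading=180.0),
        Segment(length=curve, heading=270.0, corner=corner),
    )
    return Course(segments=segments, name="track400")


def make_bridge_course(
    mode: str = "single",
    length: float = BRIDGE_LENGTH,
    elevation: float = BRIDGE_ELEVATION,
) -> Course:
    """Bridge test course: 1.5 km with 14.8 m of climbing.

    ``mode="single"`` (default) is one constant-grade ascent whose mean
    grade is 100*elevation/length (0.987 %). ``mode="up_down"`` climbs the
    full elevation over the first half and descends it over the second, for
    experiments needing a descent.
    """
    if mode == "single":
        gamma = math.asin(elevation / length)
        segments = (Segment(length=length, grade_angle=gamma, heading=0.0),)
    elif mode == "up_down":
        half = length / 2.0
        gamma = math.asin(elevation / half)
        segments = (
            Segment(length=half, grade_angle=gamma, heading=0.0),
            Segment(length=half, grade_angle=-gamma, heading=0.0),
        )
    else:
        raise ValidationError(f"unknown bridge mode {mode!r}; use 'single' or 'up_down'")
    return Course(segments=segments, name=f"bridge-{mode}")


def random_course(
    n_segments: int = 8,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    corner_prob: float = 0.2,
    max_grade_pct: float = 8.0,
) -> Course:
    """Synthesize a randomized course for simulation studies and tests."""
    if n_segments < 1:
        raise ValidationError("n_segments must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    segments = []
    for _ in range(n_segments):
        grade_pct = float(np.clip(rng.normal(0.0, 3.0), -max_grade_pct, max_grade_pct))
        corner = None
        if rng.random() < corner_prob:
            corner = CornerSpec(
                inner_radius=float(rng.uniform(10.0, 50.0)),
                road_width=float(rng.uniform(0.0, 8.0)),
                intersection_angle=float(rng.uniform(60.0, 180.0)),
            )
        segments.append(
            Segment(
                length=float(rng.uniform(200.0, 2000.0)),
                grade_angle=math.atan(grade_pct / 100.0),
                heading=float(rng.uniform(0.0, 360.0)),
                corner=corner,
            )
        )
    return Course(segments=tuple(segments), name=f"random-{seed}")


# ---------------------------------------------------------------------------
# GPX ingestion
# ---------------------------------------------------------------------------

_EARTH_RADIUS_M = 6_371_000.0


def _haversine_m(lat0: float, lon0: float, lat1: float, lon1: float) -> float:
    phi0, phi1 = math.radians(lat0), math.radians(lat1)
    dphi = phi1 - phi0
    dlam = math.radians(lon1 - lon0)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi0) * math.cos(phi1) * math.sin(dlam / 2) ** 2
    return 2 * _EARTH_RADIUS_M * math.asin(math.sqrt(a))


def _bearing_deg(lat0: float, lon0: float, lat1: float, lon1: float) -> float:
    phi0, phi1 = math.radians(lat0), math.radians(lat1)
    dlam = math.radians(lon1 - lon0)
    y = math.sin(dlam) * math.cos(phi1)
    x = math.cos(phi0) * math.sin(phi1) - math.sin(phi0) * math.cos(phi1) * math.cos(dlam)
    return math.degrees(math.atan2(y, x)) % 360.0


def read_gpx(path: str | Path) -> list[RawProfilePoint]:
    """Read GPX 1.1 track points into raw profile points.

    Distance is cumulative great-circle distance; heading at a point is the
    bearing to the next point (the last point repeats the previous heading).
    Zero-length steps are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise CourseFormatError(f"GPX file not found: {path}")
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise CourseFormatError(f"malformed GPX file {path}: {exc}") from exc

    coords: list[tuple[float, float, float]] = []
    for el in root.iter():
        if el.tag.rsplit("}", 1)[-1] == "trkpt":
            lat = float(el.attrib["lat"])
            lon = float(el.attrib["lon"])
            ele = 0.0
            for child in el:
                if child.tag.rsplit("}", 1)[-1] == "ele" and child.text is not None:
                    ele = float(child.text)
            coords.append((lat, lon, ele))
    if len(coords) < 2:
        raise CourseFormatError(f"GPX file {path} contains fewer than 2 track points")

    points: list[RawProfilePoint] = []
    dist = 0.0
    heading = 0.0
    for i, (lat, lon, ele) in enumerate(coords):
        if i > 0:
            step = _haversine_m(coords[i - 1][0], coords[i - 1][1], lat, lon)
            if step <= 0:
                continue
            dist += step
        if i < len(coords) - 1:
            heading = _bearing_deg(lat, lon, coords[i + 1][0], coords[i + 1][1])
        points.append(RawProfilePoint(distance=dist, elevation=ele, heading=heading))
    return points
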