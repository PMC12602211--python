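import math

import numpy as np
import pytest

from velopace import Course, Environment, Rider, Segment


@pytest.fixture
def env():
    return Environment()


@pytest.fixture
def rider():
    return Rider()


@pytest.fixture
def toy_env():
    """Environment giving round drag/rolling constants: 1/2*C*rho*S = 0.2
    and mu*m*g = 3 together with toy_rider, so P(v) = 0.2 v^3 + 3 v on the
    flat and P(10) = 230 W exactly."""
    return Environment(air_density=1.0, gravity=10.0, rolling_coeff=0.01)


@pytest.fixture
def toy_rider():
    return Rider(
        mass=30.0,
        drag_coeff=0.4,
        frontal_area=1.0,
        recovery_power=230.0,
        energy_budget=20_000.0,
    )


@pytest.fixture
def flat_segment():
    return Segment(length=1000.0)


@pytest.fixture
def flat_course(flat_segment):
    return Course((flat_segment,), name="flat1000")


def make_course(*specs):
    """Build a course from (length, grade_fraction) pairs."""
    return Course(
        tuple(Segment(length=s, grade_angle=math.atan(g)) for s, g in specs), name="test"
    )


@pytest.fixture
def toy3_course():
    """Flat / 3% climb / flat."""
    return make_course((1000.0, 0.0), (500.0, 0.03), (1000.0, 0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
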