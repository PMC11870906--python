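import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tumorshape as ts

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def unit_square() -> ts.Contour:
    return ts.Contour([(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)])


def star_contour(r_outer: float = 2.0, r_inner: float = 1.0) -> ts.Contour:
    """5-point star: 10 vertices alternating between two circumradii."""
    ang = np.arange(10) * np.pi / 5 + np.pi / 2
    r = np.where(np.arange(10) % 2 == 0, r_outer, r_inner)
    return ts.Contour(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))


@pytest.fixture
def star() -> ts.Contour:
    return star_contour()


def regular_ngon(n: int, radius: float = 1.0) -> ts.Contour:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return ts.Contour(np.column_stack([radius * np.cos(th), radius * np.sin(th)]))


@pytest.fixture
def circle_4096() -> ts.Contour:
    return regular_ngon(4096, radius=10.0)


def random_survival(rng, n: int, scale: float = 300.0, censor_frac: float = 0.3):
    t = rng.exponential(scale, n) + 0.5
    e = rng.random(n) >= censor_frac
    return t, e
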