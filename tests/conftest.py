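import math

import numpy as np
import pytest

from octavd.io_formats import ScanAnnotation
from octavd.synthetic import PhantomConfig, generate_phantom


def ellipse_points(n=48, center=(254.0, 254.0), a=60.0, b=50.0, rot=0.0):
    """n points on an ellipse, counter-clockwise in the y-down frame."""
    t = np.arange(n) * (2 * math.pi / n)
    ex, ey = a * np.cos(t), b * np.sin(t)
    xs = center[0] + ex * math.cos(rot) - ey * math.sin(rot)
    ys = center[1] + ex * math.sin(rot) + ey * math.cos(rot)
    return np.column_stack([xs, ys])


def make_annotation(center=(254.0, 254.0), a=60.0, b=50.0, fovea=(800.0, 254.0), laterality="OD", **kw):
    return ScanAnnotation(
        bmo_points=ellipse_points(center=center, a=a, b=b),
        fovea_xy=fovea,
        laterality=laterality,
        **kw,
    )


@pytest.fixture(scope="session")
def small_config():
    """A cheap 192-px phantom configuration for fast pipeline tests."""
    return PhantomConfig(
        shape=(192, 192),
        bmo_center=(96.3, 95.7),
        bmo_semi_axes=(40.0, 34.0),
        n_radial_vessels=40,
        width_range=(2.0, 6.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return generate_phantom(small_config)
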