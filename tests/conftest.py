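import numpy as np
import pytest

from nemaclear.director import OrientationField
from nemaclear.synthgen import PlantedDefect, SceneConfig, ideal_director_field


@pytest.fixture
def scene512():
    return SceneConfig(shape=(512, 512), seed=11)


@pytest.fixture
def plus_field(scene512):
    """Ideal +1/2 defect field, phase 0.3, centered, noise-free."""
    xm, ym = scene512.extent
    d = PlantedDefect(position=(xm / 2, ym / 2), charge=+0.5, phase=0.3)
    return ideal_director_field([d], scene512)


@pytest.fixture
def minus_field(scene512):
    """Ideal -1/2 defect field, phase 0.3, centered, noise-free."""
    xm, ym = scene512.extent
    d = PlantedDefect(position=(xm / 2, ym / 2), charge=-0.5, phase=0.3)
    return ideal_director_field([d], scene512)


def uniform_field(angle_rad, shape=(64, 64), spacing=1.0):
    theta = np.full(shape, float(angle_rad))
    return OrientationField(theta=theta, coherence=np.ones(shape),
                            grid_spacing=spacing, pixel_size=spacing)


def rectangle_loop(r0, c0, r1, c1):
    """Closed counterclockwise loop of grid nodes around a rectangle."""
    nodes = []
    nodes += [(r0, c) for c in range(c0, c1)]
    nodes += [(r, c1) for r in range(r0, r1)]
    nodes += [(r1, c) for c in range(c1, c0, -1)]
    nodes += [(r, c0) for r in range(r1, r0, -1)]
    return nodes
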