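"""Shared fixtures: canonical point-cloud and scene constructions."""

import numpy as np
import pytest

from phytoprobe import scene as scene_mod


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plane_cloud():
    """Noiseless grid on z = 0, 30 x 30 points over 0.1 m."""
    xs = np.linspace(0.0, 0.1, 30)
    xx, yy = np.meshgrid(xs, xs)
    return np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])


@pytest.fixture
def sphere_cloud(rng):
    """~2000 uniform points on a sphere of radius 0.1 m."""
    v = rng.normal(size=(2000, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return 0.1 * v


@pytest.fixture
def ribbon_cloud():
    """Axis-aligned planar ribbon, 100 x 20 mm, on z = 0."""
    xs = np.linspace(0.0, 0.100, 101)
    ys = np.linspace(0.0, 0.020, 21)
    xx, yy = np.meshgrid(xs, ys)
    return np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])


@pytest.fixture
def flat_leaf():
    return scene_mod.LeafModel(
        species_style="flat_round", length_mm=70.0, width_mm=60.0,
        attachment=(0.3, 0.3, 0.4), azimuth_deg=30.0, inclination_deg=-10.0)


@pytest.fixture
def twisted_leaf():
    return scene_mod.LeafModel(
        species_style="elongated_twisted", length_mm=300.0, width_mm=40.0,
        twist_rate=0.6, attachment=(0.3, 0.3, 0.4),
        azimuth_deg=45.0, inclination_deg=0.0)


@pytest.fixture
def soy_spec():
    """One pot, flat-round (soybean-like) plant."""
    return scene_mod.SceneSpec(
        pot_positions=((0.5, 0.5),), species_style="flat_round",
        leaves_per_plant=2, stem_height_m=0.3)


@pytest.fixture
def maize_spec():
    """One pot, elongated-twisted (maize-like) plant."""
    return scene_mod.SceneSpec(
        pot_positions=((0.5, 0.5),), species_style="elongated_twisted",
        leaves_per_plant=2, stem_height_m=0.4)


def random_rotation(rng):
    """Uniform-ish random rotation matrix via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
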