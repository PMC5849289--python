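import numpy as np
import pytest

import voxray as vx
from voxray.phantoms import PhantomSpec, make_shell_phantom, make_sphere_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture(scope="session")
def sphere_volume():
    """Smooth-edged 48^3 ball, the workhorse test scene."""
    spec = PhantomSpec("sphere", dims=(48, 48, 48),
                       params={"radius": 0.35, "edge_width": 0.08})
    return make_sphere_phantom(spec)


@pytest.fixture(scope="session")
def sphere_tf():
    return vx.TransferFunction([[0, 0, 0, 0], [1, 1, 0.6, 0.2]],
                               [[0, 0], [1, 0.6]])


@pytest.fixture()
def sphere_scene(sphere_volume, sphere_tf):
    return vx.Scene([vx.VolumeNode(sphere_volume, sphere_tf)])


@pytest.fixture(scope="session")
def head_on_camera():
    return vx.Camera(position=(0.5, 0.5, 2.5), target=(0.5, 0.5, 0.5),
                     width=64, height=64, vfov=35)


@pytest.fixture(scope="session")
def shell_volume():
    """Semi-opaque core (0.9), transparent gap, opaque outer shell (0.5)."""
    spec = PhantomSpec("shells", dims=(64, 64, 64),
                       params={"radii": [0.15, 0.25, 0.4],
                               "values": [0.9, 0.0, 0.5]})
    return make_shell_phantom(spec)


@pytest.fixture(scope="session")
def shell_tf():
    # opacity lives in two disjoint narrow bands: a spike at the shell
    # value (0.5) and a ramp up to the core value (0.9); everything in
    # between is exactly transparent, which makes peeling predictable
    return vx.TransferFunction(
        color_points=[[0.0, 0, 0, 0], [0.5, 1.0, 0.8, 0.5], [0.9, 0.2, 0.6, 1.0]],
        opacity_points=[[0.0, 0.0], [0.499, 0.0], [0.5, 0.8], [0.501, 0.0],
                        [0.85, 0.0], [0.9, 0.6]],
    )
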