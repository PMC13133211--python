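import numpy as np
import pytest

from x2br.phantoms import PrimitiveSpec, make_primitive, make_toy_thorax


@pytest.fixture(scope="session")
def sphere_spec():
    return PrimitiveSpec("sphere", {"radius": 0.4}, 4)


@pytest.fixture(scope="session")
def sphere_mesh(sphere_spec):
    return make_primitive(sphere_spec)


@pytest.fixture(scope="session")
def torus_spec():
    return PrimitiveSpec("torus", {"ring_radius": 0.3, "tube_radius": 0.1}, 4)


@pytest.fixture(scope="session")
def torus_mesh(torus_spec):
    return make_primitive(torus_spec)


@pytest.fixture(scope="session")
def capsule_spec():
    return PrimitiveSpec("capsule", {"a": (0, 0, -0.25), "b": (0, 0, 0.25), "radius": 0.12}, 3)


@pytest.fixture(scope="session")
def capsule_mesh(capsule_spec):
    return make_primitive(capsule_spec)


@pytest.fixture(scope="session")
def small_thorax():
    return make_toy_thorax(3, 3, jitter=0.0, seed=7, resolution=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def box_mesh(extents, center=(0, 0, 0)):
    """Axis-aligned closed box as a 12-triangle watertight mesh."""
    from x2br.geometry import TriMesh

    e = np.asarray(extents, dtype=float) / 2.0
    c = np.asarray(center, dtype=float)
    corners = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    ) * e + c
    faces = np.array(
        [
            [0, 1, 3], [0, 3, 2], [4, 6, 7], [4, 7, 5],
            [0, 4, 5], [0, 5, 1], [2, 3, 7], [2, 7, 6],
            [0, 2, 6], [0, 6, 4], [1, 5, 7], [1, 7, 3],
        ]
    )
    mesh = TriMesh(corners, faces)
    return mesh if mesh.signed_volume() > 0 else mesh.flipped()


def sigmoid_field(center, radius, steepness=30.0):
    """Smooth radial occupancy field used as an analytic stand-in."""
    c = np.asarray(center, dtype=float)

    def field(points):
        d = np.linalg.norm(np.atleast_2d(points) - c, axis=1)
        return 1.0 / (1.0 + np.exp(steepness * (d - radius)))

    return field
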