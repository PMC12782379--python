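import numpy as np
import pytest
import trimesh

from pact.synthetic import (LimbParams, SocketDesignParams, derive_socket,
                            generate_cohort, generate_limb)


@pytest.fixture(scope="session")
def cohort19():
    """A 19-participant synthetic cohort drawn from the reference population."""
    library, truth = generate_cohort(19, seed=11)
    return library, truth


@pytest.fixture(scope="session")
def cohort5():
    library, truth = generate_cohort(5, seed=3)
    return library, truth


@pytest.fixture(scope="session")
def base_limb():
    """A noise-free conical limb with its landmarks."""
    return generate_limb(LimbParams(noise_sd=0.0), seed=1)


@pytest.fixture(scope="session")
def base_socket(base_limb):
    """Socket derived from the base limb (default asymmetric trimline)."""
    limb, _ = base_limb
    return derive_socket(limb, SocketDesignParams())


@pytest.fixture(scope="session")
def symmetric_socket(base_limb):
    """Socket with equal epicondylar indents: exactly mirror-symmetric."""
    limb, _ = base_limb
    return derive_socket(limb, SocketDesignParams(indent_medial_scale=1.0))


@pytest.fixture
def unit_cube():
    return trimesh.creation.box(extents=[1.0, 1.0, 1.0])


@pytest.fixture
def cylinder():
    return trimesh.creation.cylinder(radius=20.0, height=80.0, sections=128)


@pytest.fixture
def sphere():
    return trimesh.creation.icosphere(subdivisions=4, radius=1.0)


def rotation(deg_xyz):
    from scipy.spatial.transform import Rotation
    return Rotation.from_euler("xyz", deg_xyz, degrees=True).as_matrix()


def angle_between(u, v) -> float:
    u = np.asarray(u) / np.linalg.norm(u)
    v = np.asarray(v) / np.linalg.norm(v)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))
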