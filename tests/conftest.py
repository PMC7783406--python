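import numpy as np
import pytest
import trimesh

from eeglocate import (
    ElectrodeSet,
    PhantomParams,
    TriangleMesh,
    load_montage,
    make_phantom,
)


@pytest.fixture(scope="session")
def montage():
    return load_montage()


@pytest.fixture(scope="session")
def icosphere_mesh():
    """Closed sphere of radius 0.1 m (analytic curvature 10 /m)."""
    s = trimesh.creation.icosphere(subdivisions=4, radius=0.1)
    return TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces))


@pytest.fixture(scope="session")
def default_phantom():
    """One default synthetic subject (64 electrodes, 15 dummy holders)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_phantom(seed=1)


@pytest.fixture(scope="session")
def quiet_phantom_params():
    """Phantom with no dummies/nuisance structure, for isolation tests."""
    return PhantomParams(
        n_dummies=0, with_ears=False, n_nuisance=0,
        surface_noise_amplitude=0.0, angular_jitter_sd=0.0,
    )


@pytest.fixture
def tetra_mesh():
    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(verts, faces)


@pytest.fixture
def unit_square_set():
    pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    return ElectrodeSet(pts, ["A", "B", "C", "D"])
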