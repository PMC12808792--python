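import numpy as np
import pytest

from corneomech.synthetic import (
    DEFAULT_SUBSTRATE,
    forward_displacement,
    make_traction_field,
    standard_dipole_scene,
)


@pytest.fixture(scope="session")
def dipole_truth():
    """Reference contractile dipole scene and its rasterized traction."""
    scene = standard_dipole_scene()
    return scene, make_traction_field(scene)


@pytest.fixture(scope="session")
def dipole_displacement(dipole_truth):
    """Exact half-space displacement of the reference dipole (um)."""
    _, truth = dipole_truth
    return forward_displacement(truth, DEFAULT_SUBSTRATE)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
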