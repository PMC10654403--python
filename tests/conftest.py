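import numpy as np
import pytest

from depotmetry.phantom import (DepotSpec, PhantomSpec, PressureSpec,
                                generate_session)


@pytest.fixture(scope="session")
def tiny_spec():
    """A small septal-growth phantom: fast but structurally complete.

    Tilt-free so that voxel-level comparison against the true mask is
    exact; the even-frame tilt path has its own dedicated tests.
    """
    return PhantomSpec(
        grid_shape=(48, 64, 64),
        n_frames=8,
        depot=DepotSpec(voxels_per_impulse=300),
        epidermis_z=6,
        dermis_hypodermis_z=16,
        even_frame_shift_vox=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_session(tiny_spec):
    return generate_session(tiny_spec, seed=11)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, shift-free variant for exact-arithmetic checks."""
    return PhantomSpec(
        grid_shape=(48, 64, 64),
        n_frames=6,
        depot=DepotSpec(voxels_per_impulse=300),
        epidermis_z=6,
        dermis_hypodermis_z=16,
        noise_gaussian_sd=0.0,
        even_frame_shift_vox=0.0,
        pressure=PressureSpec(noise_sd_mbar=0.0),
        seed=5,
    )


@pytest.fixture(scope="session")
def clean_session(clean_spec):
    return generate_session(clean_spec, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
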