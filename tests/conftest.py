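import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dentct

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tooth_noiseless():
    """Default noiseless tooth phantom (10 μm voxels), shared per session."""
    vol, truth = dentct.generate_tooth_phantom(dentct.PhantomSpec())
    return vol, truth


@pytest.fixture(scope="session")
def tooth_noisy50():
    """Default phantom with grey-value noise sd 50 mg/cm³ HA."""
    spec = dentct.PhantomSpec(noise_sd=50.0, seed=5)
    vol, truth = dentct.generate_tooth_phantom(spec)
    return vol, truth


@pytest.fixture(scope="session")
def small_tooth():
    """Coarse (20 μm) phantom for fast geometric tests."""
    spec = dentct.PhantomSpec(voxel_size_um=20.0)
    vol, truth = dentct.generate_tooth_phantom(spec)
    return spec, vol, truth


@pytest.fixture()
def no_warn():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def make_tube(nz=40, n=120, cy=None, ri=20, ro=65, span_z=True):
    """Hollow cylinder mask spanning the full z extent (no end faces)."""
    cy = (n - 1) / 2 if cy is None else cy
    r = np.sqrt(
        (np.arange(n)[:, None] - cy) ** 2 + (np.arange(n)[None, :] - cy) ** 2
    )
    ring = (r >= ri) & (r <= ro)
    return np.broadcast_to(ring, (nz, n, n)).copy()
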