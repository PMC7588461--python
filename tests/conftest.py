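import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aftomo import AcquisitionSpec, PhantomSpec, forward_project, generate_phantom

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=20,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_SPEC = PhantomSpec(
    shape_vox=(64, 64, 64),
    voxel_size_um=10.0,
    n_islets=15,
    n_vessels=2,
    islet_diameter_log_mu=np.log(60.0),
    islet_diameter_log_sigma=0.3,
    seed=11,
)


@pytest.fixture(scope="session")
def small_phantom():
    """64^3 phantom with 15 islets, shared by read-only tests."""
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_stack(small_phantom):
    """Noise-free 120-angle scan of the small phantom, zero COR offset."""
    volume, _ = small_phantom
    return forward_project(
        volume, AcquisitionSpec(n_angles=120, cor_offset_px=0.0, noise_model="none")
    )
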