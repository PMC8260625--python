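import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from petquant import (CohortSpec, PhantomSpec, VolumetricImage,
                      generate_nema_phantom, generate_patient_cohort)

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_phantom():
    """Blurred, noise-free default phantom with its spec and truth masks."""
    spec = PhantomSpec(noise_sd_fraction=0.0, seed=11)
    image, truth = generate_nema_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient cohort at default study conditions."""
    return generate_patient_cohort(CohortSpec(n_patients=12, seed=5))


@pytest.fixture()
def toy_cross_image():
    """7×7×7 image: centre voxel 10, its six face neighbours 6, elsewhere 1.

    At a 50% threshold the mask is exactly the centre plus its six face
    neighbours (7 voxels).
    """
    data = np.ones((7, 7, 7))
    c = (3, 3, 3)
    data[c] = 10.0
    for ax in range(3):
        for d in (-1, 1):
            idx = list(c)
            idx[ax] += d
            data[tuple(idx)] = 6.0
    return VolumetricImage(data, spacing_mm=(2.0, 2.0, 2.0))
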