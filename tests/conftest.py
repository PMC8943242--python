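import numpy as np
import pytest

from usdot.forward import TimeGrid, default_probe, gaussian_irf, run_forward
from usdot.optics import homogeneous_maps
from usdot.phantom import LesionSpec, PhantomConfig, generate_lesion_shape, generate_phantom


@pytest.fixture(scope="session")
def probe():
    return default_probe()


@pytest.fixture(scope="session")
def small_phantom_config():
    """1 mm phantom used across tests (fast to generate)."""
    return PhantomConfig(fat_fraction=0.6, fine_spacing=1.0, coarse_spacing=5.0,
                         texture_scale=6.0)


@pytest.fixture(scope="session")
def small_phantom(small_phantom_config):
    return generate_phantom(small_phantom_config, rng_seed=1)


@pytest.fixture(scope="session")
def lesion_mask_8mm():
    return generate_lesion_shape(LesionSpec(mean_radius=8.0, irregularity=0.3, rng_seed=3), 1.0)


@pytest.fixture(scope="session")
def coarse_grid():
    """Shape/spacing of the desk-scale optical grid plus voxel centers."""
    shape, h = (12, 11, 6), 5.0
    ax = [(np.arange(n) + 0.5) * h - n * h / 2 for n in shape]
    ax[2] = (np.arange(shape[2]) + 0.5) * h
    return shape, h, np.meshgrid(*ax, indexing="ij")


@pytest.fixture(scope="session")
def homogeneous_measurement(probe):
    """Noiseless homogeneous measurement on the desk-scale grid (one λ)."""
    tg = TimeGrid(dt=50.0, n_steps=80)
    irf = gaussian_irf(fwhm=400.0, dt=10.0)
    maps = homogeneous_maps(0.008, 1.1, (12, 11, 6), 5.0)
    return run_forward(maps, probe, tg, irf=irf)
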