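import numpy as np
import pytest

from ctri.phantom import PhantomSpec, generate_phantom
from ctri.segmentation import SegmentationParams


@pytest.fixture(scope="session")
def default_params():
    return SegmentationParams()


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless 5-slice phantom, affected (left) density 2x unaffected."""
    spec = PhantomSpec(n_slices=5, noise_sd=0.0, reticulation_density=(0.2, 0.1), seed=42)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(n_slices=5, noise_sd=5.0, reticulation_density=(0.2, 0.1), seed=42)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def mirror_phantom():
    """Limbs that are exact horizontal mirrors of each other (noise included)."""
    spec = PhantomSpec(
        n_slices=4, noise_sd=5.0, reticulation_density=(0.15, 0.15), seed=7, mirror=True
    )
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture
def two_disk_slice():
    """A 64x64 HU slice with two small limbs for oracle-scale tests."""
    img = np.full((64, 64), -1000.0)
    rr, cc = np.ogrid[:64, :64]
    for centre_col in (16, 47):
        d2 = (rr - 32) ** 2 + (cc - centre_col) ** 2
        limb = d2 <= 13**2
        muscle = d2 <= 6**2
        img[limb] = -100.0
        img[muscle] = 45.0
        skin = limb & (d2 > 11**2)
        img[skin] = 35.0
        # a detached bright trabecular speck in the fat annulus
        img[32, centre_col + 9] = 60.0
        img[33, centre_col + 9] = 60.0
        img[32, centre_col + 8] = 60.0
    return img
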