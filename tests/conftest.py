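import numpy as np
import pytest

from multiatlas import LabelMap, PhantomSpec, VolumeImage, generate_phantom
from multiatlas.cohort import DEFAULT_VOLUMES_CC


def small_spec(**overrides) -> PhantomSpec:
    """A coarse (48x48x32 @ 4 mm) phantom spec: same anatomy, 8x fewer voxels."""
    kwargs = dict(shape=(48, 48, 32), spacing=(4.0, 4.0, 4.0), noise_sd=0.0)
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def phantom():
    """Default noise-free phantom at full resolution (96x96x64 @ 2 mm)."""
    return generate_phantom(PhantomSpec(noise_sd=0.0), "phantom")


@pytest.fixture(scope="session")
def coarse_phantom():
    return generate_phantom(small_spec(), "coarse")


def make_volumes(bladder=254.0, rectum=68.0, **others):
    vols = dict(DEFAULT_VOLUMES_CC)
    vols["bladder"] = bladder
    vols["rectum"] = rectum
    vols.update(others)
    return vols


def binary_map(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> LabelMap:
    return LabelMap(mask.astype(np.int16), spacing=spacing)


def cube_mask(shape, lo, hi) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return m


def random_blob(shape, rng, p=0.5, ensure_nonempty=True) -> np.ndarray:
    from scipy import ndimage

    m = rng.random(shape) < p
    m = ndimage.binary_closing(m)
    if ensure_nonempty and not m.any():
        m[tuple(s // 2 for s in shape)] = True
    return m


def image_like(data, spacing=(1.0, 1.0, 1.0)) -> VolumeImage:
    return VolumeImage(np.asarray(data, dtype=float), spacing=spacing)
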