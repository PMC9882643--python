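import numpy as np
import pytest

from petstd import Mask, Modality, PhantomConfig, VolumeImage, generate_cohort


def make_volume(arr, modality=Modality.SUV, spacing=(4.0, 4.0, 4.0)):
    return VolumeImage(voxels=np.asarray(arr, dtype=float), spacing=spacing,
                       modality=modality)


def random_volume(rng, shape=(6, 6, 6), lo=0.0, hi=10.0, modality=Modality.SUV):
    """Random positive volume with min pinned to `lo` (the typical PET zero floor)."""
    vox = rng.uniform(lo, hi, size=shape)
    vox.ravel()[rng.integers(vox.size)] = lo
    return make_volume(vox, modality=modality)


def random_organ_mask(rng, shape=(6, 6, 6), frac=0.2):
    m = rng.random(shape) < frac
    if not m.any():
        m.ravel()[rng.integers(m.size)] = True
    return Mask(m, kind="other")


@pytest.fixture(scope="session")
def suv_cohort():
    """Default-condition SUV phantom cohort shared by read-only tests."""
    cfg = PhantomConfig.suv_default()
    return cfg, generate_cohort(cfg, 12, seed=101)
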