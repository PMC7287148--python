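import numpy as np
import pytest

from hotspot_overlap import BoundingBox, ScalarVolume, VoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_core_rim_pet(
    shape=(30, 30, 20),
    spacing=(2.0, 2.0, 3.0),
    center=(30.0, 30.0, 30.0),
    rim_radius=10.0,
    core_radius=4.0,
    suv_rim=8.0,
    suv_core=20.0,
    background=0.0,
):
    """Analytic two-compartment lesion on a plain background."""
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    data = np.full(shape, background, dtype=float)
    data[d2 <= rim_radius**2] = suv_rim
    data[d2 <= core_radius**2] = suv_core
    return ScalarVolume(data, spacing, (0, 0, 0), "PET")


@pytest.fixture
def core_rim_pet():
    return make_core_rim_pet()


@pytest.fixture
def lesion_box():
    return BoundingBox((10.0, 10.0, 12.0), (50.0, 50.0, 48.0))


def random_mask(rng, shape=(6, 6, 6), p=0.4, spacing=(2.0, 2.0, 3.0), label="m"):
    return VoiMask(rng.random(shape) < p, spacing, (0, 0, 0), label=label)
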