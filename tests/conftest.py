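import numpy as np
import pytest

from flowbold import AcquisitionSpec, NoiseSpec, Roi
from flowbold.simulate import RegionLayout


@pytest.fixture(scope="session")
def task_acq() -> AcquisitionSpec:
    """The 21-s block / TR 3 s / 84-timepoint task design."""
    return AcquisitionSpec.task()


@pytest.fixture(scope="session")
def rest_acq() -> AcquisitionSpec:
    return AcquisitionSpec.rest()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150929)


@pytest.fixture
def small_layout() -> RegionLayout:
    """One compact 12-voxel region on an 8x8x4 grid."""
    return RegionLayout.single_region(n_voxels=12, sign=1, amplitude_pct=1.0)


def roi_of(layout: RegionLayout, name: str = "roi") -> Roi:
    return Roi(name, layout.regions[name].voxels)


@pytest.fixture(scope="session")
def quiet_noise() -> NoiseSpec:
    return NoiseSpec(white_sd_pct=0.5, ar1=0.3)
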