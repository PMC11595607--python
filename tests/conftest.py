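import numpy as np
import pytest

from spherequant import Calibration, GrayImage, PipelineConfig


@pytest.fixture
def unit_cal() -> Calibration:
    """1 um/px calibration: pixel areas equal um^2 areas."""
    return Calibration(magnification="10x", microns_per_pixel=1.0)


@pytest.fixture
def default_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240229)


def make_image(pixels) -> GrayImage:
    return GrayImage(pixels=np.asarray(pixels, dtype=float))
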