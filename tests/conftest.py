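import numpy as np
import pytest

from chromacal import (
    CameraModel,
    CaptureSettings,
    DEFAULT_GRID,
    Reflectance,
    make_card_scene,
)
from chromacal.cards import classic24_reflectances, reference_card_from_reflectances
from chromacal.standards import gaussian_camera_sensitivity, led_flash


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def classic_bank():
    return classic24_reflectances()


@pytest.fixture(scope="session")
def classic_card(classic_bank):
    return reference_card_from_reflectances("classic24", classic_bank)


@pytest.fixture(scope="session")
def classic_scene(classic_bank):
    return make_card_scene(classic_bank, (4, 6))


@pytest.fixture(scope="session")
def phone_a():
    return CameraModel(
        gaussian_camera_sensitivity(), led_flash(), device_id="phoneA"
    )


@pytest.fixture
def flat_reflectance(grid):
    def _make(level: float) -> Reflectance:
        return Reflectance(np.full(grid.n_bins, level), grid=grid)

    return _make
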