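import numpy as np
import pytest

from neuromech.sicm_sim import PipetteParams, make_phantom


@pytest.fixture
def pipette() -> PipetteParams:
    return PipetteParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    """16x16 phantom over 8x8 um with a short process."""
    return make_phantom(
        16, 16, 8.0, soma_axes_um=(3.0, 2.5), process_length_um=2.5,
        soma_center_um=(2.5, 4.0),
    )
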