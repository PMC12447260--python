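import numpy as np
import pytest

from steamdiff import (
    APOPTOTIC_PRESET,
    CONTROL_PRESET,
    NoiseSpec,
    default_protocol,
    generate_dataset,
)


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def control_clean(protocol):
    """Noiseless control-preset dataset on the full STEAM grid."""
    return generate_dataset(CONTROL_PRESET, protocol, NoiseSpec(snr=np.inf))


@pytest.fixture(scope="session")
def apoptotic_clean(protocol):
    """Noiseless apoptotic-preset dataset on the full STEAM grid."""
    return generate_dataset(APOPTOTIC_PRESET, protocol, NoiseSpec(snr=np.inf))
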