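import numpy as np
import pytest

from eegrc.simulate import DEFAULT_CHANNELS, ClassModel


def class_model(label, k, line_amp=0.0, noise_var=1.0):
    """Model with the same reflection signature on every montage channel."""
    return ClassModel.from_reflection(
        label, {ch: list(k) for ch in DEFAULT_CHANNELS},
        noise_var=noise_var, line_amp=line_amp,
    )


@pytest.fixture(scope="session")
def separable_pair():
    """Two task models with opposite reflection signatures (easy pair)."""
    return class_model("M", [0.6, -0.4]), class_model("C", [-0.6, 0.4])


@pytest.fixture(scope="session")
def identical_pair():
    """Two task models with the same dynamics (no class signal)."""
    return class_model("M", [0.6, -0.4]), class_model("C", [0.6, -0.4])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
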