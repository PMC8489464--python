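import numpy as np
import pytest

from cardiomark import reference


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sigma4_run():
    """The reference short-axis training run (heatmap sigma 4 px), shared by
    the end-to-end checks so the detector is trained once per session."""
    return reference.run_reference_training(seed=42, sigma=4.0)
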