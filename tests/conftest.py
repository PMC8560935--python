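import numpy as np
import pytest

from marshres import ModelParams


@pytest.fixture
def worked_params():
    """Parameterization used for the worked closed-form examples."""
    return ModelParams(g=1.0, a=1.0, h=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
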