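import numpy as np
import pytest

from oxex import LabelDistribution


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def gamma_label_initial():
    """Measured initial label distribution on the gamma-phosphoryl of ATP."""
    return LabelDistribution(57.0, 17.0, 2.0, 24.0)
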