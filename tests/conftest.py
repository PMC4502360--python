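import numpy as np
import pytest

from timeopt import gains


@pytest.fixture(scope="session")
def canonical():
    return {
        "no_risk": gains.make_no_risk(),
        "step": gains.make_step(),
        "risk_after": gains.make_risk_after(),
        "risk_before": gains.make_risk_before(),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20230714)
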