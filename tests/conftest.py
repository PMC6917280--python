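import numpy as np
import pytest

from idmrisk import RateParameters, ScaledBetaDistribution


@pytest.fixture
def params():
    return RateParameters()


@pytest.fixture
def base_dist():
    return ScaledBetaDistribution.base_case()


@pytest.fixture
def intervention_dist():
    return ScaledBetaDistribution.intervention()


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
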