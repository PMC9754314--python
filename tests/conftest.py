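import numpy as np
import pytest

from dyadnorm import agents, synthetic_data as synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_participant():
    return synth.VirtualParticipant(id="p0", base_weight=1.0)


@pytest.fixture
def asch_under():
    return agents.AgentConfig(partner_type="asch", initial_weight=0.61)


@pytest.fixture
def sherif_under():
    return agents.AgentConfig(partner_type="sherif", initial_weight=0.61)


@pytest.fixture
def lab_schedule():
    return synth.make_schedule("lab", seed=7)


@pytest.fixture
def fmri_schedule():
    return synth.make_schedule("fmri", seed=7)
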