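import numpy as np
import pytest

from rewardtap.hgf import HGFParams
from rewardtap.simulate import AgentConfig, recovery_config, simulate_agent_session


@pytest.fixture(scope="session")
def default_session():
    """One deterministic session from the cohort-default agent."""
    return simulate_agent_session(AgentConfig(seed=42))


@pytest.fixture(scope="session")
def recovery_sessions():
    """A small batch of information-rich sessions for recovery-style tests."""
    return [
        (recovery_config(seed=s), simulate_agent_session(recovery_config(seed=s)))
        for s in range(10)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hgf_params():
    return HGFParams()
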