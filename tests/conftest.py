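import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

MU = 1.25e-8  # per-generation recurrent mutation rate used across experiments


@pytest.fixture(scope="session")
def neutral_bidirectional():
    from fastwf import MutationSelectionModel

    return MutationSelectionModel(mu_fwd=MU, mu_back=MU)


@pytest.fixture(scope="session")
def neutral_oneway():
    from fastwf import MutationSelectionModel

    return MutationSelectionModel(mu_fwd=MU)
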