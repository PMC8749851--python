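import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stridesense as ss
from stridesense.simulate import ArtefactConfig, NoiseConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

EFFORTS = ("60", "80", "100")


@pytest.fixture(scope="session")
def clean_sprints():
    """Noise- and artefact-free sprints per effort: the pure-kinematics oracle."""
    return {
        eff: ss.simulate(
            ss.make_profile(eff),
            seed=10 + i,
            artefact=ArtefactConfig(enabled=False),
            noise=NoiseConfig(acc_sigma=0.0, gyr_sigma=0.0),
        )
        for i, eff in enumerate(EFFORTS)
    }


@pytest.fixture(scope="session")
def default_sprint():
    """One 100%-effort sprint with default touch-down artefacts and noise."""
    return ss.simulate(ss.make_profile("100"), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
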