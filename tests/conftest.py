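import numpy as np
import pytest

from tfrtrace.cassette import RecombinationModel
from tfrtrace.config import Donor, MarrowMix, ScenarioConfig


@pytest.fixture
def uniform10():
    return np.full(10, 0.1)


@pytest.fixture
def three_donor_mix():
    """1:1:1 marrow mix where one donor carries the Confetti cassette."""
    return MarrowMix(
        donors=(
            Donor("driver_dtr", 1.0, autoreactive_driver=True, dtx_ablatable=True),
            Donor("foxp3_dtr", 1.0, dtx_ablatable=True),
            Donor("foxp3_confetti", 1.0, confetti_labelable=True),
        ),
        host_fraction=0.0,
    )


@pytest.fixture
def confetti_only_mix():
    return MarrowMix(donors=(Donor("foxp3_confetti", 1.0, confetti_labelable=True),))


def make_config(mix, **overrides):
    defaults = dict(
        marrow=mix,
        recombination=RecombinationModel(0.6),
        seed=1234,
        n_mice=1,
        pool_size=2000,
        n_follicles=10,
        founders_per_follicle=10,
        tzone_founders=40,
        homeostatic_target=100,
        observation_days=(10,),
        cells_sampled_per_follicle=30,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


@pytest.fixture
def config_factory():
    return make_config
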