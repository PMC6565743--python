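import numpy as np
import pytest

from tvrpipe.config import PipelineConfig
from tvrpipe.synth import BehaviorConfig, NeuronSpec, generate_behavior, generate_fluorescence


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def closed_loop_session():
    """Small closed-loop session with one neuron per functional category."""
    behavior = generate_behavior(BehaviorConfig(n_trials=12, rng_seed=11))
    rng = np.random.default_rng(11)
    specs = [NeuronSpec.make(c, rng) for c in ("rest", "run", "touch", "integrative")]
    return generate_fluorescence(behavior, specs, rng_seed=12)


@pytest.fixture(scope="session")
def perturbed_session():
    behavior = generate_behavior(
        BehaviorConfig(n_trials=15, condition="perturbed_closed_loop", rng_seed=21)
    )
    rng = np.random.default_rng(21)
    specs = [NeuronSpec.make("run", rng), NeuronSpec.make("touch", rng)]
    return generate_fluorescence(behavior, specs, rng_seed=22)


@pytest.fixture(scope="session")
def open_loop_session():
    behavior = generate_behavior(BehaviorConfig(n_trials=15, condition="open_loop", rng_seed=31))
    rng = np.random.default_rng(31)
    specs = [NeuronSpec.make(c, rng) for c in ("rest", "run", "touch", "integrative")]
    return generate_fluorescence(behavior, specs, rng_seed=32)
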