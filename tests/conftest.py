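import numpy as np
import pytest

from periax import (
    KDynParams,
    MorphoParams,
    PulseTrain,
    SimulationConfig,
    build_morphology,
)


@pytest.fixture(scope="session")
def morph():
    return build_morphology()


@pytest.fixture(scope="session")
def small_cfg():
    """A short-axon configuration for fast engine tests."""
    return SimulationConfig(
        morpho=MorphoParams(n_nodes=7),
        pulses=PulseTrain(duration=0.5, amplitude=0.06),
        electrode_node=3,
        neuron_offset=(10.0, 10.0),
        settle_ms=100.0,
    )


@pytest.fixture(scope="session")
def small_rec(small_cfg):
    from periax import run_simulation

    return run_simulation(small_cfg)
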