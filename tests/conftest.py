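import numpy as np
import pytest

from swimddm import (DDMParameters, SearchSpace, SimulationConfig,
                     StimulusProtocol, build_library, simulate)


@pytest.fixture(scope="session")
def space():
    return SearchSpace()


@pytest.fixture(scope="session")
def single_coherence_protocol():
    return StimulusProtocol(mode="continuous", coherence_levels=(1.0,))


@pytest.fixture(scope="session")
def example_params():
    """A hand-picked parameter set well inside the accepted regime."""
    return DDMParameters(sigma=1.2, mu=2.0, lam=3.0, r=0.2, delta=0.3)


@pytest.fixture(scope="session")
def example_series(example_params):
    protocol = StimulusProtocol(mode="continuous")
    config = SimulationConfig(seed=42, duration=900.0)
    return simulate(example_params, protocol, config)


@pytest.fixture(scope="session")
def library900(space):
    """Accepted-model library at the standard conditions (900 s of
    stimulation per coherence); shared by the statistical suites."""
    return build_library(space, n_models=20, duration=900.0, seed=0)


@pytest.fixture(scope="session")
def small_library(space):
    """A few accepted models at a short simulation duration (kept small:
    it feeds several structural tests, not the statistical suites)."""
    return build_library(space, n_models=4, duration=300.0, seed=11)
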