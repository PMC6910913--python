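import numpy as np
import pytest

from risclip import PipelineConfig, SimulationParams, simulate_reference


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_reference():
    """A tiny deterministic reference shared across tests."""
    params = SimulationParams(
        seed=11, n_transcripts=8, transcript_length_range=(400, 800),
        n_hairpins=5, n_contaminants=3,
    )
    return simulate_reference(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
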