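import numpy as np
import pytest

from sighsort import SynthParams, generate_population_trace


@pytest.fixture(scope="session")
def short_params() -> SynthParams:
    """A 10-minute synthetic slice recording with a handful of sighs."""
    return SynthParams(duration=600.0, seed=1)


@pytest.fixture(scope="session")
def short_recording(short_params):
    return generate_population_trace(short_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
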