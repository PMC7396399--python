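from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from petquant import (
    FrameSchedule,
    InputSpec,
    input_function_from_spec,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default_brain()


@pytest.fixture(scope="session")
def input_fn():
    """Default noiseless metabolite-corrected input function."""
    return input_function_from_spec(InputSpec())


@pytest.fixture(scope="session")
def data_dir():
    return DATA_DIR


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
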