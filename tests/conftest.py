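import random

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return random.Random(20240701)


@pytest.fixture
def small_reportset(rng):
    from oracles import random_reportset

    return random_reportset(rng, 120)
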