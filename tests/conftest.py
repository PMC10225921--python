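import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

from dyadlink import Lexicon, parse_transcript, preprocess


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lexicon():
    return Lexicon.default()


@pytest.fixture
def small_transcript():
    text = (
        "PATIENT: I was like, um, fine.\n"
        "THERAPIST: let's talk about that\n"
        "PATIENT: when I talk to you it's hard\n"
    )
    return preprocess(parse_transcript(text, dyad_id="d0"))
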