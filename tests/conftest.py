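import numpy as np
import pytest

from mitohap.simulate import generate_reference

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@pytest.fixture(scope="session")
def reference():
    return generate_reference()


def transition_of(base: str) -> str:
    return TRANSITION[base]
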