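import numpy as np
import pytest

import qualnet as qn


@pytest.fixture(scope="session")
def chondro():
    return qn.chondrocyte_model()


@pytest.fixture(scope="session")
def chondro_attractors(chondro):
    """Wild-type attractors from a moderate restart budget, shared by tests."""
    return qn.find_attractors(chondro, 4000, seed=11)


@pytest.fixture()
def toggle():
    return qn.make_toggle_switch()


@pytest.fixture()
def cascade():
    return qn.make_cascade(5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


TOGGLE_TEXT = """\
#saturation 1
#node A marker=sox9
#node B marker=runx2
B\tA\t-\t2\tslow\t# mutual repression
A\tB\t-\t2\tslow\t# mutual repression
"""


@pytest.fixture()
def toggle_text():
    return TOGGLE_TEXT
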