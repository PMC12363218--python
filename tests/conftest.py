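import pytest

from maskerp import images
from maskerp.design import build_trial_list, pseudorandomize


@pytest.fixture(scope="session")
def face_128():
    return images.synth_face(7, size=128)


@pytest.fixture(scope="session")
def oval_128():
    return images.default_oval(128)


@pytest.fixture(scope="session")
def small_plan():
    """One trial per condition cell times 4 exemplars (24 trials)."""
    return pseudorandomize(build_trial_list(4, 1), seed=0)
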