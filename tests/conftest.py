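import pytest
from hypothesis import settings

from mtakit.synthetic_cohort import make_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_cohort():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def paper_like_cohort():
    return make_fixture("paper_like")


@pytest.fixture(scope="session")
def noise_free_cohort():
    return make_fixture("noise_free")
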