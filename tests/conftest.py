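import pytest

from fseof import ScanConfig, make_linear_toy, make_redundant_toy
from fseof.toys import ToySpec, make_branched_toy, make_host_toy


@pytest.fixture
def t1():
    return make_linear_toy()


@pytest.fixture
def t3():
    return make_redundant_toy()


@pytest.fixture
def host():
    return make_host_toy()


@pytest.fixture
def t2_factory():
    def make(seed=0, **kw):
        return make_branched_toy(ToySpec(seed=seed, **kw))

    return make


@pytest.fixture
def t1_config():
    return ScanConfig(biomass_reaction_id="R_bio", target_reaction_id="EX_p")
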