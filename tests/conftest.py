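import numpy as np
import pytest

import cafescreen as cs


@pytest.fixture(scope="session")
def menu():
    return cs.load_default_menu()


@pytest.fixture(scope="session")
def protocol():
    return cs.default_protocol()


@pytest.fixture(scope="session")
def script(menu, protocol):
    return cs.generate_script(menu, protocol, seed=3)


@pytest.fixture
def perfect_responses(script):
    return [cs.ResponseSet.perfect(lv) for lv in script.levels]


@pytest.fixture
def perfect_log(script, perfect_responses):
    return cs.run_scripted_session(script, perfect_responses)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
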