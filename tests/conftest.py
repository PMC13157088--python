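import pytest

from redoxpair import fixtures


@pytest.fixture(scope="session")
def three_distance_structure():
    return fixtures.make_three_distance_fixture()


@pytest.fixture(scope="session")
def disulphide_structure():
    return fixtures.make_disulphide_structure(seed=0)


@pytest.fixture(scope="session")
def strong_training_set():
    return fixtures.make_training_set(n_pos=20, n_neg=20, effect_profile="strong", seed=1)
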