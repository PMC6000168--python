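import pytest

from zwlogic import build_chicken_model, genotype_inputs, initial_state


@pytest.fixture(scope="session")
def chicken():
    return build_chicken_model()


@pytest.fixture
def zz_inputs():
    return genotype_inputs("ZZ")


@pytest.fixture
def zw_inputs():
    return genotype_inputs("ZW")


@pytest.fixture
def zz_initial():
    return initial_state("ZZ")


@pytest.fixture
def zw_initial():
    return initial_state("ZW")


#: Free-component vectors of the two differentiated fates (inputs excluded).
TESTIS_VECTOR = {"DMRT1": 2, "HEMGN": 0, "SOX9": 1, "FOXL2": 0,
                 "AROMATASE": 0, "OESTROGEN": 0}
OVARY_VECTOR = {"DMRT1": 0, "HEMGN": 0, "SOX9": 0, "FOXL2": 1,
                "AROMATASE": 1, "OESTROGEN": 1}


def full_state(inputs, free):
    return {**inputs, **free}
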