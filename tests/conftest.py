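import pytest

from tdmd import MatureMiRNA, sequences


@pytest.fixture(scope="session")
def mir30c():
    return MatureMiRNA("mmu-miR-30c-5p", sequences.MIR30C)


@pytest.fixture(scope="session")
def mir30b():
    return MatureMiRNA("mmu-miR-30b-5p", sequences.MIR30B)


@pytest.fixture(scope="session")
def mir30_panel():
    return [MatureMiRNA(name, seq) for name, seq in sequences.MIR30_FAMILY.items()]


@pytest.fixture(scope="session")
def serpine1_mre():
    _, _, seq = sequences.mre_site()
    return seq
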