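import pytest

from nodmet.peptide import BRITACIDIN_A, GRAMICIDIN_A, TYROCIDINE_A


@pytest.fixture
def britacidin():
    return BRITACIDIN_A


@pytest.fixture
def gramicidin():
    return GRAMICIDIN_A


@pytest.fixture
def tyrocidine():
    return TYROCIDINE_A


@pytest.fixture
def five_printed_ions():
    """The five co-eluting MS1 ions reported for britacidin A: measured
    m/z with their charge states."""
    return [
        (1022.0960, 2),  # [M+2H]2+
        (1033.0848, 2),  # [M+H+Na]2+
        (1044.0746, 2),  # [M+2Na]2+
        (2043.1830, 1),  # [M+H]+
        (2065.1664, 1),  # [M+Na]+
    ]
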