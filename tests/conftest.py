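import pytest

from biosurfkit.chem import LipopeptideSpecies


@pytest.fixture
def c15() -> LipopeptideSpecies:
    """The C15 beta-hydroxy acyl-heptapeptide (cyclic surfactin scaffold)."""
    return LipopeptideSpecies.surfactin(15)


@pytest.fixture
def homologue_carbons():
    return [13, 14, 15, 16]
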