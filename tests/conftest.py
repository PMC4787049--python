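import warnings

import pytest

warnings.filterwarnings("ignore", category=DeprecationWarning)


@pytest.fixture(scope="session")
def helix_structure():
    from gemprokit.fixtures import make_helix_pdb
    from gemprokit.structures import parse_pdb

    return parse_pdb(make_helix_pdb(12), "helix12")


@pytest.fixture(scope="session")
def two_mutation_fixture():
    """(StructureRecord, MutantTruth) for the two-point-mutation crystal."""
    from gemprokit.fixtures import make_fig_style_two_mutation_pdb
    from gemprokit.structures import parse_pdb

    text, truth = make_fig_style_two_mutation_pdb(seed=0)
    return parse_pdb(text, "mutant"), truth


@pytest.fixture(scope="session")
def toy_model():
    from gemprokit.fixtures import make_toy_model

    return make_toy_model(n_rxn=10, seed=3)
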