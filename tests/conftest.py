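import pytest

from fragrank import parse_smiles


@pytest.fixture(scope="session")
def benzene():
    return parse_smiles("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def quinoline():
    return parse_smiles("c1ccc2ncccc2c1", "quinoline")


@pytest.fixture(scope="session")
def isoquinoline():
    return parse_smiles("c1ccc2cnccc2c1", "isoquinoline")


@pytest.fixture(scope="session")
def benzimidazole():
    return parse_smiles("c1ccc2[nH]cnc2c1", "benzimidazole")


@pytest.fixture(scope="session")
def toluene():
    return parse_smiles("Cc1ccccc1", "toluene")


@pytest.fixture(scope="session")
def biphenyl():
    return parse_smiles("c1ccc(-c2ccccc2)cc1", "biphenyl")


@pytest.fixture(scope="session")
def table4_metrics():
    """The three-ligand isophthalamide comparison set: experimental IC50s
    (nM; one printed range) and docked fragment energies (kcal/mol)."""
    return {
        "ic50": {"1W51": 500.0, "2P83": 11.0, "3L58": (15.0, 80.0)},
        "be": {"1W51": -10.55, "2P83": -10.96, "3L58": -11.84},
        "hac": 28,
        "mw": 374.2,
    }
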