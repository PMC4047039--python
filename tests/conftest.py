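import pytest

from gutpep.biodb import database_from_peptides
from gutpep.digestion import builtin_rulesets


@pytest.fixture(scope="session")
def trypsin():
    return builtin_rulesets()["trypsin"]


@pytest.fixture(scope="session")
def chymotrypsin_high():
    return builtin_rulesets()["chymotrypsin_high"]


@pytest.fixture()
def tiny_db():
    """Small single- and multi-activity reference set used across modules."""
    return database_from_peptides(
        [("VPP", [2]), ("IPP", [2]), ("AA", [2]), ("HL", [2, 6]), ("AAK", [4])]
    )
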