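import pytest

from qsarml import datamodel as dm
from qsarml.descriptor_ontology import load_default_ontology
from qsarml.descriptor_providers import (BUILTIN_PROVIDER_NAME,
                                         BUILTIN_PROVIDER_VERSION,
                                         default_registry)
from qsarml.fixtures import pool_molecules


@pytest.fixture(scope="session")
def ontology():
    return load_default_ontology()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def pool():
    """(name, smiles, mol) triples of the bundled molecule pool."""
    return pool_molecules()


def build_tiny_dataset() -> dm.Dataset:
    """A small consistent dataset: 2 structures, 1 descriptor (+result),
    1 response unit (+responses). Built only through the add_* helpers,
    so it must validate clean."""
    d = dm.new_dataset(dm.Metadata(authors=["T. Author"], license="CC0-1.0",
                                   description="tiny test dataset"))
    res = d.add_resource("mols.smi", "a" * 64, "SHA-256", "SMILES")
    s1 = d.add_structure(res, 0, "InChI=1S/CH4/h1H4")
    s2 = d.add_structure(res, 1, "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3")
    prov = d.add_provider(BUILTIN_PROVIDER_NAME, BUILTIN_PROVIDER_VERSION)
    desc = d.add_descriptor("qsarml:heavyAtomCount", prov)
    unit = d.add_response_unit("pIC50", "neg log IC50")
    d.add_response(s1, unit, 5.5)
    d.add_response(s2, unit, 6.25)
    d.add_result(desc, s1, [("value", 1.0)])
    d.add_result(desc, s2, [("value", 3.0)])
    return d


@pytest.fixture
def tiny_dataset():
    return build_tiny_dataset()
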