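"""Built-in descriptor panel and the provider registry contract."""

import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from qsarml.datamodel import Descriptor, Parameter
from qsarml.descriptor_providers import (BUILTIN_PROVIDER_NAME,
                                         BUILTIN_PROVIDER_VERSION,
                                         ProviderContract, ProviderRegistry,
                                         builtin_contract, calculate,
                                         default_registry)
from qsarml.errors import (CalculationError, ParameterError,
                           ProviderRegistrationError)

PROVIDER = builtin_contract().as_provider("provider-0")


def run_one(ontology_id, smiles, params=(), registry=None):
    registry = registry or default_registry()
    desc = Descriptor("descriptor-0", ontology_id, "provider-0", list(params))
    mol = Chem.MolFromSmiles(smiles) if smiles is not None else None
    [result] = calculate(registry, desc, PROVIDER, [("structure-0", mol)])
    return result.values


class TestPanel:
    @pytest.mark.parametrize("smiles, expected", [("C", 1), ("CCO", 3), ("c1ccccc1", 6)])
    def test_heavy_atom_count(self, smiles, expected):
        assert run_one("qsarml:heavyAtomCount", smiles) == [("value", expected)]

    @pytest.mark.parametrize("smiles, expected", [("C", 0), ("CCO", 2), ("c1ccccc1", 6)])
    def test_bond_count_excludes_hydrogens(self, smiles, expected):
        assert run_one("qsarml:bondCount", smiles) == [("value", expected)]

    def test_molecular_weight_from_bundled_table(self):
        [(_, mw)] = run_one("qsarml:molecularWeight", "C")
        assert mw == pytest.approx(16.043, abs=1e-3)  # 12.011 + 4 x 1.008

    @pytest.mark.parametrize("element, expected", [("O", 1), ("C", 2), ("H", 6), ("N", 0)])
    def test_element_count(self, element, expected):
        params = [Parameter("element", element, "string")]
        assert run_one("qsarml:elementCount", "CCO", params) == [("value", expected)]

    def test_hbd_and_hba(self):
        # paracetamol: one N-H and one O-H donor; one N + two O acceptors
        smiles = "CC(=O)Nc1ccc(O)cc1"
        assert run_one("qsarml:hbdCount", smiles) == [("value", 2)]
        assert run_one("qsarml:hbaCount", smiles) == [("value", 3)]

    @pytest.mark.parametrize("smiles, smarts, expected", [
        ("c1ccccc1", "[#6]", 6),
        ("CC(=O)Oc1ccccc1C(=O)O", "[CX3](=O)[OX2H1]", 1),  # one free acid group
        ("NCCc1ccc(O)c(O)c1", "c[OH]", 2),                 # catechol hydroxyls
        ("C1CCCCC1", "C1CCCCC1", 1),                       # ring matched as one atom set
    ])
    def test_smarts_fragment_count_unique_atom_sets(self, smiles, smarts, expected):
        params = [Parameter("smarts", smarts, "string")]
        assert run_one("qsarml:smartsFragmentCount", smiles, params) == [("value", expected)]

    def test_element_profile_multivalue(self):
        assert run_one("qsarml:elementProfile", "NCC(=O)O") == \
            [("nC", 2), ("nN", 1), ("nO", 2)]


class TestOracleEquivalence:
    """Counting descriptors must agree with a brute-force enumeration of
    the parsed atom/bond lists, done here by an independent code path."""

    def test_counts_match_brute_force(self, pool):
        for name, smiles, mol in pool:
            atoms = list(mol.GetAtoms())
            heavy = sum(1 for a in atoms if a.GetAtomicNum() != 1)
            bonds = sum(1 for b in mol.GetBonds()
                        if 1 not in (b.GetBeginAtom().GetAtomicNum(),
                                     b.GetEndAtom().GetAtomicNum()))
            assert run_one("qsarml:heavyAtomCount", smiles) == [("value", heavy)], name
            assert run_one("qsarml:bondCount", smiles) == [("value", bonds)], name
            profile = run_one("qsarml:elementProfile", smiles)
            for (label, got), z in zip(profile, (6, 7, 8)):
                assert got == sum(1 for a in atoms if a.GetAtomicNum() == z), name
            for symbol in ("C", "N", "O", "S"):
                expected = sum(1 for a in atoms if a.GetSymbol() == symbol)
                params = [Parameter("element", symbol, "string")]
                assert run_one("qsarml:elementCount", smiles, params) == \
                    [("value", expected)], name

    def test_hba_equals_n_plus_o(self, pool):
        for name, smiles, _ in pool:
            [(_, hba)] = run_one("qsarml:hbaCount", smiles)
            [(_, n)] = run_one("qsarml:elementCount", smiles,
                               [Parameter("element", "N", "string")])
            [(_, o)] = run_one("qsarml:elementCount", smiles,
                               [Parameter("element", "O", "string")])
            assert hba == n + o, name

    def test_smarts_carbon_equals_element_count(self, pool):
        for name, smiles, _ in pool:
            [(_, by_smarts)] = run_one("qsarml:smartsFragmentCount", smiles,
                                       [Parameter("smarts", "[#6]", "string")])
            [(_, by_count)] = run_one("qsarml:elementCount", smiles,
                                      [Parameter("element", "C", "string")])
            assert by_smarts == by_count, name


class TestBatchSemantics:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_determinism_and_order_equivariance(self, seed, pool):
        import random
        rng = random.Random(seed)
        chosen = rng.sample(pool, rng.randint(1, 8))
        structures = [(f"structure-{i}", mol) for i, (_, _, mol) in enumerate(chosen)]
        registry = default_registry()
        desc = Descriptor("descriptor-0", "qsarml:elementProfile", "provider-0")
        first = calculate(registry, desc, PROVIDER, structures)
        second = calculate(registry, desc, PROVIDER, structures)
        assert first == second
        perm = list(range(len(structures)))
        rng.shuffle(perm)
        permuted = calculate(registry, desc, PROVIDER, [structures[i] for i in perm])
        assert permuted == [first[i] for i in perm]

    def test_unparseable_molecule_yields_missing_markers(self):
        values = run_one("qsarml:elementProfile", None)
        assert values == [("nC", None), ("nN", None), ("nO", None)]

    def test_element_outside_weight_table_fails_per_structure(self):
        # tin is not in the bundled table: missing marker, not an abort
        assert run_one("qsarml:molecularWeight", "[SnH4]") == [("value", None)]


class TestRegistry:
    def test_duplicate_registration_rejected(self):
        registry = default_registry()
        with pytest.raises(ProviderRegistrationError):
            registry.register(builtin_contract())

    def test_multiple_providers_listed_sorted(self):
        registry = default_registry()
        other = ProviderContract("acme-descriptors", "2.1", "ACME",
                                 dict(builtin_contract().implementations))
        registry.register(other)
        names = [c.name for c in registry.list_implementations("qsarml:heavyAtomCount")]
        assert names == ["acme-descriptors", BUILTIN_PROVIDER_NAME]

    def test_unimplemented_id_empty(self, registry):
        assert registry.list_implementations("qsarml:gravitationalIndex") == []

    def test_builtin_version_is_recorded(self, registry):
        contract = registry.get(BUILTIN_PROVIDER_NAME, BUILTIN_PROVIDER_VERSION)
        assert contract is not None and "rdkit" in contract.version


class TestParameterValidation:
    def test_unregistered_provider(self):
        registry = ProviderRegistry()
        desc = Descriptor("descriptor-0", "qsarml:heavyAtomCount", "provider-0")
        with pytest.raises(CalculationError):
            calculate(registry, desc, PROVIDER, [])

    def test_unimplemented_descriptor(self, registry):
        desc = Descriptor("descriptor-0", "qsarml:logP", "provider-0")
        with pytest.raises(CalculationError):
            calculate(registry, desc, PROVIDER, [])

    @pytest.mark.parametrize("params", [
        [Parameter("elem", "O", "string")],            # unknown key
        [Parameter("element", 8, "integer")],          # wrong kind
        [],                                            # missing required
    ], ids=["unknown-key", "wrong-kind", "missing-required"])
    def test_rejected_parameters(self, params):
        with pytest.raises(ParameterError):
            run_one("qsarml:elementCount", "CCO", params)

    def test_invalid_smarts_rejected_before_computation(self):
        with pytest.raises(ParameterError):
            run_one("qsarml:smartsFragmentCount", "CCO",
                    [Parameter("smarts", "[#6", "string")])
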