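"""Matrix assembly, CSV export, overlap and merge algebra."""

import csv
import io
import random

import pytest

from qsarml import datamodel as dm
from qsarml.dataset_ops import (build_matrix, completeness, csv_bytes,
                                merge_datasets, overlap)
from qsarml.errors import InvalidDatasetError, MergeError
from qsarml.fixtures import pool_inchis, random_dataset
from qsarml.qsarml_io import qsarml_bytes, read_qsarml

from conftest import build_tiny_dataset


def profile_dataset():
    """2 structures x elementProfile (3 values) + 1 response unit."""
    d = dm.new_dataset(dm.Metadata(license="CC0-1.0"))
    res = d.add_resource("m.smi", "b" * 64)
    s1 = d.add_structure(res, 0, "InChI=1S/CH4/h1H4")
    s2 = d.add_structure(res, 1, "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3")
    prov = d.add_provider("qsarml-builtin", "1.0.0")
    desc = d.add_descriptor("qsarml:elementProfile", prov)
    unit = d.add_response_unit("pIC50")
    d.add_result(desc, s1, [("nC", 1.0), ("nN", 0.0), ("nO", 0.0)])
    d.add_result(desc, s2, [("nC", 2.0), ("nN", 0.0), ("nO", 1.0)])
    d.add_response(s1, unit, 5.5)
    d.add_response(s2, unit, 6.5)
    return d


def inchi_dataset(indices, response=None, descriptor_value=None):
    """Dataset over pool structures by index, with optional response and
    a shared heavyAtomCount descriptor column."""
    inchis = pool_inchis()
    d = dm.new_dataset(dm.Metadata(license="CC0-1.0"))
    res = d.add_resource("m.smi", "c" * 64)
    prov = d.add_provider("qsarml-builtin", "1.0.0")
    desc = d.add_descriptor("qsarml:heavyAtomCount", prov)
    unit = d.add_response_unit("pIC50")
    for i, idx in enumerate(indices):
        s = d.add_structure(res, i, inchis[idx])
        if response is not None:
            d.add_response(s, unit, response(idx))
        if descriptor_value is not None:
            d.add_result(desc, s, [("value", descriptor_value(idx))])
    return d


class TestMatrix:
    def test_dimensions_and_column_order(self, ontology):
        m = build_matrix(profile_dataset(), ontology=ontology)
        assert m.shape == (2, 4)
        assert m.column_labels == ["descriptor-0.nC", "descriptor-0.nN",
                                   "descriptor-0.nO", "pIC50"]
        assert m.cells[1] == [2.0, 0.0, 1.0, 6.5]

    def test_gap_becomes_missing_markers(self, ontology):
        d = profile_dataset()
        d.results.pop(1)
        m = build_matrix(d, ontology=ontology)
        assert m.cells[1] == [None, None, None, 6.5]

    def test_no_descriptors_width_is_response_count(self, ontology):
        d = profile_dataset()
        d.results.clear()
        d.descriptors.clear()
        m = build_matrix(d, ontology=ontology)
        assert m.shape == (2, 1) and m.column_labels == ["pIC50"]

    def test_declared_labels_used_when_no_results(self, ontology, registry):
        d = build_tiny_dataset()
        d.results.clear()
        prov = d.providers[0]
        d.add_descriptor("qsarml:elementProfile", prov)
        m = build_matrix(d, registry, ontology)
        assert m.column_labels[-4:-1] == ["descriptor-1.nC", "descriptor-1.nN",
                                          "descriptor-1.nO"]

    def test_refuses_inconsistent_dataset(self, ontology):
        d = profile_dataset()
        d.responses[0].structure_ref = "s99"
        with pytest.raises(InvalidDatasetError):
            build_matrix(d, ontology=ontology)

    def test_dataframe_view(self, ontology):
        df = build_matrix(profile_dataset(), ontology=ontology).to_dataframe()
        assert df.shape == (2, 4) and list(df.index) == ["structure-0", "structure-1"]


class TestCsv:
    def test_line_count_and_na(self, ontology):
        d = profile_dataset()
        d.results.pop(1)
        data = csv_bytes(build_matrix(d, ontology=ontology))
        lines = data.decode().split("\r\n")
        assert lines[-1] == "" and len(lines) == 4  # header + 2 rows + trailing CRLF
        assert "NA" in lines[2]

    def test_reparse_recovers_cells_exactly(self, ontology):
        d = random_dataset(2024)
        m = build_matrix(d, ontology=ontology)
        rows = list(csv.reader(io.StringIO(csv_bytes(m).decode())))
        assert rows[0] == ["structureId"] + m.column_labels
        for row, rid, cells in zip(rows[1:], m.row_ids, m.cells):
            assert row[0] == rid
            for text, value in zip(row[1:], cells):
                assert text == ("NA" if value is None else repr(value))
                if value is not None:
                    assert float(text) == value

    def test_label_with_comma_is_quoted(self, ontology):
        d = profile_dataset()
        d.response_units[0].name = "IC50, uM"
        data = csv_bytes(build_matrix(d, ontology=ontology)).decode()
        assert '"IC50, uM"' in data.split("\r\n")[0]

    def test_csv_stable_across_xml_round_trip(self, ontology):
        d = random_dataset(77)
        direct = csv_bytes(build_matrix(d, ontology=ontology))
        back = read_qsarml(qsarml_bytes(d, ontology), ontology)
        assert csv_bytes(build_matrix(back, ontology=ontology)) == direct


class TestCompleteness:
    def test_full_dataset(self):
        assert completeness(profile_dataset()) == 1.0

    def test_half_missing(self):
        d = build_tiny_dataset()
        d.results.pop(1)
        assert completeness(d) == 0.5

    def test_empty_conventions(self):
        assert completeness(dm.new_dataset()) == 1.0
        d = profile_dataset()
        d.structures.clear()
        d.responses.clear()
        d.results.clear()
        assert completeness(d) == 1.0


class TestOverlap:
    def test_reflexive(self):
        d = inchi_dataset([1, 2, 3])
        assert overlap(d, d) == {s.inchi for s in d.structures}

    def test_disjoint_and_symmetric_with_bound(self):
        rng = random.Random(5)
        for _ in range(20):
            a = random_dataset(rng.randrange(2**20))
            b = random_dataset(rng.randrange(2**20))
            ab, ba = overlap(a, b), overlap(b, a)
            assert ab == ba
            assert len(ab) <= min(len({s.inchi for s in a.structures}),
                                  len({s.inchi for s in b.structures}))
        assert overlap(inchi_dataset([0, 1]), inchi_dataset([2, 3])) == set()


class TestMerge:
    def test_self_merge_idempotent(self, ontology):
        d = inchi_dataset([4, 5, 6], response=float, descriptor_value=float)
        merged = merge_datasets(d, d, license="CC0-1.0")
        assert len(merged.structures) == len({s.inchi for s in d.structures})
        assert len(merged.descriptors) == 1
        assert len(merged.responses) == len(d.responses)
        assert dm.validate_dataset(merged, ontology) == []

    def test_disjoint_union_arithmetic(self, ontology):
        a = inchi_dataset([0, 1, 2], response=float, descriptor_value=float)
        b = inchi_dataset([3, 4], response=float, descriptor_value=float)
        merged = merge_datasets(a, b, license="CC0-1.0")
        assert len(merged.structures) == 5
        assert len(merged.descriptors) == 1  # same identity triple collapses
        assert len(merged.resources) == 2   # provenance of both inputs retained
        assert dm.validate_dataset(merged, ontology) == []

    def test_response_conflict_refused(self):
        a = inchi_dataset([0, 1], response=lambda i: 5.0)
        b = inchi_dataset([1, 2], response=lambda i: 6.0)
        with pytest.raises(MergeError, match="pIC50"):
            merge_datasets(a, b, license="CC0-1.0")

    def test_result_conflict_refused(self):
        a = inchi_dataset([0, 1], descriptor_value=lambda i: 1.0)
        b = inchi_dataset([1, 2], descriptor_value=lambda i: 2.0)
        with pytest.raises(MergeError, match="heavyAtomCount"):
            merge_datasets(a, b, license="CC0-1.0")

    def test_metadata_merge(self):
        a = inchi_dataset([0])
        b = inchi_dataset([1])
        a.metadata.authors = ["A", "B"]
        b.metadata.authors = ["B", "C"]
        merged = merge_datasets(a, b, license="MIT")
        assert merged.metadata.authors == ["A", "B", "C"]
        assert merged.metadata.license == "MIT"

    @staticmethod
    def merge_sets(d):
        structures = frozenset(s.inchi for s in d.structures)
        descriptors = frozenset(
            dm.descriptor_identity(x, d.provider_by_id(x.provider_ref))
            for x in d.descriptors)
        inchi_of = {s.id: s.inchi for s in d.structures}
        unit_of = {u.id: u.name for u in d.response_units}
        desc_of = {x.id: dm.descriptor_identity(x, d.provider_by_id(x.provider_ref))
                   for x in d.descriptors}
        responses = frozenset((inchi_of[r.structure_ref], unit_of[r.unit_ref], r.value)
                              for r in d.responses)
        results = frozenset((inchi_of[r.structure_ref], desc_of[r.descriptor_ref],
                             tuple(r.values)) for r in d.results)
        return structures, descriptors, responses, results

    def test_commutative_up_to_ordering(self, ontology):
        rng = random.Random(11)
        checked = 0
        for _ in range(40):
            a = random_dataset(rng.randrange(2**20))
            b = random_dataset(rng.randrange(2**20))
            try:
                ab = merge_datasets(a, b, license="CC0-1.0")
            except MergeError:
                with pytest.raises(MergeError):
                    merge_datasets(b, a, license="CC0-1.0")
                continue
            ba = merge_datasets(b, a, license="CC0-1.0")
            assert self.merge_sets(ab) == self.merge_sets(ba)
            assert dm.validate_dataset(ab, ontology) == []
            checked += 1
        assert checked >= 10  # most pairs should actually merge
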