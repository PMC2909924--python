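"""Dataset-level operations: matrix assembly, CSV export, overlap, merge.

The numeric view of a dataset is a :class:`DataMatrix` — one row per
structure, one column per descriptor value label (named
``descriptorId.valueLabel`` so multi-value descriptors stay
unambiguous), followed by one column per response unit. Absent results
and responses are explicit missing-markers, rendered ``NA`` in CSV.

Structure identity across datasets is the stored InChI string (not
resource identity): :func:`overlap` intersects InChIs and
:func:`merge_datasets` deduplicates structures by InChI, refusing —
rather than averaging — when two datasets disagree on a value for the
same structure.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import datamodel as dm
from .errors import InvalidDatasetError, MergeError
from .qsarml_io import _fmt_decimal

__all__ = [
    "DataMatrix",
    "build_matrix",
    "export_csv",
    "csv_bytes",
    "overlap",
    "merge_datasets",
    "completeness",
]

MISSING_TOKEN = "NA"


@dataclass
class DataMatrix:
    """Assembled numeric table: rows are structures, columns are
    descriptor value labels then response units."""

    row_ids: list[str]
    column_labels: list[str]
    cells: list[list[Optional[float]]]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_ids), len(self.column_labels))

    def to_dataframe(self) -> pd.DataFrame:
        """The matrix as a pandas DataFrame indexed by structure id
        (missing-markers become NaN)."""
        return pd.DataFrame(self.cells, index=self.row_ids, columns=self.column_labels,
                            dtype=float)


def _descriptor_labels(d: dm.Dataset, registry=None) -> dict[str, tuple[str, ...]]:
    """Value-label sequence per descriptor id.

    Taken from the descriptor's results when any exist (they are
    validated to agree); otherwise from the provider registry's declared
    labels; otherwise a single generic ``value`` column.
    """
    from_results: dict[str, tuple[str, ...]] = {}
    for res in d.results:
        from_results.setdefault(res.descriptor_ref, tuple(l for l, _ in res.values))
    labels: dict[str, tuple[str, ...]] = {}
    for desc in d.descriptors:
        if desc.id in from_results:
            labels[desc.id] = from_results[desc.id]
            continue
        declared = None
        if registry is not None:
            provider = d.provider_by_id(desc.provider_ref)
            contract = registry.get(provider.name, provider.version) if provider else None
            impl = contract.implementations.get(desc.ontology_id) if contract else None
            declared = impl.value_labels if impl else None
        labels[desc.id] = tuple(declared) if declared else ("value",)
    return labels


def build_matrix(d: dm.Dataset, registry=None, ontology=None) -> DataMatrix:
    """Concatenate descriptor values and responses into a data matrix.

    Rows follow structure-list order; descriptor columns are grouped by
    descriptor in descriptor-list order (values in declared label
    order); response columns come last in response-unit-list order. A
    structure with no result for a descriptor, or no response in a
    unit, gets missing-markers there. Refuses an inconsistent dataset.
    """
    violations = dm.validate_dataset(d, ontology)
    if violations:
        raise InvalidDatasetError(violations)

    labels = _descriptor_labels(d, registry)
    columns: list[str] = []
    for desc in d.descriptors:
        columns.extend(f"{desc.id}.{label}" for label in labels[desc.id])
    columns.extend(u.name for u in d.response_units)

    results_by_key = {(r.descriptor_ref, r.structure_ref): r for r in d.results}
    responses_by_key = {(r.structure_ref, r.unit_ref): r.value for r in d.responses}

    rows: list[list[Optional[float]]] = []
    for s in d.structures:
        row: list[Optional[float]] = []
        for desc in d.descriptors:
            res = results_by_key.get((desc.id, s.id))
            if res is None:
                row.extend([None] * len(labels[desc.id]))
            else:
                row.extend(v for _, v in res.values)
        for u in d.response_units:
            row.append(responses_by_key.get((s.id, u.id)))
        rows.append(row)

    return DataMatrix([s.id for s in d.structures], columns, rows)


def csv_bytes(m: DataMatrix) -> bytes:
    """RFC 4180 CSV rendering of a matrix (UTF-8, CRLF line endings).

    Header row is ``structureId`` plus the column labels; missing cells
    are ``NA``; decimals use shortest round-trip precision with ``.``
    as the decimal separator regardless of locale.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n")
    writer.writerow(["structureId"] + list(m.column_labels))
    for rid, row in zip(m.row_ids, m.cells):
        writer.writerow([rid] + [MISSING_TOKEN if v is None else _fmt_decimal(v)
                                 for v in row])
    return buf.getvalue().encode("utf-8")


def export_csv(m: DataMatrix, sink) -> None:
    """Write the CSV rendering of ``m`` to a path or binary file object."""
    data = csv_bytes(m)
    if isinstance(sink, (str, Path)):
        Path(sink).write_bytes(data)
    else:
        sink.write(data)


def overlap(a: dm.Dataset, b: dm.Dataset) -> set[str]:
    """InChIs present (as stored) in both datasets. Symmetric;
    ``overlap(d, d)`` is the set of d's distinct InChIs."""
    return {s.inchi for s in a.structures} & {s.inchi for s in b.structures}


def completeness(d: dm.Dataset, registry=None) -> float:
    """Fraction of descriptor cells that carry a value.

    Filled cells divided by ``|structures| x total descriptor value
    labels``; missing-markers inside stored results count as unfilled.
    By convention 1.0 when there are no descriptor cells at all (no
    descriptors or no structures).
    """
    labels = _descriptor_labels(d, registry)
    total = len(d.structures) * sum(len(v) for v in labels.values())
    if total == 0:
        return 1.0
    filled = sum(1 for r in d.results for _, v in r.values if v is not None)
    return filled / total


def _merge_metadata(a: dm.Metadata, b: dm.Metadata, license: str) -> dm.Metadata:
    authors = list(a.authors)
    authors.extend(x for x in b.authors if x not in authors)
    refs = list(a.references)
    refs.extend(r for r in b.references if r not in refs)
    if a.description == b.description:
        description = a.description
    else:
        description = "\n---\n".join(x for x in (a.description, b.description) if x)
    return dm.Metadata(authors=authors, license=license,
                       description=description, references=refs)


def merge_datasets(a: dm.Dataset, b: dm.Dataset, *, license: str) -> dm.Dataset:
    """Combine two datasets into one.

    Structures are deduplicated by InChI (first occurrence, in ``a``
    then ``b`` order, wins; the resources of both inputs are retained as
    provenance). Providers are unioned by (name, version), descriptors
    by their (ontology, provider, parameters) identity, responses and
    results by structure InChI. Two values for the same (InChI, unit) or
    (InChI, descriptor) that differ raise :class:`MergeError` naming the
    conflict — merging never averages. The combined dataset's license
    must be stated explicitly; authors and references are unioned.

    The output passes ``validate_dataset`` whenever both inputs do, and
    the merged structure/descriptor/result *sets* do not depend on
    argument order.
    """
    merged = dm.new_dataset(_merge_metadata(a.metadata, b.metadata, license))

    provider_key_to_id: dict[tuple[str, str], str] = {}
    descriptor_ident_to_id: dict[tuple, str] = {}
    inchi_to_id: dict[str, str] = {}
    unit_name_to_id: dict[str, str] = {}
    response_seen: dict[tuple[str, str], float] = {}
    result_seen: dict[tuple[str, str], list] = {}

    for src in (a, b):
        resource_map: dict[str, str] = {}
        for r in src.resources:
            new = merged.add_resource(r.location, r.checksum, r.checksum_algorithm,
                                      r.format)
            resource_map[r.id] = new.id

        structure_map: dict[str, str] = {}
        for s in src.structures:
            if s.inchi in inchi_to_id:
                structure_map[s.id] = inchi_to_id[s.inchi]
                continue
            new = merged.add_structure(resource_map[s.resource_ref],
                                       s.resource_index, s.inchi)
            inchi_to_id[s.inchi] = new.id
            structure_map[s.id] = new.id

        provider_map: dict[str, str] = {}
        for p in src.providers:
            key = (p.name, p.version)
            if key not in provider_key_to_id:
                new = merged.add_provider(p.name, p.version, p.vendor)
                provider_key_to_id[key] = new.id
            provider_map[p.id] = provider_key_to_id[key]

        descriptor_map: dict[str, str] = {}
        for desc in src.descriptors:
            ident = dm.descriptor_identity(desc, src.provider_by_id(desc.provider_ref))
            if ident not in descriptor_ident_to_id:
                new = merged.add_descriptor(desc.ontology_id,
                                            provider_map[desc.provider_ref],
                                            desc.parameters)
                descriptor_ident_to_id[ident] = new.id
            descriptor_map[desc.id] = descriptor_ident_to_id[ident]

        for u in src.response_units:
            if u.name not in unit_name_to_id:
                new = merged.add_response_unit(u.name, u.definition)
                unit_name_to_id[u.name] = new.id

        unit_map = {u.id: unit_name_to_id[u.name] for u in src.response_units}
        inchi_of = {s.id: s.inchi for s in src.structures}
        unit_name_of = {u.id: u.name for u in src.response_units}

        for resp in src.responses:
            key = (inchi_of[resp.structure_ref], unit_name_of[resp.unit_ref])
            if key in response_seen:
                if response_seen[key] != resp.value:
                    raise MergeError(
                        f"conflicting response values for structure {key[0]!r} "
                        f"in unit {key[1]!r}: {response_seen[key]!r} vs {resp.value!r}")
                continue
            response_seen[key] = resp.value
            merged.add_response(structure_map[resp.structure_ref],
                                unit_map[resp.unit_ref], resp.value)

        for res in src.results:
            key = (inchi_of[res.structure_ref], descriptor_map[res.descriptor_ref])
            if key in result_seen:
                if result_seen[key] != res.values:
                    desc = merged.descriptor_by_id(key[1])
                    raise MergeError(
                        f"conflicting descriptor values for structure {key[0]!r}, "
                        f"descriptor {desc.ontology_id!r}: "
                        f"{result_seen[key]!r} vs {res.values!r}")
                continue
            result_seen[key] = list(res.values)
            merged.add_result(descriptor_map[res.descriptor_ref],
                              structure_map[res.structure_ref], res.values)

    return merged
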