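"""Read and write datasets as QSAR-ML XML documents.

The document layout mirrors the dataset model: ``metadata``, then
``structureList`` (resources + structures), ``descriptorList``
(providers + descriptors), ``responseList`` (units + responses) and
``descriptorResultList``. Cross-references are serialized as id/idref
attributes; the shipped XML Schema (``data/qsarml.xsd``, namespace
``https://qsar-ml.dev/schema/1.0``) checks structure and syntax, while
reference *resolution* is checked by the data model after parsing.

Writing is deterministic: the same dataset always serializes to the
same bytes (UTF-8, mandatory XML declaration, fixed attribute order,
decimals rendered with shortest round-trip precision), so
``write(read(write(d)))`` is byte-identical to ``write(d)``.
The conventional file extension is ``.qsarml.xml``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Optional, Union

from lxml import etree

from . import datamodel as dm
from .errors import InvalidDatasetError, SchemaError

__all__ = [
    "NAMESPACE",
    "FORMAT_VERSION",
    "SchemaReport",
    "write_qsarml",
    "qsarml_bytes",
    "read_qsarml",
    "validate_schema",
]

NAMESPACE = "https://qsar-ml.dev/schema/1.0"
FORMAT_VERSION = "1.0"

_NSMAP = {None: NAMESPACE}


def _q(tag: str) -> str:
    return f"{{{NAMESPACE}}}{tag}"


_schema_cache: Optional[etree.XMLSchema] = None


def _schema() -> etree.XMLSchema:
    global _schema_cache
    if _schema_cache is None:
        data = importlib_resources.files("qsarml").joinpath("data/qsarml.xsd").read_bytes()
        _schema_cache = etree.XMLSchema(etree.fromstring(data))
    return _schema_cache


@dataclass
class SchemaReport:
    """Outcome of schema validation: ``valid`` iff ``messages`` is empty."""

    valid: bool
    messages: list[tuple[int, str]] = field(default_factory=list)


def _fmt_decimal(x: float) -> str:
    """Shortest decimal string that reparses to exactly the same float."""
    x = float(x)
    if not math.isfinite(x):
        raise ValueError(f"non-finite value {x!r} cannot be serialized")
    return repr(x)


def _fmt_parameter_value(p: dm.Parameter) -> str:
    if p.kind == "integer":
        return str(int(p.value))
    if p.kind == "decimal":
        return _fmt_decimal(float(p.value))
    return str(p.value)


def _parse_parameter_value(kind: str, raw: str) -> Union[str, int, float]:
    if kind == "integer":
        return int(raw)
    if kind == "decimal":
        return float(raw)
    return raw


def _dataset_to_element(d: dm.Dataset) -> etree._Element:
    root = etree.Element(_q("qsarml"), nsmap=_NSMAP)
    root.set("version", FORMAT_VERSION)

    meta = etree.SubElement(root, _q("metadata"))
    for author in d.metadata.authors:
        el = etree.SubElement(meta, _q("author"))
        el.text = author or None
    if d.metadata.license:
        etree.SubElement(meta, _q("license")).text = d.metadata.license
    if d.metadata.description:
        etree.SubElement(meta, _q("description")).text = d.metadata.description
    for ref in d.metadata.references:
        el = etree.SubElement(meta, _q("reference"))
        if ref.title:
            el.set("title", ref.title)
        if ref.identifier:
            el.set("identifier", ref.identifier)

    slist = etree.SubElement(root, _q("structureList"))
    for r in d.resources:
        el = etree.SubElement(slist, _q("resource"))
        el.set("id", r.id)
        el.set("location", r.location)
        el.set("checksum", r.checksum)
        el.set("checksumAlgorithm", r.checksum_algorithm)
        el.set("format", r.format)
    for s in d.structures:
        el = etree.SubElement(slist, _q("structure"))
        el.set("id", s.id)
        el.set("resourceRef", s.resource_ref)
        el.set("resourceIndex", str(s.resource_index))
        el.set("inchi", s.inchi)

    dlist = etree.SubElement(root, _q("descriptorList"))
    for p in d.providers:
        el = etree.SubElement(dlist, _q("descriptorProvider"))
        el.set("id", p.id)
        el.set("name", p.name)
        el.set("version", p.version)
        if p.vendor:
            el.set("vendor", p.vendor)
    for x in d.descriptors:
        el = etree.SubElement(dlist, _q("descriptor"))
        el.set("id", x.id)
        el.set("ontologyRef", x.ontology_id)
        el.set("providerRef", x.provider_ref)
        for par in x.parameters:
            pe = etree.SubElement(el, _q("parameter"))
            pe.set("key", par.key)
            pe.set("kind", par.kind)
            pe.set("value", _fmt_parameter_value(par))

    rlist = etree.SubElement(root, _q("responseList"))
    for u in d.response_units:
        el = etree.SubElement(rlist, _q("responseUnit"))
        el.set("id", u.id)
        el.set("name", u.name)
        if u.definition:
            el.set("definition", u.definition)
    for resp in d.responses:
        el = etree.SubElement(rlist, _q("response"))
        el.set("structureRef", resp.structure_ref)
        el.set("unitRef", resp.unit_ref)
        el.set("value", _fmt_decimal(resp.value))

    reslist = etree.SubElement(root, _q("descriptorResultList"))
    for res in d.results:
        el = etree.SubElement(reslist, _q("descriptorResult"))
        el.set("descriptorRef", res.descriptor_ref)
        el.set("structureRef", res.structure_ref)
        for label, value in res.values:
            ve = etree.SubElement(el, _q("value"))
            ve.set("label", label)
            if value is None:
                ve.set("missing", "true")
            else:
                ve.text = _fmt_decimal(value)

    return root


def qsarml_bytes(d: dm.Dataset, ontology=None) -> bytes:
    """Serialize ``d`` to QSAR-ML bytes; refuses an inconsistent dataset.

    ``ontology`` (optional registry) enables ontology-id resolution in
    the pre-write validation; structural checks run regardless.
    """
    violations = dm.validate_dataset(d, ontology)
    if violations:
        raise InvalidDatasetError(violations)
    root = _dataset_to_element(d)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def write_qsarml(d: dm.Dataset, sink, ontology=None) -> None:
    """Write ``d`` as a QSAR-ML document to ``sink`` (path or binary file).

    Raises :class:`InvalidDatasetError` (listing the violations) instead
    of writing an inconsistent dataset. Output is byte-deterministic and
    always passes :func:`validate_schema`.
    """
    data = qsarml_bytes(d, ontology)
    if isinstance(sink, (str, Path)):
        Path(sink).write_bytes(data)
    else:
        sink.write(data)


def _read_source(source) -> bytes:
    if isinstance(source, bytes):
        return source
    if isinstance(source, (str, Path)):
        return Path(source).read_bytes()
    data = source.read()
    return data if isinstance(data, bytes) else data.encode("utf-8")


def validate_schema(source) -> SchemaReport:
    """Validate a byte source against the QSAR-ML schema.

    Never raises on invalid content: non-XML bytes, an empty stream or a
    schema violation all come back as ``valid=False`` with ``(line,
    message)`` diagnostics.
    """
    data = _read_source(source)
    try:
        doc = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        return SchemaReport(False, [(exc.lineno or 0, str(exc))])
    schema = _schema()
    if schema.validate(doc):
        return SchemaReport(True, [])
    return SchemaReport(False, [(e.line, e.message) for e in schema.error_log])


def read_qsarml(source, ontology=None) -> dm.Dataset:
    """Parse a QSAR-ML document back into a :class:`Dataset`.

    The document is schema-validated first (:class:`SchemaError` on
    failure), then reconstructed, then checked for internal consistency
    against ``ontology`` (:class:`InvalidDatasetError` on e.g. dangling
    references). ``read(write(d))`` equals ``d`` field-for-field.
    """
    data = _read_source(source)
    report = validate_schema(data)
    if not report.valid:
        raise SchemaError(report.messages)
    root = etree.fromstring(data)

    d = dm.Dataset()
    meta = root.find(_q("metadata"))
    d.metadata = dm.Metadata(
        authors=[el.text or "" for el in meta.findall(_q("author"))],
        license=meta.findtext(_q("license"), default=""),
        description=meta.findtext(_q("description"), default=""),
        references=[dm.Reference(el.get("title", ""), el.get("identifier", ""))
                    for el in meta.findall(_q("reference"))],
    )

    slist = root.find(_q("structureList"))
    for el in slist.findall(_q("resource")):
        d.resources.append(dm.Resource(el.get("id"), el.get("location"),
                                       el.get("checksum"),
                                       el.get("checksumAlgorithm"),
                                       el.get("format")))
    for el in slist.findall(_q("structure")):
        d.structures.append(dm.StructureEntry(el.get("id"), el.get("resourceRef"),
                                              int(el.get("resourceIndex")),
                                              el.get("inchi")))

    dlist = root.find(_q("descriptorList"))
    for el in dlist.findall(_q("descriptorProvider")):
        d.providers.append(dm.DescriptorProvider(el.get("id"), el.get("name"),
                                                 el.get("version"),
                                                 el.get("vendor", "")))
    for el in dlist.findall(_q("descriptor")):
        params = [dm.Parameter(pe.get("key"),
                               _parse_parameter_value(pe.get("kind"), pe.get("value")),
                               pe.get("kind"))
                  for pe in el.findall(_q("parameter"))]
        d.descriptors.append(dm.Descriptor(el.get("id"), el.get("ontologyRef"),
                                           el.get("providerRef"), params))

    rlist = root.find(_q("responseList"))
    for el in rlist.findall(_q("responseUnit")):
        d.response_units.append(dm.ResponseUnit(el.get("id"), el.get("name"),
                                                el.get("definition", "")))
    for el in rlist.findall(_q("response")):
        d.responses.append(dm.Response(el.get("structureRef"), el.get("unitRef"),
                                       float(el.get("value"))))

    reslist = root.find(_q("descriptorResultList"))
    for el in reslist.findall(_q("descriptorResult")):
        values: list[tuple[str, Optional[float]]] = []
        for ve in el.findall(_q("value")):
            if ve.get("missing") in ("true", "1"):
                values.append((ve.get("label"), None))
            else:
                values.append((ve.get("label"), float(ve.text)))
        d.results.append(dm.DescriptorResult(el.get("descriptorRef"),
                                             el.get("structureRef"), values))

    violations = dm.validate_dataset(d, ontology)
    if violations:
        raise InvalidDatasetError(violations)
    return d
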