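"""Typed in-memory model of a QSAR dataset.

A :class:`Dataset` aggregates everything needed to reproduce the *setup*
of a QSAR analysis: the chemical structures (as indexed records inside
checksummed file resources, each carrying its Standard InChI), the
descriptors chosen (each referencing an ontology entry and a versioned
software implementation, with optional parameters), the measured
responses, and the calculated descriptor values.

The model is deliberately permissive at construction time: any field
combination can be built, and :func:`validate_dataset` reports every
broken invariant as a :class:`Violation` value rather than raising.
Serialization lives in :mod:`qsarml.qsarml_io`; this module is purely
in-memory.

Identifiers are opaque tokens. The ``add_*`` helpers on :class:`Dataset`
generate them as deterministic slugs (entity kind + ordinal) so that a
dataset built twice from the same inputs serializes byte-for-byte
identically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

__all__ = [
    "CHECKSUM_ALGORITHMS",
    "RESOURCE_FORMATS",
    "PARAMETER_KINDS",
    "Reference",
    "Metadata",
    "Resource",
    "StructureEntry",
    "DescriptorProvider",
    "Parameter",
    "Descriptor",
    "ResponseUnit",
    "Response",
    "DescriptorResult",
    "Dataset",
    "Violation",
    "new_dataset",
    "validate_dataset",
    "descriptor_identity",
]

#: Supported checksum algorithms mapped to their hex-digest length.
CHECKSUM_ALGORITHMS = {"SHA-256": 64, "SHA-1": 40, "MD5": 32}

#: Structure file formats a Resource may declare.
RESOURCE_FORMATS = ("SDF", "SMILES")

#: Declared scalar kinds a Parameter value may take.
PARAMETER_KINDS = ("string", "integer", "decimal")

_HEX_RE = re.compile(r"^[0-9a-f]+$")


@dataclass
class Reference:
    """A literature reference attached to the dataset metadata."""

    title: str = ""
    identifier: str = ""  # DOI, URL or free-form citation


@dataclass
class Metadata:
    """Dataset-level provenance: authors, license, description, references."""

    authors: list[str] = field(default_factory=list)
    license: str = ""
    description: str = ""
    references: list[Reference] = field(default_factory=list)


@dataclass
class Resource:
    """A structure file referenced by path or URL, with an integrity checksum."""

    id: str
    location: str
    checksum: str
    checksum_algorithm: str = "SHA-256"
    format: str = "SMILES"


@dataclass
class StructureEntry:
    """One chemical structure: a record inside a Resource plus its InChI.

    ``resource_index`` is the 0-based ordinal of the record within the
    resource file (an internal addressing convention, not chemistry
    semantics). ``inchi`` is the Standard InChI of the record, stored so
    that any later change to the underlying file can be detected.
    """

    id: str
    resource_ref: str
    resource_index: int
    inchi: str


@dataclass
class DescriptorProvider:
    """A versioned software implementation that supplies descriptor values."""

    id: str
    name: str
    version: str
    vendor: str = ""


@dataclass(frozen=True)
class Parameter:
    """A (key, value) setting for a descriptor, with an explicit value kind."""

    key: str
    value: Union[str, int, float]
    kind: str = "string"


@dataclass
class Descriptor:
    """A descriptor choice: ontology entry + provider + parameters.

    Two descriptors with the same (ontology_id, provider, parameters)
    identity are duplicates and rejected by :func:`validate_dataset`.
    """

    id: str
    ontology_id: str
    provider_ref: str
    parameters: list[Parameter] = field(default_factory=list)


@dataclass
class ResponseUnit:
    """The unit/kind of a measured endpoint, e.g. IC50 or LD50."""

    id: str
    name: str
    definition: str = ""


@dataclass
class Response:
    """A measured endpoint value for one structure in one unit."""

    structure_ref: str
    unit_ref: str
    value: float


@dataclass
class DescriptorResult:
    """The value vector produced by one descriptor for one structure.

    ``values`` is an ordered list of ``(label, value)`` pairs; a value of
    ``None`` is the explicit missing-marker (the label slot is kept so
    that label sequences stay aligned across structures).
    """

    descriptor_ref: str
    structure_ref: str
    values: list[tuple[str, Optional[float]]] = field(default_factory=list)


@dataclass
class Dataset:
    """Root aggregate: everything required to reproduce a QSAR dataset setup."""

    metadata: Metadata = field(default_factory=Metadata)
    resources: list[Resource] = field(default_factory=list)
    structures: list[StructureEntry] = field(default_factory=list)
    providers: list[DescriptorProvider] = field(default_factory=list)
    descriptors: list[Descriptor] = field(default_factory=list)
    response_units: list[ResponseUnit] = field(default_factory=list)
    responses: list[Response] = field(default_factory=list)
    results: list[DescriptorResult] = field(default_factory=list)

    # -- deterministic-slug builders ------------------------------------
    # Writers generate ids as "<kind>-<ordinal>" so repeated builds from
    # the same inputs are byte-identical on serialization.

    def add_resource(self, location: str, checksum: str,
                     checksum_algorithm: str = "SHA-256",
                     format: str = "SMILES") -> Resource:
        r = Resource(f"resource-{len(self.resources)}", location, checksum,
                     checksum_algorithm, format)
        self.resources.append(r)
        return r

    def add_structure(self, resource: Union[Resource, str], resource_index: int,
                      inchi: str) -> StructureEntry:
        ref = resource.id if isinstance(resource, Resource) else resource
        s = StructureEntry(f"structure-{len(self.structures)}", ref,
                           resource_index, inchi)
        self.structures.append(s)
        return s

    def add_provider(self, name: str, version: str, vendor: str = "") -> DescriptorProvider:
        p = DescriptorProvider(f"provider-{len(self.providers)}", name, version, vendor)
        self.providers.append(p)
        return p

    def add_descriptor(self, ontology_id: str,
                       provider: Union[DescriptorProvider, str],
                       parameters: Sequence[Parameter] = ()) -> Descriptor:
        ref = provider.id if isinstance(provider, DescriptorProvider) else provider
        d = Descriptor(f"descriptor-{len(self.descriptors)}", ontology_id, ref,
                       list(parameters))
        self.descriptors.append(d)
        return d

    def add_response_unit(self, name: str, definition: str = "") -> ResponseUnit:
        u = ResponseUnit(f"unit-{len(self.response_units)}", name, definition)
        self.response_units.append(u)
        return u

    def add_response(self, structure: Union[StructureEntry, str],
                     unit: Union[ResponseUnit, str], value: float) -> Response:
        sref = structure.id if isinstance(structure, StructureEntry) else structure
        uref = unit.id if isinstance(unit, ResponseUnit) else unit
        r = Response(sref, uref, float(value))
        self.responses.append(r)
        return r

    def add_result(self, descriptor: Union[Descriptor, str],
                   structure: Union[StructureEntry, str],
                   values: Sequence[tuple[str, Optional[float]]]) -> DescriptorResult:
        dref = descriptor.id if isinstance(descriptor, Descriptor) else descriptor
        sref = structure.id if isinstance(structure, StructureEntry) else structure
        res = DescriptorResult(dref, sref, [(str(l), None if v is None else float(v))
                                            for l, v in values])
        self.results.append(res)
        return res

    # -- lookup helpers --------------------------------------------------

    def resource_by_id(self, rid: str) -> Optional[Resource]:
        return next((r for r in self.resources if r.id == rid), None)

    def structure_by_id(self, sid: str) -> Optional[StructureEntry]:
        return next((s for s in self.structures if s.id == sid), None)

    def provider_by_id(self, pid: str) -> Optional[DescriptorProvider]:
        return next((p for p in self.providers if p.id == pid), None)

    def descriptor_by_id(self, did: str) -> Optional[Descriptor]:
        return next((d for d in self.descriptors if d.id == did), None)

    def unit_by_id(self, uid: str) -> Optional[ResponseUnit]:
        return next((u for u in self.response_units if u.id == uid), None)


@dataclass(frozen=True)
class Violation:
    """One broken invariant: which entity, which rule, human-readable why."""

    entity_id: str
    rule: str
    message: str


def new_dataset(metadata: Optional[Metadata] = None) -> Dataset:
    """Return an empty dataset carrying ``metadata`` (all entity lists empty)."""
    return Dataset(metadata=metadata if metadata is not None else Metadata())


def descriptor_identity(descriptor: Descriptor,
                        provider: Optional[DescriptorProvider]) -> tuple:
    """Identity triple used for duplicate detection and dataset merging.

    Parameters are compared order-insensitively (sorted by key) because
    parameter order carries no meaning.
    """
    params = tuple(sorted((p.key, p.kind, str(p.value)) for p in descriptor.parameters))
    pname, pversion = (provider.name, provider.version) if provider else ("?", "?")
    return (descriptor.ontology_id, pname, pversion, params)


def _check_unique(ids, kind: str, out: list[Violation]) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            out.append(Violation(i, "duplicate-id", f"{kind} id {i!r} is not unique"))
        seen.add(i)


def validate_dataset(d: Dataset, ontology=None) -> list[Violation]:
    """Check every cross-reference and uniqueness invariant of ``d``.

    Returns one :class:`Violation` per broken invariant, in a
    deterministic order (entities are visited in list order). An empty
    list means the dataset is internally consistent.

    ``ontology`` is an :class:`~qsarml.descriptor_ontology.OntologyRegistry`;
    when given, every descriptor's ``ontology_id`` must resolve in it.
    When ``None``, ontology resolution is skipped (structural checks only).
    """
    out: list[Violation] = []

    _check_unique((r.id for r in d.resources), "resource", out)
    _check_unique((s.id for s in d.structures), "structure", out)
    _check_unique((p.id for p in d.providers), "provider", out)
    _check_unique((x.id for x in d.descriptors), "descriptor", out)
    _check_unique((u.id for u in d.response_units), "response unit", out)

    resource_ids = {r.id for r in d.resources}
    structure_ids = {s.id for s in d.structures}
    provider_ids = {p.id for p in d.providers}
    descriptor_ids = {x.id for x in d.descriptors}
    unit_ids = {u.id for u in d.response_units}

    for ref in d.metadata.references:
        if not ref.title and not ref.identifier:
            out.append(Violation("metadata", "empty-reference",
                                 "reference needs a title or an identifier"))

    for r in d.resources:
        if r.checksum_algorithm not in CHECKSUM_ALGORITHMS:
            out.append(Violation(r.id, "unknown-algorithm",
                                 f"checksum algorithm {r.checksum_algorithm!r} not supported"))
        else:
            want = CHECKSUM_ALGORITHMS[r.checksum_algorithm]
            if not _HEX_RE.match(r.checksum) or len(r.checksum) != want:
                out.append(Violation(r.id, "invalid-checksum",
                                     f"checksum is not a {want}-char lowercase hex digest"))
        if r.format not in RESOURCE_FORMATS:
            out.append(Violation(r.id, "unknown-format",
                                 f"resource format {r.format!r} not supported"))

    for s in d.structures:
        if s.resource_ref not in resource_ids:
            out.append(Violation(s.id, "dangling-reference",
                                 f"structure references unknown resource {s.resource_ref!r}"))
        if not s.inchi.startswith("InChI=1S/"):
            out.append(Violation(s.id, "invalid-inchi",
                                 "inchi must be a Standard InChI (prefix 'InChI=1S/')"))
        if s.resource_index < 0:
            out.append(Violation(s.id, "invalid-index", "resource_index must be >= 0"))

    for p in d.providers:
        if not p.name or not p.version:
            out.append(Violation(p.id, "empty-provider",
                                 "provider needs a non-empty name and version"))

    seen_identity: dict[tuple, str] = {}
    for x in d.descriptors:
        if x.provider_ref not in provider_ids:
            out.append(Violation(x.id, "dangling-reference",
                                 f"descriptor references unknown provider {x.provider_ref!r}"))
        if ontology is not None and x.ontology_id not in ontology:
            out.append(Violation(x.id, "unknown-ontology-id",
                                 f"ontology id {x.ontology_id!r} does not resolve"))
        for par in x.parameters:
            if not par.key:
                out.append(Violation(x.id, "empty-parameter-key",
                                     "parameter key must be non-empty"))
            if par.kind not in PARAMETER_KINDS:
                out.append(Violation(x.id, "unknown-parameter-kind",
                                     f"parameter kind {par.kind!r} not one of {PARAMETER_KINDS}"))
        ident = descriptor_identity(x, d.provider_by_id(x.provider_ref))
        if ident in seen_identity:
            out.append(Violation(x.id, "duplicate-descriptor",
                                 f"same ontology/provider/parameters as {seen_identity[ident]!r}"))
        else:
            seen_identity[ident] = x.id

    for u in d.response_units:
        if not u.name:
            out.append(Violation(u.id, "empty-name", "response unit name must be non-empty"))

    seen_resp: set[tuple[str, str]] = set()
    for i, resp in enumerate(d.responses):
        rid = f"response-{i}"
        if resp.structure_ref not in structure_ids:
            out.append(Violation(rid, "dangling-reference",
                                 f"response references unknown structure {resp.structure_ref!r}"))
        if resp.unit_ref not in unit_ids:
            out.append(Violation(rid, "dangling-reference",
                                 f"response references unknown unit {resp.unit_ref!r}"))
        key = (resp.structure_ref, resp.unit_ref)
        if key in seen_resp:
            out.append(Violation(rid, "duplicate-response",
                                 f"second response for structure/unit pair {key!r}"))
        seen_resp.add(key)

    seen_res: set[tuple[str, str]] = set()
    labels_for: dict[str, tuple[str, ...]] = {}
    for i, res in enumerate(d.results):
        rid = f"result-{i}"
        if res.descriptor_ref not in descriptor_ids:
            out.append(Violation(rid, "dangling-reference",
                                 f"result references unknown descriptor {res.descriptor_ref!r}"))
        if res.structure_ref not in structure_ids:
            out.append(Violation(rid, "dangling-reference",
                                 f"result references unknown structure {res.structure_ref!r}"))
        key = (res.descriptor_ref, res.structure_ref)
        if key in seen_res:
            out.append(Violation(rid, "duplicate-result",
                                 f"second result for descriptor/structure pair {key!r}"))
        seen_res.add(key)
        labels = tuple(l for l, _ in res.values)
        if len(set(labels)) != len(labels):
            out.append(Violation(rid, "duplicate-label",
                                 "value labels within one result must be unique"))
        prev = labels_for.setdefault(res.descriptor_ref, labels)
        if labels != prev:
            out.append(Violation(rid, "inconsistent-labels",
                                 f"label sequence {labels!r} differs from {prev!r} "
                                 f"for descriptor {res.descriptor_ref!r}"))

    return out
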