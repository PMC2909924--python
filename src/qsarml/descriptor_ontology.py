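"""Descriptor ontology registry.

Every descriptor in a dataset points into an ontology that pins down
*what* is being computed, independently of any software that computes
it. Entries carry a unique id, a human name, a crisp definition, a
category (constitutional, topological, geometric or electronic) and an
optional literature reference.

The registry is loaded from a flat TSV file (one entry per line,
columns ``ontology_id  name  category  definition  reference``, ``#``
comments and a mandatory header line). The package bundles a default
file whose ids live in the ``qsarml:`` namespace — a documented
stand-in, not a claim of identity with any external ontology; external
ontology files in the same format can be loaded and combined via
:func:`extend_registry`.
"""

from __future__ import annotations

import difflib
import io
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Union

from .errors import OntologyLoadError, OntologyLookupError

__all__ = [
    "CATEGORIES",
    "OntologyEntry",
    "OntologyRegistry",
    "load_ontology",
    "load_default_ontology",
    "extend_registry",
    "lookup",
    "list_by_category",
]

CATEGORIES = ("constitutional", "topological", "geometric", "electronic")

_COLUMNS = ("ontology_id", "name", "category", "definition", "reference")


@dataclass(frozen=True)
class OntologyEntry:
    ontology_id: str
    name: str
    definition: str
    category: str
    reference: str = ""


@dataclass
class OntologyRegistry:
    """Immutable-after-load mapping of ontology id to entry."""

    entries: dict[str, OntologyEntry] = field(default_factory=dict)
    source: str = ""

    def __contains__(self, ontology_id: str) -> bool:
        return ontology_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())


def _parse_lines(lines, source: str) -> OntologyRegistry:
    entries: dict[str, OntologyEntry] = {}
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if not header_seen:
            if tuple(f.strip() for f in fields) != _COLUMNS:
                raise OntologyLoadError(
                    f"{source}:{lineno}: expected header {' '.join(_COLUMNS)!r}")
            header_seen = True
            continue
        if len(fields) < 4:
            raise OntologyLoadError(f"{source}:{lineno}: expected >=4 tab-separated fields")
        oid, name, category, definition = (f.strip() for f in fields[:4])
        reference = fields[4].strip() if len(fields) > 4 else ""
        if category not in CATEGORIES:
            raise OntologyLoadError(
                f"{source}:{lineno}: unknown category {category!r} "
                f"(must be one of {', '.join(CATEGORIES)})")
        if oid in entries:
            raise OntologyLoadError(f"{source}:{lineno}: duplicate ontology id {oid!r}")
        entries[oid] = OntologyEntry(oid, name, definition, category, reference)
    return OntologyRegistry(entries=entries, source=source)


def load_ontology(source: Union[str, Path, bytes, io.IOBase]) -> OntologyRegistry:
    """Load an ontology registry from a TSV file, path, bytes, or stream.

    Raises :class:`OntologyLoadError` on duplicate ids, unknown
    categories or a malformed header. An empty file (header only, or
    nothing at all) yields an empty registry.
    """
    if isinstance(source, bytes):
        return _parse_lines(source.decode("utf-8").splitlines(), "<bytes>")
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
        return _parse_lines(text.splitlines(), str(source))
    data = source.read()
    if isinstance(data, bytes):
        data = data.decode("utf-8")
    return _parse_lines(data.splitlines(), "<stream>")


def load_default_ontology() -> OntologyRegistry:
    """Load the ontology file bundled with the package."""
    ref = importlib_resources.files("qsarml").joinpath("data/ontology.tsv")
    reg = _parse_lines(ref.read_text(encoding="utf-8").splitlines(), "qsarml:data/ontology.tsv")
    return reg


def extend_registry(base: OntologyRegistry, extra: OntologyRegistry) -> OntologyRegistry:
    """Combine two registries into a new one; overlapping ids are an error."""
    dup = sorted(set(base.entries) & set(extra.entries))
    if dup:
        raise OntologyLoadError(f"duplicate ontology ids across files: {', '.join(dup)}")
    merged = dict(base.entries)
    merged.update(extra.entries)
    return OntologyRegistry(entries=merged, source=f"{base.source}+{extra.source}")


def lookup(registry: OntologyRegistry, ontology_id: str) -> OntologyEntry:
    """Return the entry for ``ontology_id``.

    Raises :class:`OntologyLookupError` carrying the nearest matches
    (by id and by name) when the id is unknown.
    """
    entry = registry.entries.get(ontology_id)
    if entry is not None:
        return entry
    candidates = list(registry.entries) + [e.name for e in registry.entries.values()]
    suggestions = difflib.get_close_matches(ontology_id, candidates, n=3, cutoff=0.4)
    raise OntologyLookupError(ontology_id, suggestions)


def list_by_category(registry: OntologyRegistry, category: str) -> list[OntologyEntry]:
    """All entries of one category, sorted by ontology id (stable output)."""
    if category not in CATEGORIES:
        raise OntologyLoadError(f"unknown category {category!r}")
    return sorted((e for e in registry if e.category == category),
                  key=lambda e: e.ontology_id)
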