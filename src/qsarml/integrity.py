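"""Integrity mechanisms: per-structure InChI and per-resource checksums.

A dataset stores, for every structure file, a digest of the raw bytes,
and for every structure record, its Standard InChI. Together these make
accidental edits, transmission errors and silent structure changes
detectable: :func:`verify_dataset` recomputes both and reports every
discrepancy without modifying the dataset.

This module also owns the structure-file readers (SDF V2000 and SMILES,
one record per line with an optional whitespace-separated title) that
the rest of the package builds on.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Callable, Optional, Union

from rdkit import Chem, RDLogger

from .datamodel import CHECKSUM_ALGORITHMS, Dataset
from .errors import ChecksumAlgorithmError, StructureError

# InChI generation emits advisory notes (proton rearrangements etc.) via
# the RDKit logger; they are not errors and would swamp batch output.
RDLogger.DisableLog("rdApp.info")
RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "StructureRecord",
    "Mismatch",
    "IntegrityReport",
    "compute_inchi",
    "compute_checksum",
    "read_structures",
    "add_structure_resource",
    "verify_dataset",
]

_HASHLIB_NAMES = {"SHA-256": "sha256", "SHA-1": "sha1", "MD5": "md5"}


@dataclass
class StructureRecord:
    """One record of a structure file: its 0-based index, parsed molecule
    (``None`` if unparseable) and title."""

    index: int
    mol: Optional[Chem.Mol]
    title: str = ""


@dataclass(frozen=True)
class Mismatch:
    """A stored/recomputed disagreement found during verification."""

    entity_id: str
    kind: str  # "checksum" or "inchi"
    stored: str
    recomputed: str


@dataclass
class IntegrityReport:
    checked: int = 0
    mismatches: list[Mismatch] = field(default_factory=list)
    missing_resources: list[str] = field(default_factory=list)

    @property
    def intact(self) -> bool:
        return not self.mismatches and not self.missing_resources


def compute_inchi(mol: Chem.Mol) -> str:
    """Standard InChI of a parsed molecule (prefix ``InChI=1S/``).

    Deterministic; raises :class:`StructureError` for an unparseable
    molecule (``None``) or one the InChI algorithm rejects.
    """
    if mol is None:
        raise StructureError("cannot compute InChI of an unparseable molecule")
    inchi = Chem.MolToInchi(mol)
    if not inchi:
        raise StructureError("InChI generation failed for molecule")
    return inchi


def compute_checksum(data: Union[bytes, BinaryIO], algorithm: str = "SHA-256") -> str:
    """Lowercase hex digest of ``data`` (bytes or a binary stream).

    ``algorithm`` must be one of SHA-256, SHA-1, MD5; anything else is a
    :class:`ChecksumAlgorithmError`. Streams are consumed in chunks.
    """
    name = _HASHLIB_NAMES.get(algorithm)
    if name is None:
        raise ChecksumAlgorithmError(
            f"unknown checksum algorithm {algorithm!r}; "
            f"supported: {', '.join(CHECKSUM_ALGORITHMS)}")
    h = hashlib.new(name)
    if isinstance(data, bytes):
        h.update(data)
    else:
        for chunk in iter(lambda: data.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_structures(path: Union[str, Path], format: str) -> list[StructureRecord]:
    """Read all records of an SDF or SMILES structure file, in file order.

    Unparseable records are returned with ``mol=None`` (callers decide
    whether that is fatal); the record *count* always reflects the file,
    so ``resource_index`` addressing stays stable.
    """
    path = Path(path)
    if format == "SMILES":
        records = []
        idx = 0
        for line in path.read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            title = parts[1].strip() if len(parts) > 1 else ""
            records.append(StructureRecord(idx, Chem.MolFromSmiles(smiles), title))
            idx += 1
        return records
    if format == "SDF":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        records = []
        for idx, mol in enumerate(supplier):
            title = mol.GetProp("_Name") if mol is not None and mol.HasProp("_Name") else ""
            records.append(StructureRecord(idx, mol, title))
        return records
    raise StructureError(f"unsupported structure format {format!r}")


def add_structure_resource(d: Dataset, file_path: Union[str, Path], *,
                           location: Optional[str] = None,
                           format: Optional[str] = None):
    """Import a structure file into ``d`` as a Resource plus one
    StructureEntry per record.

    The checksum (SHA-256 of the raw bytes) and every record's InChI
    are computed here, at import time — they are the reference values
    that :func:`verify_dataset` later recomputes. ``location`` is the
    path stored in the dataset (defaults to the file name); ``format``
    is inferred from the suffix (``.sdf`` -> SDF, else SMILES) when not
    given. An unparseable record aborts with its index named.

    Returns ``(resource, structures)``.
    """
    file_path = Path(file_path)
    if format is None:
        format = "SDF" if file_path.suffix.lower() in (".sdf", ".sd", ".mol") else "SMILES"
    if location is None:
        location = file_path.name
    if any(r.location == location for r in d.resources):
        raise StructureError(f"resource {location!r} is already part of the dataset")

    records = read_structures(file_path, format)
    for rec in records:
        if rec.mol is None:
            raise StructureError(
                f"record {rec.index} of {file_path} could not be parsed")

    checksum = compute_checksum(file_path.read_bytes(), "SHA-256")
    resource = d.add_resource(location, checksum, "SHA-256", format)
    structures = [d.add_structure(resource, rec.index, compute_inchi(rec.mol))
                  for rec in records]
    return resource, structures


def _default_resolver(root: Union[str, Path]) -> Callable[[str], Path]:
    root = Path(root)

    def resolve(location: str) -> Path:
        p = Path(location)
        return p if p.is_absolute() else root / p

    return resolve


def verify_dataset(d: Dataset,
                   resource_root: Union[str, Path, Callable[[str], Path]] = ".",
                   ) -> IntegrityReport:
    """Recompute every checksum and InChI in ``d`` and report discrepancies.

    ``resource_root`` resolves resource locations: either a base
    directory for relative paths, or a callable ``location -> Path``.
    Unreachable resources are listed in ``missing_resources`` and their
    structures are left unchecked (unverifiable, not wrong). A structure
    record that no longer parses is reported as an InChI mismatch with
    recomputed value ``"unparseable"``. The dataset is never modified.
    """
    resolve = resource_root if callable(resource_root) else _default_resolver(resource_root)
    report = IntegrityReport()
    records_by_resource: dict[str, Optional[list[StructureRecord]]] = {}

    for res in d.resources:
        path = resolve(res.location)
        if not path.is_file():
            report.missing_resources.append(res.id)
            records_by_resource[res.id] = None
            continue
        report.checked += 1
        actual = compute_checksum(path.read_bytes(), res.checksum_algorithm)
        if actual != res.checksum:
            report.mismatches.append(Mismatch(res.id, "checksum", res.checksum, actual))
        records_by_resource[res.id] = read_structures(path, res.format)

    for s in d.structures:
        records = records_by_resource.get(s.resource_ref)
        if records is None:  # resource missing or dangling ref: unverifiable
            continue
        report.checked += 1
        if s.resource_index >= len(records) or records[s.resource_index].mol is None:
            report.mismatches.append(Mismatch(s.id, "inchi", s.inchi, "unparseable"))
            continue
        actual = compute_inchi(records[s.resource_index].mol)
        if actual != s.inchi:
            report.mismatches.append(Mismatch(s.id, "inchi", s.inchi, actual))

    return report
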