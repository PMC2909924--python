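"""Exception hierarchy shared across the package.

Validation of a :class:`~qsarml.datamodel.Dataset` reports problems as
*data* (lists of ``Violation``); exceptions are reserved for operations
that cannot produce a meaningful result (unreadable input, refusal to
serialize an inconsistent dataset, merge conflicts, ...).
"""

from __future__ import annotations


class QsarmlError(Exception):
    """Base class for all package-specific errors."""


class InvalidDatasetError(QsarmlError):
    """Raised when an operation refuses to proceed on an inconsistent dataset.

    Carries the list of :class:`~qsarml.datamodel.Violation` objects that
    describe what is wrong.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(f"[{v.rule}] {v.entity_id}: {v.message}" for v in self.violations)
        super().__init__(f"dataset is not internally consistent: {lines}")


class SchemaError(QsarmlError):
    """An XML document failed schema validation (or was not XML at all)."""

    def __init__(self, messages):
        self.messages = list(messages)
        detail = "; ".join(f"line {line}: {msg}" for line, msg in self.messages)
        super().__init__(f"document does not conform to the QSAR-ML schema: {detail}")


class StructureError(QsarmlError):
    """A chemical structure record could not be parsed or processed."""


class ChecksumAlgorithmError(QsarmlError):
    """An unsupported checksum algorithm was requested."""


class OntologyLoadError(QsarmlError):
    """The ontology file is malformed (duplicate id, unknown category, ...)."""


class OntologyLookupError(QsarmlError):
    """An ontology id is not present in the registry.

    ``suggestions`` holds near matches (by id or name) to help the caller.
    """

    def __init__(self, ontology_id, suggestions=()):
        self.ontology_id = ontology_id
        self.suggestions = list(suggestions)
        msg = f"unknown ontology id {ontology_id!r}"
        if self.suggestions:
            msg += "; did you mean: " + ", ".join(self.suggestions)
        super().__init__(msg)


class ProviderRegistrationError(QsarmlError):
    """A provider with the same (name, version) is already registered."""


class CalculationError(QsarmlError):
    """A descriptor calculation could not be dispatched (unknown provider
    or a provider that does not implement the requested ontology id)."""


class ParameterError(QsarmlError):
    """A descriptor parameter was rejected (unknown key, wrong kind,
    missing required parameter, or an unparseable pattern value).

    Raised before any per-structure computation starts.
    """


class MergeError(QsarmlError):
    """Two datasets disagree on a value for the same structure and cannot
    be merged without losing information."""
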