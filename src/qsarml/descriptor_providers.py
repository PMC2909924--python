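"""Descriptor provider contract and the built-in deterministic provider.

A *provider* is a named, versioned piece of software that implements
one or more ontology descriptors. The contract is intentionally small:
given the same structures and parameters, an implementation must return
identical values on every call, and its value-label sequence is fixed
and declared up front. Several providers may implement the same
ontology descriptor (different software, different versions); a
:class:`ProviderRegistry` keeps them discoverable per ontology id and
the user picks which one a dataset binds to.

The built-in provider ``qsarml-builtin`` implements a small, exactly
specified panel (atom/bond counts, molecular weight from a bundled
atomic-weight table, H-bond donor/acceptor counts, a parameterized
element count, SMARTS fragment counting by unique atom sets, and a
three-value element profile). Aromaticity perception follows RDKit's
default model; the RDKit version is recorded in the provider version
string so calculated values stay attributable to an exact toolkit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import import_module, resources as importlib_resources
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import rdkit
from rdkit import Chem

from .datamodel import Descriptor, DescriptorProvider, DescriptorResult
from .errors import CalculationError, ParameterError, ProviderRegistrationError

log = logging.getLogger(__name__)

__all__ = [
    "BUILTIN_PROVIDER_NAME",
    "BUILTIN_PROVIDER_VERSION",
    "ParameterSpec",
    "DescriptorImplementation",
    "ProviderContract",
    "ProviderRegistry",
    "register_provider",
    "list_implementations",
    "calculate",
    "builtin_contract",
    "default_registry",
    "load_provider_config",
    "atomic_weights",
]

BUILTIN_PROVIDER_NAME = "qsarml-builtin"
#: Build metadata records the cheminformatics toolkit (and hence the
#: aromaticity model) behind the calculated values.
BUILTIN_PROVIDER_VERSION = f"1.0.0+rdkit.{rdkit.__version__}"


@dataclass(frozen=True)
class ParameterSpec:
    """One accepted parameter of a descriptor implementation."""

    key: str
    kind: str  # "string" | "integer" | "decimal"
    required: bool = True


@dataclass(frozen=True)
class DescriptorImplementation:
    """A concrete, deterministic implementation of one ontology descriptor."""

    ontology_id: str
    value_labels: tuple[str, ...]
    func: Callable[[Chem.Mol, dict], tuple[float, ...]]
    parameters: tuple[ParameterSpec, ...] = ()


@dataclass
class ProviderContract:
    """A provider (name, version, vendor) plus everything it implements."""

    name: str
    version: str
    vendor: str = ""
    implementations: dict[str, DescriptorImplementation] = field(default_factory=dict)

    def as_provider(self, provider_id: str = "") -> DescriptorProvider:
        """Materialize a dataset-side provider entry for this contract."""
        return DescriptorProvider(provider_id, self.name, self.version, self.vendor)


class ProviderRegistry:
    """Registered provider contracts, keyed by (name, version)."""

    def __init__(self) -> None:
        self._contracts: dict[tuple[str, str], ProviderContract] = {}

    def register(self, contract: ProviderContract) -> None:
        key = (contract.name, contract.version)
        if key in self._contracts:
            raise ProviderRegistrationError(
                f"provider {contract.name!r} version {contract.version!r} "
                "is already registered")
        self._contracts[key] = contract

    def get(self, name: str, version: str) -> Optional[ProviderContract]:
        return self._contracts.get((name, version))

    def contracts(self) -> list[ProviderContract]:
        return [self._contracts[k] for k in sorted(self._contracts)]

    def list_implementations(self, ontology_id: str) -> list[ProviderContract]:
        """All providers implementing ``ontology_id``, sorted by (name, version)."""
        return [c for c in self.contracts() if ontology_id in c.implementations]

    def versions_of(self, name: str) -> list[str]:
        return sorted(v for n, v in self._contracts if n == name)


def register_provider(registry: ProviderRegistry, contract: ProviderContract) -> None:
    registry.register(contract)


def list_implementations(registry: ProviderRegistry, ontology_id: str):
    return registry.list_implementations(ontology_id)


def _coerced_params(impl: DescriptorImplementation,
                    descriptor: Descriptor) -> dict:
    """Validate descriptor parameters against the implementation's specs.

    Unknown keys, kind mismatches and missing required parameters raise
    :class:`ParameterError` before any per-structure work starts.
    """
    specs = {s.key: s for s in impl.parameters}
    out: dict = {}
    for p in descriptor.parameters:
        spec = specs.get(p.key)
        if spec is None:
            raise ParameterError(
                f"descriptor {impl.ontology_id!r} does not accept parameter {p.key!r} "
                f"(accepted: {sorted(specs) or 'none'})")
        if p.kind != spec.kind:
            raise ParameterError(
                f"parameter {p.key!r} must be of kind {spec.kind!r}, got {p.kind!r}")
        out[p.key] = p.value
    for spec in impl.parameters:
        if spec.required and spec.key not in out:
            raise ParameterError(
                f"descriptor {impl.ontology_id!r} requires parameter {spec.key!r}")
    return out


def calculate(registry: ProviderRegistry, descriptor: Descriptor,
              provider: DescriptorProvider,
              structures: Sequence[tuple[str, Optional[Chem.Mol]]],
              ) -> list[DescriptorResult]:
    """Run one descriptor over a batch of structures.

    ``structures`` is an ordered list of ``(structure_id, mol)`` pairs
    (``mol`` may be ``None`` for an unparseable record). One
    :class:`DescriptorResult` is returned per input structure, in input
    order. Per-structure failures yield the declared labels with
    missing-markers and a logged warning — the batch never aborts.
    Deterministic: identical inputs give identical results.
    """
    contract = registry.get(provider.name, provider.version)
    if contract is None:
        raise CalculationError(
            f"no registered provider {provider.name!r} version {provider.version!r}")
    impl = contract.implementations.get(descriptor.ontology_id)
    if impl is None:
        raise CalculationError(
            f"provider {provider.name!r} does not implement {descriptor.ontology_id!r}")
    params = _coerced_params(impl, descriptor)
    if impl.ontology_id == "qsarml:smartsFragmentCount":
        # fail fast on an unparseable pattern, before any computation
        if Chem.MolFromSmarts(str(params["smarts"])) is None:
            raise ParameterError(f"invalid SMARTS pattern {params['smarts']!r}")

    results = []
    missing = [(label, None) for label in impl.value_labels]
    for sid, mol in structures:
        if mol is None:
            log.warning("structure %s: unparseable molecule, reporting missing values", sid)
            values = list(missing)
        else:
            try:
                computed = impl.func(mol, params)
                values = list(zip(impl.value_labels, (float(v) for v in computed)))
            except Exception as exc:  # per-structure failure policy
                log.warning("structure %s: %s calculation failed (%s), "
                            "reporting missing values", sid, descriptor.ontology_id, exc)
                values = list(missing)
        results.append(DescriptorResult(descriptor.id, sid, values))
    return results


# ---------------------------------------------------------------------------
# built-in panel


def atomic_weights() -> dict[str, float]:
    """The bundled standard atomic-weight table (symbol -> weight)."""
    text = importlib_resources.files("qsarml").joinpath(
        "data/atomic_weights.tsv").read_text(encoding="utf-8")
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("symbol"):
            continue
        symbol, weight = line.split("\t")
        table[symbol] = float(weight)
    return table


_WEIGHTS = atomic_weights()


def _heavy_atom_count(mol, params):
    return (mol.GetNumHeavyAtoms(),)


def _bond_count(mol, params):
    n = sum(1 for b in mol.GetBonds()
            if b.GetBeginAtom().GetAtomicNum() != 1
            and b.GetEndAtom().GetAtomicNum() != 1)
    return (n,)


def _molecular_weight(mol, params):
    total = 0.0
    for atom in Chem.AddHs(mol).GetAtoms():
        symbol = atom.GetSymbol()
        if symbol not in _WEIGHTS:
            raise ValueError(f"element {symbol!r} not in the bundled weight table")
        total += _WEIGHTS[symbol]
    return (total,)


def _element_count(mol, params):
    symbol = str(params["element"])
    if symbol == "H":
        n = sum(1 for a in Chem.AddHs(mol).GetAtoms() if a.GetAtomicNum() == 1)
    else:
        n = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == symbol)
    return (n,)


def _hbd_count(mol, params):
    n = sum(1 for a in mol.GetAtoms()
            if a.GetAtomicNum() in (7, 8) and a.GetTotalNumHs(includeNeighbors=True) >= 1)
    return (n,)


def _hba_count(mol, params):
    return (sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8)),)


def _smarts_fragment_count(mol, params):
    pattern = Chem.MolFromSmarts(str(params["smarts"]))
    if pattern is None:
        raise ValueError(f"invalid SMARTS {params['smarts']!r}")
    # group-counting semantics: symmetry-equivalent embeddings of the
    # same atom set count once
    matches = mol.GetSubstructMatches(pattern, uniquify=False, maxMatches=100000)
    return (len({frozenset(m) for m in matches}),)


def _element_profile(mol, params):
    counts = {6: 0, 7: 0, 8: 0}
    for a in mol.GetAtoms():
        z = a.GetAtomicNum()
        if z in counts:
            counts[z] += 1
    return (counts[6], counts[7], counts[8])


def builtin_contract() -> ProviderContract:
    """The built-in deterministic descriptor panel."""
    impls = [
        DescriptorImplementation("qsarml:heavyAtomCount", ("value",), _heavy_atom_count),
        DescriptorImplementation("qsarml:bondCount", ("value",), _bond_count),
        DescriptorImplementation("qsarml:molecularWeight", ("value",), _molecular_weight),
        DescriptorImplementation("qsarml:elementCount", ("value",), _element_count,
                                 (ParameterSpec("element", "string"),)),
        DescriptorImplementation("qsarml:hbdCount", ("value",), _hbd_count),
        DescriptorImplementation("qsarml:hbaCount", ("value",), _hba_count),
        DescriptorImplementation("qsarml:smartsFragmentCount", ("value",),
                                 _smarts_fragment_count,
                                 (ParameterSpec("smarts", "string"),)),
        DescriptorImplementation("qsarml:elementProfile", ("nC", "nN", "nO"),
                                 _element_profile),
    ]
    return ProviderContract(
        name=BUILTIN_PROVIDER_NAME,
        version=BUILTIN_PROVIDER_VERSION,
        vendor="qsarml project",
        implementations={i.ontology_id: i for i in impls},
    )


def default_registry() -> ProviderRegistry:
    """A fresh registry with the built-in provider registered."""
    registry = ProviderRegistry()
    registry.register(builtin_contract())
    return registry


def load_provider_config(path: Union[str, Path],
                         registry: Optional[ProviderRegistry] = None,
                         ) -> ProviderRegistry:
    """Register external providers listed in a flat config file.

    Format: one ``module:attribute`` per line (``#`` comments allowed);
    each attribute must be a :class:`ProviderContract`, or a zero-argument
    callable returning one. This is the extension point for third-party
    descriptor software — e.g. an adapter wrapping a remote service.
    """
    registry = registry if registry is not None else default_registry()
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ProviderRegistrationError(
                f"{path}:{lineno}: expected 'module:attribute', got {line!r}")
        module_name, attr = line.rsplit(":", 1)
        obj = getattr(import_module(module_name), attr)
        contract = obj() if callable(obj) and not isinstance(obj, ProviderContract) else obj
        registry.register(contract)
    return registry
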