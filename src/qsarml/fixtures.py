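"""Deterministic synthetic inputs for tests, demos and verification runs.

Everything here is generated, seeded and tiny: a bundled pool of 50
small drug-like molecules (all stereo-free and at most 20 heavy atoms,
so every entry parses, round-trips through SDF, and yields a Standard
InChI), a fixture writer that materializes a SMILES resource file, a
response CSV and a built QSAR-ML dataset on disk — optionally with
exactly one named fault injected — and an in-memory random-dataset
generator for property-based round-trip testing.

Response values are seeded pseudo-random numbers on a pIC50-like scale
(uniform in 4–9); they carry no structure–activity signal whatsoever.
The fixtures exercise the plumbing, not QSAR modeling.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from rdkit import Chem

from . import datamodel as dm
from .descriptor_providers import BUILTIN_PROVIDER_NAME, BUILTIN_PROVIDER_VERSION
from .integrity import add_structure_resource, compute_checksum, compute_inchi
from .qsarml_io import qsarml_bytes, read_qsarml

__all__ = [
    "CORRUPTIONS",
    "POOL",
    "FixtureSpec",
    "FixtureManifest",
    "pool_molecules",
    "pool_inchis",
    "make_fixture",
    "load_fixture_dataset",
    "random_dataset",
]

CORRUPTIONS = ("none", "flip-byte-in-resource", "mutate-structure", "dangle-reference")

#: (name, SMILES) pool of small drug-like molecules. Kept stereo-free so
#: SMILES- and SDF-derived InChIs agree exactly for every entry.
POOL: tuple[tuple[str, str], ...] = (
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    ("nicotine", "CN1CCCC1c1cccnc1"),
    ("benzene", "c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("aniline", "Nc1ccccc1"),
    ("pyridine", "c1ccncc1"),
    ("ethanol", "CCO"),
    ("methane", "C"),
    ("acetone", "CC(C)=O"),
    ("acetic-acid", "CC(=O)O"),
    ("benzoic-acid", "OC(=O)c1ccccc1"),
    ("salicylic-acid", "OC(=O)c1ccccc1O"),
    ("nitrobenzene", "O=[N+]([O-])c1ccccc1"),
    ("styrene", "C=Cc1ccccc1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("indole", "c1ccc2[nH]ccc2c1"),
    ("imidazole", "c1c[nH]cn1"),
    ("furan", "c1ccoc1"),
    ("thiophene", "c1ccsc1"),
    ("pyrrole", "c1cc[nH]c1"),
    ("cyclohexane", "C1CCCCC1"),
    ("cyclohexanol", "OC1CCCCC1"),
    ("glucose", "OCC1OC(O)C(O)C(O)C1O"),
    ("glycerol", "OCC(O)CO"),
    ("urea", "NC(N)=O"),
    ("glycine", "NCC(=O)O"),
    ("alanine", "CC(N)C(=O)O"),
    ("phenylalanine", "NC(Cc1ccccc1)C(=O)O"),
    ("serine", "OCC(N)C(=O)O"),
    ("cysteine", "NC(CS)C(=O)O"),
    ("dopamine", "NCCc1ccc(O)c(O)c1"),
    ("serotonin", "NCCc1c[nH]c2ccc(O)cc12"),
    ("adrenaline", "CNCC(O)c1ccc(O)c(O)c1"),
    ("histamine", "NCCc1c[nH]cn1"),
    ("tyramine", "NCCc1ccc(O)cc1"),
    ("benzamide", "NC(=O)c1ccccc1"),
    ("acetanilide", "CC(=O)Nc1ccccc1"),
    ("anisole", "COc1ccccc1"),
    ("benzaldehyde", "O=Cc1ccccc1"),
    ("cinnamaldehyde", "O=CC=Cc1ccccc1"),
    ("vanillin", "COc1cc(C=O)ccc1O"),
    ("coumarin", "O=c1ccc2ccccc2o1"),
    ("uracil", "O=c1cc[nH]c(=O)[nH]1"),
    ("thymine", "Cc1c[nH]c(=O)[nH]c1=O"),
    ("adenine", "Nc1ncnc2[nH]cnc12"),
    ("theobromine", "Cn1cnc2c1c(=O)[nH]c(=O)n2C"),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one fixture. Equal specs produce byte-identical output."""

    n_structures: int
    seed: int = 0
    corruption: str = "none"

    def __post_init__(self):
        if self.n_structures < 0:
            raise ValueError("n_structures must be >= 0")
        if self.corruption not in CORRUPTIONS:
            raise ValueError(f"corruption must be one of {CORRUPTIONS}")
        if self.corruption != "none" and self.n_structures < 1:
            raise ValueError("corruption needs at least one structure")
        if self.n_structures > len(POOL):
            raise ValueError(f"at most {len(POOL)} structures available in the pool")


@dataclass
class FixtureManifest:
    """What a fixture wrote: (file name, SHA-256) pairs, post-corruption."""

    directory: Path
    files: list[tuple[str, str]] = field(default_factory=list)

    @property
    def dataset_path(self) -> Path:
        return self.directory / "dataset.qsarml.xml"

    @property
    def resource_path(self) -> Path:
        return self.directory / "structures.smi"

    @property
    def responses_path(self) -> Path:
        return self.directory / "responses.csv"


def pool_molecules() -> list[tuple[str, str, Chem.Mol]]:
    """The pool as parsed molecules: (name, smiles, mol)."""
    return [(name, smi, Chem.MolFromSmiles(smi)) for name, smi in POOL]


_pool_inchi_cache: Optional[list[str]] = None


def pool_inchis() -> list[str]:
    """Standard InChIs of the pool, in pool order (computed once)."""
    global _pool_inchi_cache
    if _pool_inchi_cache is None:
        _pool_inchi_cache = [compute_inchi(Chem.MolFromSmiles(smi)) for _, smi in POOL]
    return list(_pool_inchi_cache)


def _write_manifest(directory: Path, names: list[str]) -> FixtureManifest:
    manifest = FixtureManifest(directory)
    lines = []
    for name in names:
        digest = compute_checksum((directory / name).read_bytes(), "SHA-256")
        manifest.files.append((name, digest))
        lines.append(f"{name}\t{digest}")
    (directory / "manifest.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return manifest


def make_fixture(spec: FixtureSpec, sink_dir: Union[str, Path]) -> FixtureManifest:
    """Write a complete fixture into ``sink_dir``.

    Produces ``structures.smi`` (n seeded pool molecules), a seeded
    ``responses.csv`` (pIC50 column keyed by structure id), a built and
    schema-valid ``dataset.qsarml.xml`` whose checksums/InChIs were
    computed from the clean files, and ``manifest.tsv`` listing every
    file with its final SHA-256. When ``spec.corruption`` is not
    ``"none"``, exactly that one fault is applied *after* the dataset
    is built, so verification sees precisely the intended discrepancy.
    """
    directory = Path(sink_dir)
    directory.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    chosen = rng.sample(range(len(POOL)), spec.n_structures)
    entries = [POOL[i] for i in chosen]
    smi_lines = [f"{smiles} {name}" for name, smiles in entries]
    resource_path = directory / "structures.smi"
    resource_path.write_text("\n".join(smi_lines) + ("\n" if smi_lines else ""),
                             encoding="utf-8")

    values = [round(rng.uniform(4.0, 9.0), 3) for _ in entries]
    csv_lines = ["structureId,value"]
    csv_lines += [f"structure-{i},{v}" for i, v in enumerate(values)]
    (directory / "responses.csv").write_text("\n".join(csv_lines) + "\n",
                                             encoding="utf-8")

    d = dm.new_dataset(dm.Metadata(
        authors=["qsarml fixture generator"],
        license="CC0-1.0",
        description=f"synthetic fixture (n={spec.n_structures}, seed={spec.seed})",
    ))
    _, structures = add_structure_resource(d, resource_path,
                                           location="structures.smi",
                                           format="SMILES")
    unit = d.add_response_unit("pIC50", "negative log10 of IC50 in mol/L (synthetic)")
    for s, v in zip(structures, values):
        d.add_response(s, unit, v)

    dataset_path = directory / "dataset.qsarml.xml"
    dataset_path.write_bytes(qsarml_bytes(d))

    if spec.corruption == "flip-byte-in-resource":
        # change one byte inside a record *title*: the file digest moves
        # but every molecule still parses to the same InChI
        idx = rng.randrange(spec.n_structures)
        line = smi_lines[idx]
        flipped = line[:-1] + ("X" if line[-1] != "X" else "Y")
        smi_lines[idx] = flipped
        resource_path.write_text("\n".join(smi_lines) + "\n", encoding="utf-8")
    elif spec.corruption == "mutate-structure":
        # swap one record's SMILES for a different pool molecule,
        # keeping the title: one InChI mismatch (plus the checksum one)
        idx = rng.randrange(spec.n_structures)
        remaining = [i for i in range(len(POOL)) if i not in chosen]
        name = entries[idx][0]
        _, new_smiles = POOL[rng.choice(remaining)]
        smi_lines[idx] = f"{new_smiles} {name}"
        resource_path.write_text("\n".join(smi_lines) + "\n", encoding="utf-8")
    elif spec.corruption == "dangle-reference":
        # retarget one response at a structure id that does not exist;
        # still schema-valid, but reference resolution must fail
        data = dataset_path.read_bytes()
        data = re.sub(rb'structureRef="[^"]*"',
                      b'structureRef="structure-missing"', data, count=1)
        dataset_path.write_bytes(data)

    return _write_manifest(directory,
                           ["structures.smi", "responses.csv", "dataset.qsarml.xml"])


def load_fixture_dataset(directory: Union[str, Path], ontology=None) -> dm.Dataset:
    """Read back the dataset a fixture wrote (raises on a dangling fault)."""
    return read_qsarml(Path(directory) / "dataset.qsarml.xml", ontology)


# ---------------------------------------------------------------------------
# in-memory random datasets for property-based testing

_AUTHORS = ("A. Researcher", "B. Modeler", "C. Chemist", "D. Curator")
_LICENSES = ("CC0-1.0", "CC-BY-4.0", "MIT")
_UNITS = (("pIC50", "negative log molar IC50"), ("LD50", "lethal dose, mg/kg"),
          ("logS", "log aqueous solubility"))
_DESCRIPTOR_CHOICES = (
    ("qsarml:heavyAtomCount", ()),
    ("qsarml:bondCount", ()),
    ("qsarml:hbaCount", ()),
    ("qsarml:elementCount", (dm.Parameter("element", "C", "string"),)),
    ("qsarml:elementCount", (dm.Parameter("element", "O", "string"),)),
    ("qsarml:smartsFragmentCount", (dm.Parameter("smarts", "[#7,#8]", "string"),)),
    ("qsarml:elementProfile", ()),
)
_LABELS = {"qsarml:elementProfile": ("nC", "nN", "nO")}


def random_dataset(seed_or_rng: Union[int, random.Random], *,
                   max_structures: int = 6,
                   with_results: bool = True) -> dm.Dataset:
    """A small, internally consistent random dataset.

    All ontology ids resolve in the bundled ontology and all InChIs are
    real (drawn from the pool), so the result always passes
    ``validate_dataset`` — which makes this the workhorse for round-trip
    and merge property tests. Fully deterministic given the seed.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, random.Random)
           else random.Random(seed_or_rng))

    meta = dm.Metadata(
        authors=list(rng.sample(_AUTHORS, rng.randint(0, 3))),
        license=rng.choice(_LICENSES),
        description=f"random dataset {rng.randrange(10**6)}",
        references=[dm.Reference(title=f"study {rng.randrange(100)}",
                                 identifier=f"doi:10.1000/{rng.randrange(10**4)}")
                    for _ in range(rng.randint(0, 2))],
    )
    d = dm.new_dataset(meta)

    for i in range(rng.randint(1, 2)):
        digest = compute_checksum(rng.getrandbits(64).to_bytes(8, "big"), "SHA-256")
        d.add_resource(f"set{i}.smi", digest, "SHA-256", "SMILES")

    inchis = pool_inchis()
    n_structures = rng.randint(0, max_structures)
    for i, pool_idx in enumerate(rng.sample(range(len(POOL)), n_structures)):
        d.add_structure(rng.choice(d.resources), i, inchis[pool_idx])

    builtin = d.add_provider(BUILTIN_PROVIDER_NAME, BUILTIN_PROVIDER_VERSION,
                             "qsarml project")
    providers = [builtin]
    if rng.random() < 0.3:
        providers.append(d.add_provider("acme-descriptors", "2.1", "ACME"))

    n_desc = rng.randint(0, min(4, len(_DESCRIPTOR_CHOICES)))
    for choice_idx in rng.sample(range(len(_DESCRIPTOR_CHOICES)), n_desc):
        oid, params = _DESCRIPTOR_CHOICES[choice_idx]
        d.add_descriptor(oid, rng.choice(providers), params)

    for name, definition in rng.sample(_UNITS, rng.randint(0, 2)):
        d.add_response_unit(name, definition)

    for s in d.structures:
        for u in d.response_units:
            if rng.random() < 0.7:
                d.add_response(s, u, rng.uniform(-5.0, 12.0))

    if with_results:
        for desc in d.descriptors:
            labels = _LABELS.get(desc.ontology_id, ("value",))
            for s in d.structures:
                if rng.random() < 0.8:
                    values = [(lab, None if rng.random() < 0.1
                               else rng.uniform(-100.0, 500.0))
                              for lab in labels]
                    d.add_result(desc, s, values)

    return d
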