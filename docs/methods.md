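# Methods

## The model

A QSAR dataset setup is modeled as a single aggregate with five parts:

1. **Structures.** A `Resource` is a structure file (SDF V2000 or SMILES,
   one record per line with an optional whitespace-separated title),
   referenced by path or URL and carrying a checksum of its raw bytes with an
   explicit algorithm (`SHA-256` default; `SHA-1`/`MD5` accepted for
   compatibility with older material). A `StructureEntry` addresses one
   record inside a resource by a 0-based `resource_index` — an internal
   addressing convention, not chemistry — and stores the record's Standard
   InChI. The pair (checksum, InChI) is the integrity contract: the checksum
   detects *any* byte change in the file, the InChI detects (and localizes)
   *chemical* change of a specific record, and also serves as the
   cross-dataset identity key.
2. **Descriptors.** A `Descriptor` is a triple: an ontology id (what is
   computed), a provider reference (which software, at which version,
   computes it) and optional typed parameters (how). Two descriptors with the
   same (ontology id, provider, parameter set) are duplicates and rejected;
   parameter order is not part of the identity.
3. **Responses.** Measured endpoints, one value per (structure, unit);
   replicate measurements must be aggregated by the caller before import.
4. **Results.** One value vector per (descriptor, structure) pair, as ordered
   `(label, value)` pairs. A failed value is an explicit missing-marker, never
   a dropped slot, so label sequences stay aligned across structures; all
   results of one descriptor must share one label sequence.
5. **Metadata.** Authors, license, description, literature references.

Consistency (reference resolution, uniqueness, label discipline, checksum
syntax, Standard-InChI prefix) is checked by `validate_dataset`, which
returns a deterministic list of violations rather than raising: a dataset
with problems is still a useful object to inspect and report on.

## Serialization

Datasets exchange as XML under the project namespace
`https://qsar-ml.dev/schema/1.0`, validated against the shipped XSD. Element
and attribute names are lowerCamelCase after the entity names
(`structureList`, `descriptorResult`, …). Design choices aimed at
bit-reproducibility:

- ids are deterministic slugs (`structure-0`, `descriptor-2`, …) generated
  by the builders, so rebuilding the same dataset yields identical bytes;
- UTF-8 with a mandatory XML declaration; fixed element and attribute order;
- decimals are written as the shortest string that reparses to the same
  double (Python `repr`), so numeric round trips are exact and
  `write(read(write(d)))` equals `write(d)` byte-for-byte;
- non-finite values are refused at write time (the schema types response
  values as `xs:double`, and `NaN`/`inf` have no place in a dataset);
- the writer refuses an inconsistent dataset outright, listing violations.

The schema deliberately types cross-references as plain strings, not
ID/IDREF: reference *resolution* is the data model's job, so a dangling
reference is reported as a model violation with its rule name rather than as
an opaque schema error. Structures are stored by reference only (resource +
index), never inline.

## Integrity verification

`verify_dataset` recomputes every resource checksum from the file bytes and
every structure InChI by re-reading the referenced record, and reports each
discrepancy with the stored and recomputed values. An unreachable resource
is *unverifiable, not wrong*: it lands in `missing_resources` and its
structures are skipped. A record that no longer parses is an InChI mismatch
with recomputed value `"unparseable"`. Only Standard InChI (`InChI=1S/`,
default options) is used; checksums are over raw bytes, not any
canonicalized form — the simplest contract a third party can re-verify with
standard tools.

## Descriptor providers

A provider implementation must be deterministic and declare its value labels
and accepted parameters up front. Parameter validation (unknown key, wrong
kind, missing required, unparseable SMARTS) happens before any per-structure
work; per-structure failures (unparseable molecule, element outside the
weight table) yield missing-markers plus a logged warning and never abort the
batch. Results come back in input order, so permuting the input permutes the
output identically.

The built-in panel (`qsarml-builtin`) is intentionally small and exactly
specified:

| descriptor | category | values | definition |
|---|---|---|---|
| heavyAtomCount | constitutional | 1 | non-hydrogen atoms |
| bondCount | constitutional | 1 | bonds between heavy atoms |
| molecularWeight | constitutional | 1 | sum of standard atomic weights incl. implicit H |
| elementCount | constitutional | 1 | atoms of element given by parameter `element` (implicit H counted for H) |
| elementProfile | constitutional | 3 (nC, nN, nO) | carbon/nitrogen/oxygen counts |
| smartsFragmentCount | topological | 1 | matches of parameter `smarts`, counted as unique atom sets |
| hbdCount | electronic | 1 | N/O atoms bearing ≥1 H |
| hbaCount | electronic | 1 | N + O atoms |

Numerical conventions: molecular weight uses the bundled IUPAC-2021 abridged
standard atomic weights (`data/atomic_weights.tsv`) — values are exact sums
over that table, e.g. methane = 12.011 + 4 × 1.008 = 16.043. SMARTS matches
are counted as *unique atom sets* (symmetry-equivalent embeddings collapse
to one), which gives the group-counting semantics expected of acidic/basic
fragment counts; raw embedding counts would depend on pattern symmetry.
Aromaticity perception follows RDKit's default model, and the RDKit version
is embedded in the provider version string
(`1.0.0+rdkit.<version>`), so a dataset records exactly which perception
model produced its values.

The ontology registry bundles entries for the whole panel plus a few
defined-but-unimplemented descriptors (ringCount, logP, gravitationalIndex)
under the `qsarml:` id namespace — a documented stand-in scheme, not a claim
of identity with any external ontology; external ontology files in the same
TSV format can be loaded alongside, with duplicate ids rejected.

## Matrix, CSV, merge

The data matrix has one row per structure (structure-list order) and columns
`descriptorId.valueLabel` (descriptor-list order, declared label order)
followed by response-unit names. The label sequence of a descriptor with no
stored results is taken from the provider registry's declaration when
available, else a single generic `value` column. CSV output is RFC 4180
(CRLF, minimal quoting, UTF-8) with `NA` for missing cells and `.` as the
decimal separator regardless of locale; because decimals use shortest
round-trip formatting, reparsing the CSV recovers every cell exactly.

`completeness` is filled descriptor cells over `|structures| × total value
labels`, defined as 1.0 when that denominator is zero (no structures or no
descriptors — nothing is missing).

Merging uses the stored InChI as structure identity: structures deduplicate
by InChI (first occurrence wins; both inputs' resources are kept as
provenance), providers by (name, version), descriptors by their identity
triple, response units by name. Two differing values for the same (InChI,
unit) or (InChI, descriptor) abort the merge with the conflict named —
conflicts signal provenance problems and are never averaged. Merged metadata
unions authors and references; the combined license must be stated
explicitly (the CLI infers it only when both inputs agree). Consequently the
merged structure/descriptor/response/result *sets* are independent of
argument order.

## Fixtures and what passing tests mean

The fixture generator draws from a bundled pool of 50 small drug-like
molecules (≤ 20 heavy atoms, all valence-valid, deliberately stereo-free so
SMILES- and SDF-derived InChIs agree without relying on wedge-bond round
trips). All randomness flows from the single spec seed; equal specs produce
byte-identical directories. Response values are uniform pseudo-random
numbers on a pIC50-like scale (4–9): they carry *no* structure–activity
signal, so passing tests demonstrate correct plumbing — serialization,
integrity, calculation, assembly — and say nothing about predictive
modeling, which is out of scope.

Fault injection is surgical by construction: `flip-byte-in-resource` edits
one byte inside a record *title*, so exactly one checksum moves and no
molecule changes; `mutate-structure` swaps one record's SMILES for a
different pool molecule, giving exactly one InChI mismatch plus the
unavoidable checksum mismatch; `dangle-reference` retargets one response at
a nonexistent structure id, which passes the schema but fails reference
resolution. Faults are applied *after* the dataset is built, mirroring
post-hoc tampering.

Features of real data the fixtures do not emulate: multi-file resource
layouts, remote (URL) resources, SDF data fields, salts/mixtures,
stereochemistry, and tautomer ambiguity.

## Verification problem sizes

The verification script (`scripts/acceptance.py`) and the heavyweight test
module use these sizes, chosen so a full run completes in seconds while
still exercising hundreds of independent cases: 200 generated datasets for
round-trip fidelity, 100 fixtures per corruption mode (4 molecules each) for
integrity detection plus 100 clean fixtures for false positives, 500 pooled
molecules for descriptor/oracle agreement, 50 dataset shapes for the
matrix/CSV contract, 100 random pairs for merge algebra, and a 20-molecule
end-to-end CLI pipeline.

## Known limitations

- Only SDF V2000 and one-record-per-line SMILES resources are read; no
  gzip, no SDF data-field import, no streaming of very large files.
- The provider contract is local and synchronous; remote services can be
  adapted behind it, but no network code ships in the package.
- InChIKey is not used; identity comparisons are full-InChI string equality.
- Responses are single-valued per (structure, unit); no replicate storage.
- Dataset merging keeps the first-seen definition of a response unit when
  names collide; definitions are not compared.
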