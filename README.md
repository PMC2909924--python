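# qsarml

Reproducible setup and exchange of QSAR datasets.

QSAR (Quantitative Structure–Activity Relationship) modeling correlates
chemical structure, expressed as numerical *descriptors*, with a measured
*response* such as pIC50. The statistical side of QSAR is well policed; the
*setup* of the dataset usually is not: published datasets rarely state which
structures were used byte-for-byte, which descriptor definitions were meant,
which software (and version) computed them, or with which parameters. That
makes most QSAR datasets impossible to reproduce or merge.

`qsarml` treats the dataset setup itself as the artifact:

- **Typed data model** (`qsarml.datamodel`) — structures (indexed records of
  checksummed file resources, each carrying its Standard InChI), descriptors
  (each referencing an ontology entry + a versioned provider + parameters),
  response values with units, and calculated descriptor value vectors.
  `validate_dataset` reports every broken cross-reference or uniqueness
  invariant as data, never by raising.
- **QSAR-ML XML exchange format** (`qsarml.qsarml_io`) — deterministic,
  schema-validated serialization (XSD shipped in `src/qsarml/data/qsarml.xsd`,
  namespace `https://qsar-ml.dev/schema/1.0`, extension `.qsarml.xml`).
  `read(write(d)) == d` field-for-field and writes are byte-reproducible.
- **Integrity** (`qsarml.integrity`) — SHA-256/SHA-1/MD5 resource checksums
  and per-structure Standard InChIs, computed at import and re-verified on
  demand: any edit to a structure file is detected and attributed to the
  right resource or structure.
- **Descriptor ontology** (`qsarml.descriptor_ontology`) — a flat-TSV
  registry assigning each descriptor a unique id, crisp definition and one of
  four categories (constitutional, topological, geometric, electronic);
  extensible by loading additional files.
- **Versioned descriptor providers** (`qsarml.descriptor_providers`) — a
  plugin contract (deterministic calculation, declared value labels and
  parameters) plus a built-in panel: heavy-atom/bond counts, molecular weight
  from a bundled atomic-weight table, element counts, H-bond donor/acceptor
  counts, SMARTS fragment counts, and a multi-value element profile.
- **Dataset operations** (`qsarml.dataset_ops`) — assemble the numeric
  matrix, export RFC 4180 CSV, compute overlap between datasets and merge
  them with InChI-based structure identity and refuse-on-conflict semantics.
- **Fixtures** (`qsarml.fixtures`) — seeded synthetic structure/response
  sets (and deliberately corrupted variants) so everything is testable
  offline.
- **CLI** (`qsarml`) — `new`, `add-structures`, `add-descriptor`,
  `add-responses`, `calculate`, `validate`, `verify`, `export`, `merge`,
  `info`, all operating on the dataset file as the single source of truth.

## Worked example

Five molecules and a response table (the package's own fixture generator can
produce these: `make_fixture(FixtureSpec(5, seed=31), "inputs")`):

```sh
qsarml new study.qsarml.xml --author "A. Researcher" --license CC0-1.0
qsarml add-structures study.qsarml.xml structures.smi
qsarml add-descriptor study.qsarml.xml qsarml:heavyAtomCount
qsarml add-descriptor study.qsarml.xml qsarml:elementCount -P element=O
qsarml add-descriptor study.qsarml.xml qsarml:elementProfile
qsarml add-responses study.qsarml.xml responses.csv --unit pIC50
qsarml calculate study.qsarml.xml
qsarml verify study.qsarml.xml
qsarml export study.qsarml.xml --format csv -o matrix.csv
```

which prints, among other things:

```
added 5 structures from structures.smi
added qsarml:heavyAtomCount (qsarml-builtin 1.0.0+rdkit.2024.09.2)
calculated 15 results; completeness 1.000
checked 6 entities; intact
```

`calculated 15 results` is 3 descriptors × 5 structures; `completeness
1.000` means every descriptor cell has a value; `checked 6 entities; intact`
means the 1 resource checksum and 5 structure InChIs all re-verified. The
exported matrix (`descriptorId.valueLabel` columns, then response units):

```
structureId,descriptor-0.value,descriptor-1.value,descriptor-2.nC,descriptor-2.nN,descriptor-2.nO,pIC50
structure-0,13.0,4.0,9.0,0.0,4.0,4.704
structure-1,6.0,2.0,3.0,1.0,2.0,4.216
...
```

Row one is aspirin: 13 heavy atoms, 4 oxygens, element profile C9/N0/O4, and
its (synthetic) pIC50 of 4.704. If anyone later edits a structure file —
say swaps phenol for aniline — verification pins it down exactly:

```
$ qsarml verify study.qsarml.xml
checksum mismatch on resource-0: stored b2040af0… != recomputed 7e7406ee…
inchi mismatch on structure-2: stored InChI=1S/C6H6O/… != recomputed InChI=1S/C6H7N/…
checked 6 entities; NOT intact
```

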