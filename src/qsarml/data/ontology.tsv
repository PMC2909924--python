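# Bundled descriptor ontology (flat TSV format).
# Columns: ontology_id, name, category, definition, reference.
# Ids are namespaced "qsarml:" — a documented stand-in identifier scheme;
# externally supplied ontology files in the same format may be loaded alongside.
ontology_id	name	category	definition	reference
qsarml:heavyAtomCount	Heavy atom count	constitutional	Number of non-hydrogen atoms in the molecule.	Todeschini & Consonni, Handbook of Molecular Descriptors, Wiley-VCH 2000
qsarml:bondCount	Bond count	constitutional	Number of bonds between heavy atoms; bonds to hydrogen (implicit or explicit) are excluded.	Todeschini & Consonni, Handbook of Molecular Descriptors, Wiley-VCH 2000
qsarml:molecularWeight	Molecular weight	constitutional	Sum of average (standard) atomic weights over all atoms including implicit hydrogens.	IUPAC CIAAW, Standard Atomic Weights 2021
qsarml:elementCount	Element count	constitutional	Number of atoms of a given element (parameter "element"); implicit hydrogens are counted when element=H.	Todeschini & Consonni, Handbook of Molecular Descriptors, Wiley-VCH 2000
qsarml:elementProfile	Element profile (C, N, O)	constitutional	Counts of carbon, nitrogen and oxygen atoms, reported as the three labelled values nC, nN, nO.	Todeschini & Consonni, Handbook of Molecular Descriptors, Wiley-VCH 2000
qsarml:smartsFragmentCount	SMARTS fragment count	topological	Number of distinct substructure matches of a SMARTS pattern (parameter "smarts"), counted as unique atom sets.	Daylight Theory Manual, SMARTS
qsarml:ringCount	Ring count	topological	Number of smallest set of smallest rings (SSSR) in the molecular graph.	Todeschini & Consonni, Handbook of Molecular Descriptors, Wiley-VCH 2000
qsarml:hbdCount	Hydrogen bond donor count	electronic	Number of nitrogen or oxygen atoms bearing at least one hydrogen (explicit or implicit).	Lipinski et al., Adv Drug Deliv Rev 1997, 23:3-25
qsarml:hbaCount	Hydrogen bond acceptor count	electronic	Number of nitrogen plus oxygen atoms.	Lipinski et al., Adv Drug Deliv Rev 1997, 23:3-25
qsarml:logP	Octanol-water partition coefficient	electronic	Calculated logarithm of the octanol/water partition coefficient (atomic contribution method).	Wildman & Crippen, J Chem Inf Comput Sci 1999, 39:868-873
qsarml:gravitationalIndex	Gravitational index	geometric	Sum over bonded atom pairs of the product of atomic masses divided by squared interatomic distance; requires 3D coordinates.	Katritzky et al., J Phys Chem 1996, 100:10400-10407
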