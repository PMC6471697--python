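# External resource files (not distributed)

The two acceptance checks that reproduce the published integration numbers
for the real resources need the publicly distributed files below, dropped
into this directory. They are not shipped with the package.

| file | content | source |
| --- | --- | --- |
| `acsn_modules.gmt` | gene sets of the ACSN functional modules (GMT) | https://navicell.curie.fr/pages/maps_ReconMap%202.html / https://acsn.curie.fr/downloads.html |
| `reconmap_subsystems.gmt` | gene sets of the ReconMap 2.0 subsystems (GMT) | same page |
| `reconmap2.xml` | ReconMap 2.0 CellDesigner SBML map | https://vmh.uni.lu/#downloadview |
| `recon204_rules.tsv` | Recon2.04 reaction→GPR export, `reaction_id<TAB>rule` over Entrez ids | exported from the Recon2.04 model distribution |
| `entrez2hugo.tsv` | two-column Entrez→HUGO symbol table | e.g. HGNC BioMart export |

With the files in place, `pytest tests/test_acceptance.py` runs the two
real-data checks; without them those two tests fail with a pointer here.
All other tests are self-contained.
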