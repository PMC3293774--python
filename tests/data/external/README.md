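# External reference data (not bundled)

Two acceptance tests compare against public database records that cannot be
redistributed here as structures:

* `1sax.pdb`, `1u8r.pdb`, `1z9c.pdb` (and `1mzb.pdb`) — template protein-DNA
  complexes from the RCSB PDB;
* `slr1738.fasta` — the PerR-like regulator protein sequence.

Populate this directory once with

    python scripts/fetch_templates.py

(requires network access).  Without these files the two tests that need
them fail with a message pointing here; everything else in the suite is
self-contained.
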