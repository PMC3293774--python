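#!/usr/bin/env python
"""One-time fetch of the external reference data used by the acceptance tests.

Downloads the template complex entries (1MZB, 1SAX, 1U8R, 1Z9C) from the
RCSB and the PerR-like regulator Slr1738 protein sequence (Synechocystis sp.
PCC 6803, UniProt gene slr1738) into ``tests/data/external/``.  Requires
network access; the rest of the test suite never touches the network.

Usage::

    python scripts/fetch_templates.py
"""

from __future__ import annotations

import os
import sys
import urllib.request

OUT_DIR = os.path.join(os.path.dirname(__file__), "..", "tests", "data",
                       "external")
PDB_IDS = ("1MZB", "1SAX", "1U8R", "1Z9C")
RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"
UNIPROT_URL = ("https://rest.uniprot.org/uniprotkb/stream?format=fasta&query="
               "gene:slr1738+AND+organism_id:1111708")


def fetch(url: str, dest: str) -> None:
    print(f"fetching {url} -> {dest}")
    with urllib.request.urlopen(url, timeout=60) as resp:
        data = resp.read()
    with open(dest, "wb") as fh:
        fh.write(data)


def main() -> int:
    os.makedirs(OUT_DIR, exist_ok=True)
    for pdb_id in PDB_IDS:
        fetch(RCSB_URL.format(pdb_id=pdb_id),
              os.path.join(OUT_DIR, f"{pdb_id.lower()}.pdb"))
    fetch(UNIPROT_URL, os.path.join(OUT_DIR, "slr1738.fasta"))
    print("done")
    return 0


if __name__ == "__main__":
    sys.exit(main())
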