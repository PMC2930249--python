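"""Download the reference PDB entries (3MFF, 1OGA, 1BD2) into data/reference/.

Requires network access; run once before executing the reference-validation
tests. Files land as plain-text PDB next to the repository root:

    python scripts/fetch_reference.py [--dest data/reference]
"""

from __future__ import annotations

import argparse
import sys
import urllib.error
import urllib.request
from pathlib import Path

PDB_IDS = ("3mff", "1oga", "1bd2")
MIRRORS = (
    "https://files.rcsb.org/download/{id}.pdb",
    "https://www.ebi.ac.uk/pdbe/entry-files/download/pdb{id}.ent",
)


def fetch(pdb_id: str, dest: Path) -> bool:
    out = dest / f"{pdb_id}.pdb"
    if out.exists():
        print(f"{pdb_id}: already present ({out})")
        return True
    for mirror in MIRRORS:
        url = mirror.format(id=pdb_id)
        try:
            with urllib.request.urlopen(url, timeout=60) as resp:
                data = resp.read()
            out.write_bytes(data)
            print(f"{pdb_id}: downloaded {len(data)} bytes from {url}")
            return True
        except (urllib.error.URLError, OSError) as exc:
            print(f"{pdb_id}: {url} failed ({exc})")
    return False


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", default=Path(__file__).resolve().parents[1] / "data" / "reference",
                        type=Path)
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    ok = all([fetch(pdb_id, args.dest) for pdb_id in PDB_IDS])
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
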