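"""Reference crystal structures used for validating against published values.

The published comparison is between the 1F1E8hu TcR ectodomain (PDB 3MFF,
two copies per asymmetric unit), the JM22 TcR (PDB 1OGA, in complex with
HLA-A2/flu peptide) and the B7 TcR (PDB 1BD2, in complex with HLA-A2/Tax).
These entries are not shipped with the package; download them once with
``python scripts/fetch_reference.py`` (or place the files manually) into
``data/reference/``.  ``load_reference`` then serves parsed models.

Domain boundaries below use the author numbering of each deposited entry;
the TcR α-chain constant domain spans roughly residues 116–205 with the
variable domain before it.
"""

from __future__ import annotations

import os
from pathlib import Path

from .model import DomainDefinition, StructureModel
from .structure_io import read_structure

__all__ = ["reference_dir", "reference_path", "load_reference", "REFERENCE_DOMAINS"]

PDB_IDS = ("3mff", "1oga", "1bd2")

#: Chain assignments per entry (TcR α / β chains; MHC chains unused).
#: 3MFF asymmetric unit: copy 1 = chains A (α) + B (β), copy 2 = C + D.
#: 1OGA: D = JM22 α chain, E = β chain. 1BD2: D = B7 α chain, E = β chain.
REFERENCE_DOMAINS: dict[str, dict[str, DomainDefinition]] = {
    "3mff": {
        "Valpha_1": DomainDefinition("Valpha", "A", [(1, 115)]),
        "Calpha_1": DomainDefinition("Calpha", "A", [(116, 205)]),
        "Vbeta_1": DomainDefinition("Vbeta", "B", [(1, 116)]),
        "Valpha_2": DomainDefinition("Valpha", "C", [(1, 115)]),
        "Calpha_2": DomainDefinition("Calpha", "C", [(116, 205)]),
        "Vbeta_2": DomainDefinition("Vbeta", "D", [(1, 116)]),
    },
    "1oga": {
        "Valpha": DomainDefinition("Valpha", "D", [(1, 115)]),
        "Calpha": DomainDefinition("Calpha", "D", [(116, 205)]),
        "Vbeta": DomainDefinition("Vbeta", "E", [(1, 116)]),
    },
    "1bd2": {
        "Valpha": DomainDefinition("Valpha", "D", [(1, 115)]),
        "Calpha": DomainDefinition("Calpha", "D", [(116, 205)]),
        "Vbeta": DomainDefinition("Vbeta", "E", [(1, 116)]),
    },
}


def reference_dir() -> Path:
    env = os.environ.get("STRANDSLIP_REFERENCE_DIR")
    if env:
        return Path(env)
    return Path(__file__).resolve().parents[2] / "data" / "reference"


def reference_path(pdb_id: str) -> Path | None:
    """Local path of a reference entry, or None if not downloaded."""
    base = reference_dir()
    for suffix in (".pdb", ".ent", ".cif"):
        p = base / f"{pdb_id.lower()}{suffix}"
        if p.exists():
            return p
    return None


def load_reference(pdb_id: str) -> StructureModel:
    path = reference_path(pdb_id)
    if path is None:
        raise FileNotFoundError(
            f"reference structure {pdb_id.upper()} not found under {reference_dir()}; "
            "run `python scripts/fetch_reference.py` with network access to download "
            "PDB entries " + ", ".join(p.upper() for p in PDB_IDS)
        )
    return read_structure(path)
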