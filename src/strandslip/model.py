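"""Coordinate hierarchy shared by all analysis stages.

The hierarchy is deliberately minimal: a :class:`StructureModel` owns ordered
chains, each chain owns ordered residues, each residue owns atoms.  Author
residue numbering (with insertion codes) is the public coordinate convention
throughout the package; all residue ranges are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: 3-letter -> 1-letter code for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureError(ValueError):
    """Raised for unparseable or structurally invalid coordinate input."""


@dataclass
class AtomRecord:
    """One atom after alternate-location resolution.

    Coordinates are in Å, ``b_factor`` in Å² (isotropic displacement
    parameter), ``occupancy`` a fraction in [0, 1].
    """

    serial: int
    name: str
    element: str
    alt_loc: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(
                f"atom {self.serial} {self.name}: coordinates must be a finite 3-vector"
            )
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(
                f"atom {self.serial} {self.name}: occupancy {self.occupancy} outside [0, 1]"
            )
        if self.b_factor < 0:
            raise StructureError(
                f"atom {self.serial} {self.name}: negative B-factor {self.b_factor}"
            )


@dataclass
class Residue:
    """A residue identified by (chain_id, seq_number, insertion_code)."""

    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    is_hetero: bool = False

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def rid(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        icode = self.insertion_code.strip()
        return f"{self.chain_id}/{self.res_name}{self.seq_number}{icode}"

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> AtomRecord | None:
        return self.atom("CA")


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    """Parsed coordinate hierarchy for one model of a structure."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    source_format: str = "pdb"

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise StructureError(f"structure {self.id!r} has no chain {chain_id!r}")

    def residues(self, protein_only: bool = True) -> list[Residue]:
        """All residues in file order; by default waters/heteroatoms excluded."""
        out: list[Residue] = []
        for c in self.chains:
            for r in c.residues:
                if protein_only and (r.is_water or r.is_hetero):
                    continue
                out.append(r)
        return out

    def atoms(self, protein_only: bool = True) -> list[AtomRecord]:
        return [a for r in self.residues(protein_only) for a in r.atoms]


@dataclass
class DomainDefinition:
    """A labelled selection of inclusive author-numbering ranges on one chain."""

    label: str
    chain_id: str
    ranges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        spans = sorted(self.ranges)
        for start, end in spans:
            if start > end:
                raise StructureError(f"domain {self.label}: range ({start}, {end}) has start > end")
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise StructureError(f"domain {self.label}: overlapping ranges")

    def contains(self, seq_number: int) -> bool:
        return any(s <= seq_number <= e for s, e in self.ranges)


@dataclass
class Domain:
    """An ordered residue selection used as the unit of comparison.

    Residue order follows the source chain; gaps (e.g. crystallographically
    disordered residues) are simply absent.
    """

    label: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise StructureError(f"domain {self.label}: empty residue selection")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def ca_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.ca is not None]

    def ca_coords(self) -> np.ndarray:
        """N×3 array of Cα positions, residues without Cα skipped."""
        coords = [r.ca.coords for r in self.residues if r.ca is not None]
        if not coords:
            raise StructureError(f"domain {self.label}: no Cα atoms")
        return np.vstack(coords)

    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms]
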