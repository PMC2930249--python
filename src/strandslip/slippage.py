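"""Quantifying β-strand register slippage.

A register slip means the same spatial strand positions are occupied by
different (sequence-shifted) residues in two conformations of one sequence.
It is detected by contrasting the two residue correspondences:

* the **dual RMSD** — a low topological RMSD (the fold is conserved)
  combined with a high chemical RMSD (chemically identical residues sit far
  apart in the common-fold frame) is the signature of slippage;
* the **register-shift profile** — the per-residue integer offset between a
  residue's topological and chemical partners, measured in alignment-column
  space so that author-numbering offsets between constructs never masquerade
  as slippage;
* **slipped segments** — maximal runs of constant nonzero offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correspondence import (
    AlignmentConfig,
    Correspondence,
    CorrespondenceError,
    chemical_correspondence,
    topological_alignment,
)
from .geometry import kabsch_superpose, rmsd_under_transform
from .model import Domain, Residue

__all__ = [
    "DualRmsd",
    "RegisterShiftProfile",
    "ProfileEntry",
    "SlippageSegment",
    "dual_rmsd",
    "register_profile",
    "call_segments",
    "profile_to_frame",
]


@dataclass
class DualRmsd:
    """The pair of statistics contrasted by the slippage analysis.

    rmsd_topological : Å — Kabsch RMSD over the topological (spatial) pairs.
    rmsd_chemical : Å — RMSD of the chemical (sequence-identity) pairs
        evaluated in the topological superposition frame, with no refit.
    """

    rmsd_topological: float
    rmsd_chemical: float
    n_topological: int
    n_chemical: int
    equivalenced_fraction: float

    def as_dict(self) -> dict:
        return {
            "rmsd_topological_A": round(self.rmsd_topological, 3),
            "rmsd_chemical_A": round(self.rmsd_chemical, 3),
            "n_topological": self.n_topological,
            "n_chemical": self.n_chemical,
            "equivalenced_fraction": round(self.equivalenced_fraction, 4),
        }


@dataclass
class ProfileEntry:
    residue: Residue
    topological_partner: Residue
    chemical_partner: Residue
    offset: int
    displacement: float
    index_a: int  # position of `residue` in domain A's Cα residue list


@dataclass
class RegisterShiftProfile:
    """Per-residue register offsets for domain A residues with both partners."""

    entries: list[ProfileEntry]
    n_missing: int  # residues of A lacking one of the two partners

    def offsets(self) -> np.ndarray:
        return np.array([e.offset for e in self.entries], dtype=int)


@dataclass
class SlippageSegment:
    """A maximal run of consecutive residues sharing one nonzero offset."""

    start_residue: Residue
    end_residue: Residue
    offset: int
    length: int
    mean_displacement: float

    def as_dict(self) -> dict:
        return {
            "start": self.start_residue.label,
            "end": self.end_residue.label,
            "offset": self.offset,
            "length": self.length,
            "mean_displacement_A": round(self.mean_displacement, 3),
        }


def dual_rmsd(
    domain_a: Domain,
    domain_b: Domain,
    config: AlignmentConfig | None = None,
    refit_chemical: bool = False,
) -> DualRmsd:
    """Topological RMSD and chemical RMSD of two domains in a shared frame.

    The chemical pairs are by default evaluated under the *topological*
    superposition without refitting, so the two numbers are directly
    comparable: both measure deviations in the common-fold frame.
    ``refit_chemical=True`` instead performs an independent Kabsch fit on
    the chemical pairs.
    """
    topo, sup = topological_alignment(domain_a, domain_b, config)
    chem = chemical_correspondence(domain_a, domain_b)
    ca, cb = chem.paired_coords()
    if refit_chemical:
        rmsd_chem = kabsch_superpose(ca, cb).rmsd
    else:
        rmsd_chem = rmsd_under_transform(ca, cb, sup)
    return DualRmsd(
        rmsd_topological=sup.rmsd,
        rmsd_chemical=rmsd_chem,
        n_topological=len(topo.pairs),
        n_chemical=len(chem.pairs),
        equivalenced_fraction=topo.equivalenced_fraction,
    )


def register_profile(
    chem_corr: Correspondence, topo_corr: Correspondence
) -> RegisterShiftProfile:
    """Per-residue sequence-register offsets between the two correspondences.

    For each residue of domain A paired in both correspondences, the offset
    is the alignment-column index of its topological partner minus that of
    its chemical partner (both indices into domain B's modeled residue
    list). The displacement is the distance between the two partner Cα
    positions in domain B's own frame. Residues lacking either partner are
    omitted and counted in ``n_missing``.
    """
    if chem_corr.domain_a is not topo_corr.domain_a or chem_corr.domain_b is not topo_corr.domain_b:
        raise CorrespondenceError("profile requires both correspondences on the same domain pair")
    chem_map = chem_corr.partner_of_a()
    topo_map = topo_corr.partner_of_a()
    res_a = chem_corr._res_a
    res_b = chem_corr._res_b
    entries: list[ProfileEntry] = []
    n_missing = 0
    for ia in range(len(res_a)):
        if ia in chem_map and ia in topo_map:
            jc, jt = chem_map[ia], topo_map[ia]
            disp = float(np.linalg.norm(res_b[jt].ca.coords - res_b[jc].ca.coords))
            entries.append(
                ProfileEntry(
                    residue=res_a[ia],
                    topological_partner=res_b[jt],
                    chemical_partner=res_b[jc],
                    offset=jt - jc,
                    displacement=disp,
                    index_a=ia,
                )
            )
        else:
            n_missing += 1
    if not entries:
        raise CorrespondenceError(
            "disjoint coverage: no residue has both a chemical and a topological partner"
        )
    return RegisterShiftProfile(entries=entries, n_missing=n_missing)


def call_segments(profile: RegisterShiftProfile, min_run: int = 3) -> list[SlippageSegment]:
    """Maximal constant-offset runs of length ≥ ``min_run`` with nonzero offset.

    Runs require consecutive profile entries (a residue missing from the
    profile breaks the run). The default ``min_run=3`` reflects that one
    β-strand turn is the smallest biologically meaningful slip unit.
    """
    if not profile.entries:
        raise CorrespondenceError("empty register-shift profile")
    segments: list[SlippageSegment] = []
    run: list[ProfileEntry] = []

    def flush() -> None:
        if run and run[0].offset != 0 and len(run) >= min_run:
            segments.append(
                SlippageSegment(
                    start_residue=run[0].residue,
                    end_residue=run[-1].residue,
                    offset=run[0].offset,
                    length=len(run),
                    mean_displacement=float(np.mean([e.displacement for e in run])),
                )
            )

    for entry in profile.entries:
        if run and (entry.offset != run[-1].offset or entry.index_a != run[-1].index_a + 1):
            flush()
            run = []
        run.append(entry)
    flush()
    return segments


def profile_to_frame(profile: RegisterShiftProfile) -> pd.DataFrame:
    """One row per residue: id, partners, register offset, displacement (Å)."""
    return pd.DataFrame(
        {
            "residue": [e.residue.label for e in profile.entries],
            "topological_partner": [e.topological_partner.label for e in profile.entries],
            "chemical_partner": [e.chemical_partner.label for e in profile.entries],
            "offset": [e.offset for e in profile.entries],
            "displacement_A": [round(e.displacement, 3) for e in profile.entries],
        }
    )
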