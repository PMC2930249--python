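"""Idealized two-sheet β-sandwich Cα-trace generator.

The generator emulates the geometry the slippage analysis runs on — an
Ig-like domain: two stacked β-sheets (default 4 + 3 antiparallel strands)
connected by loops, with canonical β-strand axial rise (3.3 Å/residue) and a
±0.3 Å pleat. It produces a baseline domain and, via ``shift_segments``, a
"twin" in which a contiguous run of residues slides by k positions along
the fixed spatial scaffold — the same fold built from a shifted sequence
register, i.e. a piston-like β-strand slip. The k residues displaced off
the scaffold by the slide are omitted from the twin's chain, mirroring how
a lengthened, disordered loop absorbs the register change in real
structures.

Every output is deterministic given the spec's seed; coordinates, sequence
and B-factors are reproducible bitwise. A GroundTruth record carries the
true residue→scaffold-position map and the register offsets a profile
comparison against the unshifted baseline should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    AtomRecord,
    Chain,
    ONE_TO_THREE,
    Residue,
    StructureError,
    StructureModel,
)

__all__ = ["SyntheticDomainSpec", "GroundTruth", "generate_domain", "generate_heterodimer"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticDomainSpec:
    """Parameters of one synthetic β-sandwich domain.

    ``shift_segments`` is a list of ``(start, end, k)`` in residue numbers
    (1-based, inclusive): residues start..end are placed k scaffold
    positions towards the N terminus (k > 0) or C terminus (k < 0).
    ``noise_seed`` defaults to ``seed``; give twins distinct noise seeds to
    make their coordinate noise independent while sharing scaffold and
    sequence.
    """

    sheet_strands: tuple[int, int] = (4, 3)
    strand_length: int = 8
    axial_rise: float = 3.3
    pleat: float = 0.3
    inter_strand_spacing: float = 4.8
    inter_sheet_spacing: float = 10.0
    loop_length: int = 4
    shift_segments: list[tuple[int, int, int]] = field(default_factory=list)
    noise_sigma: float = 0.0
    b_profile: str = "constant"  # constant | sheet_gradient
    b_base: float = 30.0
    b_sheet_delta: float = 15.0
    seed: int = 0
    noise_seed: int | None = None

    @property
    def n_strands(self) -> int:
        return sum(self.sheet_strands)

    @property
    def n_residues(self) -> int:
        return self.n_strands * self.strand_length + (self.n_strands - 1) * self.loop_length

    def validate(self) -> None:
        if self.noise_sigma < 0:
            raise StructureError("noise_sigma must be ≥ 0")
        if self.b_profile not in ("constant", "sheet_gradient"):
            raise StructureError(f"unknown b_profile {self.b_profile!r}")
        n = self.n_residues
        zones: list[tuple[int, int]] = []
        for start, end, k in self.shift_segments:
            if not (1 <= start <= end <= n):
                raise StructureError(f"shift segment ({start},{end}) outside chain 1..{n}")
            if abs(k) >= self.strand_length:
                raise StructureError(f"|k|={abs(k)} must be below strand_length")
            if k == 0:
                raise StructureError("shift segment with k=0 is a no-op; remove it")
            lo = start - k if k > 0 else start
            hi = end if k > 0 else end - k
            if lo < 1 or hi > n:
                raise StructureError(
                    f"shift segment ({start},{end},{k:+d}) collides with a chain terminus"
                )
            zones.append((lo, hi))
        zones.sort()
        for (_, e1), (s2, _) in zip(zones, zones[1:]):
            if s2 <= e1:
                raise StructureError("shift segments (incl. displaced zones) overlap")


@dataclass
class GroundTruth:
    """What the generator actually built.

    position_of : residue number → scaffold position index (0-based).
    omitted : residue numbers absent from this domain's chain.
    profile_offsets : the register offset a chemical-vs-topological profile
        of (unshifted baseline as A) vs (this domain as B) should report for
        each baseline residue where both partners are defined.
    """

    position_of: dict[int, int]
    omitted: list[int]
    profile_offsets: dict[int, int]


def _scaffold(spec: SyntheticDomainSpec) -> np.ndarray:
    """Cα positions of the unshifted serpentine scaffold, one per residue."""
    n_bottom, n_top = spec.sheet_strands
    length, rise = spec.strand_length, spec.axial_rise
    pts: list[np.ndarray] = []
    for s in range(spec.n_strands):
        sheet = 0 if s < n_bottom else 1
        row = s if sheet == 0 else s - n_bottom
        z0 = sheet * spec.inter_sheet_spacing
        y = row * spec.inter_strand_spacing
        forward = s % 2 == 0
        strand = []
        for m in range(length):
            x = (m if forward else length - 1 - m) * rise
            pleat_dir = 1.0 if sheet == 0 else -1.0
            z = z0 + pleat_dir * spec.pleat * (1 if m % 2 == 0 else -1)
            strand.append(np.array([x, y, z]))
        if s > 0:
            pts.extend(_loop(pts[-1], strand[0], spec.loop_length))
        pts.extend(strand)
    return np.vstack(pts)


def _loop(p_from: np.ndarray, p_to: np.ndarray, n: int) -> list[np.ndarray]:
    """n loop residues on an arc bulging outward from the chord."""
    chord = p_to - p_from
    # bulge perpendicular to the chord, biased along ±x (beyond the sheet edge)
    ref = np.array([1.0, 0.0, 0.0]) if abs(chord[0]) < 0.9 * np.linalg.norm(chord) else np.array([0.0, 0.0, 1.0])
    perp = ref - chord * (ref @ chord) / (chord @ chord)
    norm = np.linalg.norm(perp)
    perp = perp / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    sign = 1.0 if p_from[0] >= 0 else -1.0
    out = []
    for i in range(1, n + 1):
        t = i / (n + 1)
        out.append(p_from + t * chord + sign * 3.0 * np.sin(np.pi * t) * perp)
    return out


def _sequence(spec: SyntheticDomainSpec) -> str:
    """Pseudo-random sequence with no letter repeated within a 6-residue window.

    The window constraint makes the twin/baseline global alignment have a
    unique optimum, so gap placement around an omitted run is never
    ambiguous and noiseless register recovery is exact.
    """
    rng = np.random.default_rng([int(spec.seed) % (2**31), 101])
    letters: list[str] = []
    for _ in range(spec.n_residues):
        recent = set(letters[-6:])
        choices = [c for c in AMINO_ACIDS if c not in recent]
        letters.append(choices[int(rng.integers(len(choices)))])
    return "".join(letters)


def _bfactor(spec: SyntheticDomainSpec, z: float) -> float:
    if spec.b_profile == "constant":
        return spec.b_base
    top = z >= spec.inter_sheet_spacing / 2.0
    return spec.b_base + (spec.b_sheet_delta if top else 0.0)


def generate_domain(spec: SyntheticDomainSpec) -> tuple[StructureModel, GroundTruth]:
    """Build one synthetic domain and its ground truth.

    Register shifts slide residue identities along the fixed scaffold; the
    displaced residues are omitted from the chain. Gaussian coordinate noise
    (``noise_sigma``) is added i.i.d. per atom afterwards. Serine residues
    get a pseudo-OG atom 2.4 Å from the Cα so hydrogen-bond geometry is
    exercisable on synthetic structures.
    """
    spec.validate()
    scaffold = _scaffold(spec)
    seq = _sequence(spec)
    n = spec.n_residues

    position_of: dict[int, int] = {i: i - 1 for i in range(1, n + 1)}
    omitted: set[int] = set()
    profile_offsets: dict[int, int] = {}
    for start, end, k in spec.shift_segments:
        for i in range(start, end + 1):
            position_of[i] = i - 1 - k
        if k > 0:
            omitted.update(range(start - k, start))
            lo, hi = start, end - k
        else:
            omitted.update(range(end + 1, end - k + 1))
            lo, hi = start - k, end
        for i in range(lo, hi + 1):
            profile_offsets[i] = k

    noise_seed = spec.seed if spec.noise_seed is None else spec.noise_seed
    noise_rng = np.random.default_rng([int(noise_seed) % (2**31), 211])

    chain = Chain(id="A")
    serial = 0
    for i in range(1, n + 1):
        if i in omitted:
            continue
        pos = scaffold[position_of[i]].copy()
        one = seq[i - 1]
        b = _bfactor(spec, scaffold[position_of[i]][2])
        res = Residue(
            chain_id="A",
            seq_number=i,
            insertion_code="",
            res_name=ONE_TO_THREE[one],
        )
        serial += 1
        atoms_xyz = [("CA", "C", pos)]
        if one == "S":
            og_dir = np.array([0.0, 0.0, 1.0 if pos[2] < spec.inter_sheet_spacing / 2 else -1.0])
            atoms_xyz.append(("OG", "O", pos + 2.4 * og_dir))
        for name, element, xyz in atoms_xyz:
            coords = xyz + noise_rng.normal(0.0, spec.noise_sigma, 3) if spec.noise_sigma else xyz
            res.atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=element,
                    alt_loc="",
                    coords=coords,
                    occupancy=1.0,
                    b_factor=b,
                )
            )
            serial += 1
        chain.residues.append(res)
    model = StructureModel(id=f"synthetic-{spec.seed}", chains=[chain], source_format="pdb")
    truth = GroundTruth(
        position_of={i: position_of[i] for i in position_of if i not in omitted},
        omitted=sorted(omitted),
        profile_offsets=profile_offsets,
    )
    return model, truth


def generate_heterodimer(
    spec_a: SyntheticDomainSpec,
    spec_b: SyntheticDomainSpec,
    interface_gap: float = 5.0,
) -> StructureModel:
    """Two synthetic domains with facing sheets separated by ``interface_gap`` Å.

    Domain B is flipped so its bottom sheet faces A's top sheet; the gap is
    measured between the two facing sheet planes. Placements that clash
    (any inter-domain atom pair below 2 Å) are rejected.
    """
    model_a, _ = generate_domain(spec_a)
    model_b, _ = generate_domain(spec_b)
    atoms_a = model_a.atoms()
    coords_a = np.vstack([a.coords for a in atoms_a])
    atoms_b = model_b.atoms()
    coords_b = np.vstack([a.coords for a in atoms_b])
    # flip B about the x-axis (z -> -z, y -> -y) then translate above A
    flipped = coords_b * np.array([1.0, -1.0, -1.0])
    shift_z = coords_a[:, 2].max() + interface_gap - flipped[:, 2].min()
    # roughly centre the sheets over each other in y
    shift_y = coords_a[:, 1].mean() - flipped[:, 1].mean()
    flipped = flipped + np.array([0.0, shift_y, shift_z])
    from scipy.spatial import cKDTree

    if cKDTree(coords_a).query(flipped, k=1)[0].min() < 2.0:
        raise StructureError(
            f"heterodimer placement at gap {interface_gap} Å clashes (< 2 Å contact)"
        )
    chain_b = Chain(id="B")
    k = 0
    for res in model_b.chains[0].residues:
        nr = Residue(
            chain_id="B",
            seq_number=res.seq_number,
            insertion_code=res.insertion_code,
            res_name=res.res_name,
        )
        for a in res.atoms:
            nr.atoms.append(
                AtomRecord(
                    serial=a.serial,
                    name=a.name,
                    element=a.element,
                    alt_loc=a.alt_loc,
                    coords=flipped[k],
                    occupancy=a.occupancy,
                    b_factor=a.b_factor,
                )
            )
            k += 1
        chain_b.residues.append(nr)
    return StructureModel(
        id=f"synthetic-dimer-{spec_a.seed}-{spec_b.seed}",
        chains=[model_a.chains[0], chain_b],
        source_format="pdb",
    )
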