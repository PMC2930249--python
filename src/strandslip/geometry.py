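"""Rigid-body superposition, RMSD and hydrogen-bond geometry.

The superposition is the classical least-squares fit of one point set onto
another (Kabsch): subtract centroids, SVD of the covariance, sign-correct the
smallest singular vector so the rotation is proper (determinant +1, no
reflection — chirality must be preserved for protein coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AtomRecord

__all__ = [
    "SuperpositionResult",
    "HBondCriteria",
    "kabsch_superpose",
    "rmsd_under_transform",
    "detect_hbond",
]


class GeometryError(ValueError):
    pass


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping a moving point set onto a reference.

    ``apply(x)`` computes ``x @ rotation.T + translation``; ``rmsd`` is the
    minimized Cα (or all-atom) RMSD over the ``n_pairs`` fitted pairs.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class HBondCriteria:
    """Heavy-atom distance window for hydrogen-bond detection.

    Deposited crystal structures lack hydrogens, so the criterion is
    donor–acceptor distance only: 2.4 Å (below which the contact is a clash
    or covalent) to 3.5 Å (conventional upper bound).
    """

    max_donor_acceptor_distance: float = 3.5
    min_distance: float = 2.4

    def __post_init__(self) -> None:
        if not self.min_distance < self.max_donor_acceptor_distance:
            raise GeometryError("H-bond criteria: min distance must be below max")


def _check_pairing(coords_a: np.ndarray, coords_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or b.ndim != 2 or b.shape[1] != 3:
        raise GeometryError("coordinates must be N×3 arrays")
    if a.shape[0] != b.shape[0]:
        raise GeometryError(f"paired coordinate sets differ in length: {a.shape[0]} vs {b.shape[0]}")
    return a, b


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares fit of ``coords_b`` (moving) onto ``coords_a`` (reference).

    Parameters are paired row-wise; at least 3 non-collinear points are
    required. Returns the proper rotation, translation and minimized RMSD.
    """
    a, b = _check_pairing(coords_a, coords_b)
    n = a.shape[0]
    if n < 3:
        raise GeometryError(f"superposition needs at least 3 point pairs, got {n}")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    pa = a - cen_a
    pb = b - cen_b
    if np.linalg.matrix_rank(pa, tol=1e-8) < 2 or np.linalg.matrix_rank(pb, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) point set: rotation is underdetermined")
    h = pb.T @ pa
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cen_a - rot @ cen_b
    moved = b @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_pairs=n)


def rmsd_under_transform(
    coords_a: np.ndarray, coords_b: np.ndarray, superposition: SuperpositionResult
) -> float:
    """RMSD of ``coords_b`` against ``coords_a`` in an externally supplied frame.

    No re-optimization is performed: the transform comes from ``superposition``
    (typically fitted on a different residue pairing), so the value is always
    ≥ the Kabsch RMSD of this pairing.
    """
    a, b = _check_pairing(coords_a, coords_b)
    moved = superposition.apply(b)
    return float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))


def detect_hbond(
    atom_1: AtomRecord, atom_2: AtomRecord, criteria: HBondCriteria | None = None
) -> tuple[bool, float]:
    """Distance-only hydrogen-bond test between two heavy atoms.

    Both atoms must be plausible donors/acceptors (N or O). Returns
    ``(bonded, distance)``; never raises on a non-bonded geometry.
    """
    criteria = criteria or HBondCriteria()
    for atom in (atom_1, atom_2):
        if atom.element not in ("N", "O"):
            raise GeometryError(
                f"atom {atom.name} ({atom.element}) is not a plausible donor/acceptor"
            )
    dist = float(np.linalg.norm(atom_1.coords - atom_2.coords))
    bonded = criteria.min_distance <= dist <= criteria.max_donor_acceptor_distance
    return bonded, dist
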