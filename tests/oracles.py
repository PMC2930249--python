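"""Independent oracles used to validate the package's own implementations.

Each oracle deliberately takes a different computational route from the code
it checks: superposition via the quaternion characteristic-polynomial method
(the package uses SVD), alignment via exhaustive enumeration (the package
uses biopython's dynamic programming), SASA via closed-form sphere-cap
geometry (the package uses numerical quadrature).
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum RMSD of two paired point sets via the quaternion method.

    Builds the 4×4 key matrix from the covariance of the centered sets; the
    largest eigenvalue lambda gives the minimized residual
    E = G_a + G_b − 2·lambda, with the proper-rotation constraint built into
    the quaternion parameterization.
    """
    a = np.asarray(coords_a, float) - np.mean(coords_a, axis=0)
    b = np.asarray(coords_b, float) - np.mean(coords_b, axis=0)
    n = a.shape[0]
    m = b.T @ a  # 3x3 covariance, moving (b) onto reference (a)
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    ga = float(np.sum(a * a))
    gb = float(np.sum(b * b))
    e = max(0.0, ga + gb - 2.0 * lam)
    return float(np.sqrt(e / n))


def brute_force_global_alignments(
    seq_a: str, seq_b: str, match: float = 1.0, mismatch: float = 0.0, gap: float = -1.0
) -> tuple[float, list[list[tuple[int, int]]]]:
    """All optimal global alignments of two short sequences by enumeration.

    Returns the optimal score and, for each optimal alignment, the list of
    aligned columns as index pairs. Exponential — intended for sequences of
    a dozen residues.
    """
    best: dict[str, object] = {"score": -np.inf, "alignments": []}

    def recurse(i: int, j: int, score: float, cols: list[tuple[int, int]]) -> None:
        if i == len(seq_a) and j == len(seq_b):
            if score > best["score"] + 1e-12:
                best["score"] = score
                best["alignments"] = [list(cols)]
            elif abs(score - best["score"]) <= 1e-12:
                best["alignments"].append(list(cols))
            return
        # bound: even all-matches cannot beat the best
        remaining = min(len(seq_a) - i, len(seq_b) - j)
        if score + remaining * match < best["score"] - 1e-12:
            return
        if i < len(seq_a) and j < len(seq_b):
            s = match if seq_a[i] == seq_b[j] else mismatch
            cols.append((i, j))
            recurse(i + 1, j + 1, score + s, cols)
            cols.pop()
        if i < len(seq_a):
            recurse(i + 1, j, score + gap, cols)
        if j < len(seq_b):
            recurse(i, j + 1, score + gap, cols)

    recurse(0, 0, 0.0, [])
    return float(best["score"]), best["alignments"]  # type: ignore[return-value]


def sphere_cap_area(radius: float, cap_height: float) -> float:
    """Area of a spherical cap of height h on a sphere of radius r: 2πrh."""
    return 2.0 * np.pi * radius * cap_height


def two_sphere_sasa(r1: float, r2: float, d: float) -> tuple[float, float]:
    """Exact accessible areas of two intersecting spheres (extended radii).

    For spheres of radii r1, r2 with center distance d, each loses the cap
    cut off by the radical plane. Returns the two accessible areas.
    """
    if d >= r1 + r2:
        return 4 * np.pi * r1**2, 4 * np.pi * r2**2
    # distance from center 1 to the intersection plane
    x1 = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h1 = r1 - x1
    h2 = r2 - (d - x1)
    a1 = 4 * np.pi * r1**2 - sphere_cap_area(r1, h1)
    a2 = 4 * np.pi * r2**2 - sphere_cap_area(r2, h2)
    return a1, a2
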