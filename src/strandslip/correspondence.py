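"""Residue correspondences between two domains.

Two pairings of the same pair of domains are contrasted throughout the
package:

* **chemical** — residues paired by sequence identity (global alignment of
  the one-letter sequences). For sequence-identical constructs this pairs
  each modeled residue with its chemically identical counterpart regardless
  of author-numbering offsets.
* **topological** — residues paired by spatial equivalence, ignoring
  sequence register: an iterative structure-based alignment that alternates
  Kabsch superposition on the current pair set with a monotone dynamic-
  programming re-pairing scored on inter-structure Cα–Cα distances.

When a β-sheet register has slipped, the two correspondences disagree over
the slipped segment; that disagreement is what :mod:`strandslip.slippage`
quantifies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy.spatial.distance import cdist

from .geometry import GeometryError, SuperpositionResult, kabsch_superpose
from .model import Domain, Residue

__all__ = [
    "AlignmentConfig",
    "Correspondence",
    "chemical_correspondence",
    "topological_alignment",
]


class CorrespondenceError(ValueError):
    pass


@dataclass
class AlignmentConfig:
    """Parameters of the iterative topological alignment.

    d_cut : Å — distance below which two Cα positions are considered
        spatially equivalent; 3.8 Å, one Cα–Cα bond length, is standard
        structure-alignment practice.
    gap : score units — dynamic-programming gap penalty.
    max_iter : iteration cap; convergence is declared when the pair *set*
        is unchanged (not the RMSD, to avoid floating-point flutter).
    """

    d_cut: float = 3.8
    gap: float = 1.0
    max_iter: int = 50


@dataclass
class Correspondence:
    """An ordered, crossing-free pairing between two domains.

    ``pairs`` holds index pairs into ``domain_a.ca_residues()`` and
    ``domain_b.ca_residues()``; ``equivalenced_fraction`` is the paired share
    of the smaller domain's residues.
    """

    domain_a: Domain
    domain_b: Domain
    pairs: list[tuple[int, int]]
    method: str  # "chemical" | "topological"
    equivalenced_fraction: float
    converged: bool = True
    _res_a: list[Residue] = field(repr=False, default_factory=list)
    _res_b: list[Residue] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if not self._res_a:
            self._res_a = self.domain_a.ca_residues()
        if not self._res_b:
            self._res_b = self.domain_b.ca_residues()
        self._assert_monotone()

    def _assert_monotone(self) -> None:
        for (i1, j1), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            if i2 <= i1 or j2 <= j1:
                raise CorrespondenceError(
                    f"{self.method} correspondence has crossing pairs "
                    f"({i1},{j1}) -> ({i2},{j2})"
                )

    def residue_pairs(self) -> list[tuple[Residue, Residue]]:
        return [(self._res_a[i], self._res_b[j]) for i, j in self.pairs]

    def paired_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Paired Cα coordinate arrays (each n_pairs × 3)."""
        if not self.pairs:
            raise CorrespondenceError("no pairs in correspondence")
        a = np.vstack([self._res_a[i].ca.coords for i, _ in self.pairs])
        b = np.vstack([self._res_b[j].ca.coords for _, j in self.pairs])
        return a, b

    def partner_of_a(self) -> dict[int, int]:
        return dict(self.pairs)


def _identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def chemical_correspondence(domain_a: Domain, domain_b: Domain) -> Correspondence:
    """Pair residues by sequence identity via global alignment.

    Scoring is identity-based (match +1, mismatch 0, gap −1); pairs are the
    aligned identical-residue columns. Residues without a Cα atom are
    excluded (they cannot contribute geometry downstream).
    """
    res_a = domain_a.ca_residues()
    res_b = domain_b.ca_residues()
    if len(res_a) < 10 or len(res_b) < 10:
        raise CorrespondenceError(
            f"chemical correspondence needs ≥10 residues per domain "
            f"(got {len(res_a)}, {len(res_b)})"
        )
    seq_a = "".join(r.one_letter for r in res_a)
    seq_b = "".join(r.one_letter for r in res_b)
    alignment = _identity_aligner().align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    n_cols = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            n_cols += 1
            # nonstandard residues ('X') never count as chemically identical
            if seq_a[i] == seq_b[j] and seq_a[i] != "X":
                pairs.append((i, j))
    if n_cols and len(pairs) / n_cols < 0.30:
        warnings.warn(
            "sequence identity of aligned pairs below 30%: the chemical RMSD "
            "is poorly defined for such distant sequences",
            stacklevel=2,
        )
    fraction = len(pairs) / min(len(res_a), len(res_b))
    return Correspondence(
        domain_a=domain_a,
        domain_b=domain_b,
        pairs=pairs,
        method="chemical",
        equivalenced_fraction=fraction,
        _res_a=res_a,
        _res_b=res_b,
    )


def _monotone_repair(dist: np.ndarray, d_cut: float, gap: float) -> list[tuple[int, int]]:
    """Monotone pairing by semi-global dynamic programming.

    Score of pairing (i, j) is ``max(0, d_cut − d_ij)``; internal gaps cost
    ``gap`` per skipped residue; end gaps are free (the alignment is global
    over both chains but terminal overhangs are not penalized, preventing
    spurious terminal pairs). Pairs at distance > d_cut are dropped from the
    returned set.
    """
    n_a, n_b = dist.shape
    score = np.maximum(0.0, d_cut - dist)
    m = np.zeros((n_a + 1, n_b + 1))
    # 0 = diagonal, 1 = up (skip residue of A), 2 = left (skip residue of B)
    move = np.zeros((n_a + 1, n_b + 1), dtype=np.int8)
    for i in range(1, n_a + 1):
        diag = m[i - 1, :-1] + score[i - 1, :]
        up = m[i - 1, 1:] - gap
        row = m[i]
        for j in range(1, n_b + 1):
            left = row[j - 1] - gap
            best, mv = diag[j - 1], 0
            if up[j - 1] > best:
                best, mv = up[j - 1], 1
            if left > best:
                best, mv = left, 2
            row[j] = best
            move[i, j] = mv
    # free end gaps: start traceback at the best cell of the last row/column
    last_col = m[:, n_b]
    last_row = m[n_a, :]
    if last_col.max() >= last_row.max():
        i, j = int(last_col.argmax()), n_b
    else:
        i, j = n_a, int(last_row.argmax())
    pairs: list[tuple[int, int]] = []
    while i > 0 and j > 0:
        mv = move[i, j]
        if mv == 0:
            if dist[i - 1, j - 1] <= d_cut:
                pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif mv == 1:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def topological_alignment(
    domain_a: Domain,
    domain_b: Domain,
    config: AlignmentConfig | None = None,
) -> tuple[Correspondence, SuperpositionResult]:
    """Sequence-independent structural alignment of two domains.

    Algorithm: (1) seed the pair set from the chemical correspondence;
    (2) Kabsch-superpose domain B onto domain A over the current pairs;
    (3) rebuild the inter-structure Cα–Cα distance matrix in the superposed
    frame and re-derive a monotone correspondence by dynamic programming;
    (4) iterate until the pair set is unchanged or ``max_iter`` is reached.
    The returned superposition and RMSD are over the final pair set, and
    ``equivalenced_fraction`` is relative to the smaller domain.
    """
    config = config or AlignmentConfig()
    res_a = domain_a.ca_residues()
    res_b = domain_b.ca_residues()
    if len(res_a) < 20 or len(res_b) < 20:
        raise CorrespondenceError(
            f"topological alignment needs ≥20 Cα atoms per domain "
            f"(got {len(res_a)}, {len(res_b)})"
        )
    coords_a = np.vstack([r.ca.coords for r in res_a])
    coords_b = np.vstack([r.ca.coords for r in res_b])

    seed = chemical_correspondence(domain_a, domain_b)
    pairs = list(seed.pairs)
    if len(pairs) < 3:
        raise CorrespondenceError("chemical seed correspondence has fewer than 3 pairs")

    converged = False
    sup = None
    for _ in range(config.max_iter):
        ia = [i for i, _ in pairs]
        ib = [j for _, j in pairs]
        try:
            sup = kabsch_superpose(coords_a[ia], coords_b[ib])
        except GeometryError as exc:
            raise CorrespondenceError(f"superposition failed during iteration: {exc}") from exc
        dist = cdist(coords_a, sup.apply(coords_b))
        new_pairs = _monotone_repair(dist, config.d_cut, config.gap)
        if len(new_pairs) < 3:
            break  # keep best-so-far rather than collapse
        if new_pairs == pairs:
            converged = True
            break
        pairs = new_pairs

    ia = [i for i, _ in pairs]
    ib = [j for _, j in pairs]
    sup = kabsch_superpose(coords_a[ia], coords_b[ib])
    corr = Correspondence(
        domain_a=domain_a,
        domain_b=domain_b,
        pairs=pairs,
        method="topological",
        equivalenced_fraction=len(pairs) / min(len(res_a), len(res_b)),
        converged=converged,
        _res_a=res_a,
        _res_b=res_b,
    )
    return corr, sup
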