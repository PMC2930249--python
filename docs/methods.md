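# Methods

## The problem and the statistic

Two crystal structures of the same (or sequence-identical) β-sandwich
domain can differ not by unfolding but by *register slippage*: between two
anchor turns, every residue slides k positions along the strands, so the
same spatial scaffold positions are occupied by chemically different
residues. A single superposition cannot expose this — the fold superposes
well either way. strandslip therefore computes two residue pairings of the
same domain pair and contrasts them.

**Chemical correspondence.** Global alignment of the one-letter sequences
with identity scoring (match +1, mismatch 0, gap −1, end gaps penalized);
the pairs are the aligned identical-residue columns. For sequence-identical
constructs this pairs every modeled residue with its counterpart regardless
of author-numbering offsets. Domains with fewer than 10 residues are
rejected; aligned identity below 30% raises a warning because a "chemical
RMSD" between distant homologues is poorly defined. Nonstandard residues
map to `X` and never pair chemically, though their coordinates participate
in all geometry.

**Topological correspondence.** An iterative sequence-independent
structural alignment: (1) seed with the chemical pairs (the intended
comparisons are between sequence-identical or closely homologous Ig
domains, so the seed is always sensible); (2) Kabsch-superpose B onto A
over the current pairs; (3) rebuild the Cα–Cα inter-structure distance
matrix in that frame and re-derive a monotone pairing by dynamic
programming with pair score max(0, d_cut − d_ij) and linear gap penalty g,
global over both chains but with free end gaps (no spurious terminal
pairs); (4) iterate to a fixed point of the pair *set* (not the RMSD,
which is subject to floating-point flutter), capped at `max_iter`.
Defaults: d_cut = 3.8 Å (one Cα–Cα bond length — the conventional
"equivalent position" radius in structure alignment), g = 1.0 score unit,
max_iter = 50. Pairs farther than d_cut in the final frame are dropped.
The reported `equivalenced_fraction` is paired residues over the smaller
domain's residue count. Non-sequential (topology-crossing) alignments are
out of scope: slippage is a sequential phenomenon, and the monotone DP
enforces that.

**Dual RMSD.** `rmsd_topological` is the Kabsch RMSD over the final
topological pairs. `rmsd_chemical` is the RMSD of the chemical pairs
evaluated **in the topological superposition frame with no refit**: both
numbers then measure displacement in the common-fold frame, and their gap
is the slippage signal. Refitting the chemical pairs independently would
conflate the two statistics; it is still available behind
`refit_chemical=True` for sensitivity analysis (it can only lower the
chemical value, which a test asserts).

**Register profile and segments.** For each residue of A with both
partners, the offset is the index of the topological partner minus the
index of the chemical partner, both in *alignment-column space* (positions
in B's modeled residue list) — author-numbering offsets between constructs
therefore cannot masquerade as slippage. The displacement is the distance
between the two partner Cα positions in B's own frame. Slipped segments
are maximal runs of constant nonzero offset with length ≥ `min_run`
(default 3: one strand turn is the smallest biologically meaningful slip);
residues missing from the profile break runs.

## Superposition

Kabsch via SVD of the 3×3 covariance of the centered point sets, with the
smallest singular vector sign-corrected so the rotation is always proper
(determinant +1) — chirality is never inverted. Fewer than 3 pairs, or
rank-deficient (collinear) sets, are hard errors. `rmsd_under_transform`
evaluates a pairing in an externally supplied frame without
re-optimization and is therefore never below the Kabsch RMSD of that
pairing. The test suite checks the implementation against an independently
implemented quaternion characteristic-polynomial oracle and against 1000
random rotations for optimality.

## Surface areas, contacts, B-factors

Shrake–Rupley SASA with a deterministic golden-spiral lattice (default 960
points per atom; no random number use, so results are identical across
platforms). Radii are Chothia-style united-atom values (C 1.70, N 1.55,
O 1.52, S 1.80 Å), probe 1.4 Å; an element without a radius entry is a
hard error naming the atom. At 960 points the quadrature is converged to
<1% against 3840 points, and totals agree with an independent
implementation (biotite) to ~0.1% on identical radii.

Buried interface area is SASA(A) + SASA(B) − SASA(A∪B), summed over both
faces (not halved) — the convention that yields the ~1450–1500 Å²
magnitudes customary for Vα/Vβ Ig-domain interfaces. Hydrogens are dropped
at parse time; waters and heteroatoms (glycans included) are excluded from
interface, RMSD and B-factor computations by default.

Hydrogen bonds are detected by heavy-atom distance only (donor/acceptor N
or O, default window 2.4–3.5 Å): deposited crystal structures at ~2 Å
resolution lack hydrogens, so an angular term is not computable; 3.5 Å is
the conventional upper bound.

B-factor summaries are unweighted arithmetic means of the isotropic B over
the selected non-hydrogen protein atoms. Crystal-contact listing pairs
residues across two disjoint sets with any inter-atomic distance ≤ 4 Å; it
operates on the copies present in the deposited asymmetric unit
(symmetry mates are not generated).

## Structure I/O policy

Parsing is delegated to gemmi (PDB fixed-column and mmCIF); a light
fixed-column validator rejects malformed ATOM/HETATM records by line
number, since gemmi itself is deliberately lenient. Alternate locations
are resolved to a single conformer — highest occupancy, ties to the
alphabetically first altloc — because single-conformer geometry is
required downstream. Author residue numbering with insertion codes is the
public convention (inclusive ranges), matching how crystallographic papers
quote residues. Writing is fixed-column PDB; a write→read round trip
reproduces coordinates to 3 decimals and B to 2 decimals (format
precision).

## The synthetic generator

`SyntheticDomainSpec` builds an idealized Ig-like β-sandwich Cα trace: two
sheets (4 + 3 antiparallel strands, 8 residues each by default), axial
rise 3.3 Å/residue with a ±0.3 Å pleat, 4.8 Å between strands, 10 Å
between sheets, 4-residue connecting loops on outward arcs. These are
canonical β-sheet dimensions; the 3.3 Å rise fixes the closed-form
expectation that a k-residue slip displaces chemical partners by ≈ k×3.3 Å
within a strand. Serine residues get a pseudo-OG atom 2.4 Å from the Cα so
hydrogen-bond geometry is exercisable synthetically; B-factors are either
constant (30 Å²) or `sheet_gradient` (top sheet +15 Å², emulating a mobile
top sheet).

A register shift (start, end, k) keeps the scaffold fixed and places twin
residues start..end at scaffold positions start−k..end−k; the k residues
displaced off the scaffold are omitted from the twin's chain, the same way
a lengthened disordered loop absorbs the register change in real
structures. This construction keeps the scaffold single-occupancy, so at
σ=0 the expected profile is exact: offset k on the overlap zone, 0
elsewhere, and segment recovery can be asserted without tolerance.
Sequences are pseudo-random 20-letter strings, identical between a domain
and its twin, generated with the constraint that no letter repeats within
a 6-residue window — this makes the twin/baseline global alignment have a
unique optimum, so gap placement around the omitted run is never ambiguous.
Gaussian coordinate noise (i.i.d. per atom, after the shift) is drawn from
a `noise_seed` that defaults to the spec seed; twins should be given a
distinct noise seed so the two structures' errors are uncorrelated. All
output is bitwise deterministic given the seeds.

What the generator does *not* emulate: side chains beyond the pseudo-OG,
realistic backbone dihedrals, strand twist and shear, sequence-dependent
packing, and crystal-lattice environment. Passing tests on synthetic data
therefore demonstrate the correctness of the algorithms (pairing,
superposition, offset bookkeeping, area quadrature) under controlled
geometry — not robustness to every distortion of real crystal structures.
Validation against deposited structures is a separate test group that
requires downloading the reference entries (`scripts/fetch_reference.py`);
those tests report published-value comparisons (asymmetric-unit copy
agreement, Vα/Vβ interface areas, the constant-domain dual RMSD, mean
B-factors, a DE-loop serine hydrogen bond).

## Problem sizes and numerical choices

The default test and acceptance runs use 80-residue domains (108 when a
12-residue strand length is needed to host |k| ≤ 3 slips inside one
strand), 100 replicates for recovery-rate estimates, and 960-point SASA
quadrature — sizes chosen so each statistic is stable at the tolerances
asserted while the whole suite runs in seconds. Convergence of the
iterative alignment is declared on pair-set equality; if `max_iter` is
exhausted the best-so-far correspondence is returned with
`converged=False`. Ties in the DP favor the diagonal (pairing over
gapping). Degenerate inputs — empty selections, < 3 superposition pairs,
collinear point sets, overlapping atom sets in interface calculations —
are hard errors rather than silent results.

## Known limitations

- The equivalence criterion (d_cut) is a free parameter; the fraction of
  equivalenced residues reported for real domain pairs depends on it, and
  published fractions from other alignment programs with unpublished
  criteria can only be matched approximately.
- The chemical RMSD's frame convention (shared topological frame, no
  refit) is one of two defensible readings; the alternative is exposed as
  a flag and always gives a smaller value.
- Monotone DP cannot represent topology-crossing equivalences.
- Crystal contacts are intra-asymmetric-unit only.
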