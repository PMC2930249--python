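# strandslip

Detection and quantification of **β-strand register slippage** between two
conformations of a protein domain.

Some β-sheet proteins are metamorphic: the same sequence can occupy a
β-sandwich scaffold in more than one sequence register, with a contiguous
run of residues slid by *k* positions along the strands ("piston-like"
slippage) while the global fold is unchanged. The classic case is the
T-cell receptor α-chain constant (Cα) domain, whose loosely packed top
sheet permits exactly this rearrangement. Detecting slippage requires
contrasting two different residue pairings of the same pair of structures:

* **chemical correspondence** — residues paired by sequence identity
  (global alignment of the one-letter sequences);
* **topological correspondence** — residues paired by spatial equivalence,
  from an iterative sequence-independent structural alignment (Kabsch
  superposition alternating with monotone dynamic-programming re-pairing on
  the inter-structure Cα–Cα distance matrix).

A conserved fold (low RMSD over topological pairs) combined with a large
RMSD of the *chemical* pairs evaluated in the same superposition frame is
the slippage signature; the per-residue integer offset between each
residue's two partners localizes the slipped segments and gives the shift
*k*. The package also provides deterministic Shrake–Rupley SASA and buried
interface areas, crystal-contact listing, B-factor summaries, heavy-atom
hydrogen-bond checks, and a synthetic Ig-fold β-sandwich generator with
known ground-truth register shifts so the entire pipeline is testable
without downloading any structures.

## Worked example

```python
from strandslip import (
    Domain, SyntheticDomainSpec, generate_domain,
    chemical_correspondence, topological_alignment,
    dual_rmsd, register_profile, call_segments,
)

# baseline domain and a twin whose residues 27-32 slipped by k=+2
base, _  = generate_domain(SyntheticDomainSpec(seed=1))
twin, _  = generate_domain(SyntheticDomainSpec(seed=1, shift_segments=[(27, 32, 2)],
                                               noise_sigma=0.2, noise_seed=99))
dom_a = Domain("baseline", base.chains[0].residues)
dom_b = Domain("twin", twin.chains[0].residues)

dual = dual_rmsd(dom_a, dom_b)
print(dual.as_dict())

chem = chemical_correspondence(dom_a, dom_b)
topo, _ = topological_alignment(dom_a, dom_b)
for seg in call_segments(register_profile(chem, topo)):
    print(seg.as_dict())
```

Output:

```
{'rmsd_topological_A': 0.33, 'rmsd_chemical_A': 1.825, 'n_topological': 78,
 'n_chemical': 78, 'equivalenced_fraction': 1.0}
{'start': 'A/ASN27', 'end': 'A/SER30', 'offset': 2, 'length': 4,
 'mean_displacement_A': 6.588}
```

The fold superposes at the coordinate-noise scale (0.33 Å ≈ σ√3 for a
noiseless baseline against a twin with 0.2 Å per-coordinate noise), yet
chemically identical residues sit 1.8 Å apart on average in that frame —
and the profile localizes the cause: residues 27–30 occupy strand positions
two register steps away, displaced by ~6.6 Å ≈ k × 3.3 Å (the β-strand
axial rise).

The same analysis runs on real coordinate files through the CLI:

```sh
strandslip compare config.yaml -o report     # JSON + per-residue TSV + log
strandslip generate --seed 2 --shift 27:32:2 # synthetic PDB + ground truth
strandslip sasa structure.pdb --chain A
strandslip bfactor structure.pdb --chain A --ranges 116-205
```

where `config.yaml` names the two structures, chains and residue ranges,
and optionally buried-surface, B-factor and hydrogen-bond analyses (all
cutoffs — `d_cut`, `gap_penalty`, `probe_radius`, `hbond_min`/`hbond_max`,
`min_run` — are config keys).

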