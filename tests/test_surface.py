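import numpy as np
import pytest

from strandslip import (
    AtomRecord,
    Domain,
    SyntheticDomainSpec,
    buried_surface,
    crystal_contacts,
    generate_domain,
    generate_heterodimer,
    mean_bfactor,
    shrake_rupley,
)
from strandslip.surface import DEFAULT_RADII, SurfaceError

from conftest import domain_from_model
from oracles import two_sphere_sasa


def carbon(serial, xyz, b=0.0):
    return AtomRecord(serial, "CA", "C", "", np.asarray(xyz, float), b_factor=b)


def test_single_sphere_matches_analytic_area():
    result = shrake_rupley([carbon(1, (0, 0, 0))])
    exact = 4 * np.pi * (1.70 + 1.40) ** 2
    assert result.total == pytest.approx(exact, rel=0.005)
    assert result.per_atom.shape == (1,)
    assert result.total == pytest.approx(result.per_atom.sum())


def test_disjoint_spheres_are_additive():
    pair = [carbon(1, (0, 0, 0)), carbon(2, (100, 0, 0))]
    single = shrake_rupley([pair[0]]).total
    assert shrake_rupley(pair).total == pytest.approx(2 * single, rel=1e-9)


def test_overlapping_spheres_match_cap_formula():
    d = 2.0
    pair = [carbon(1, (0, 0, 0)), carbon(2, (d, 0, 0))]
    result = shrake_rupley(pair)
    r = 1.70 + 1.40
    a1, a2 = two_sphere_sasa(r, r, d)
    assert result.per_atom[0] == pytest.approx(a1, rel=0.01)
    assert result.total == pytest.approx(a1 + a2, rel=0.01)


def test_mixed_element_pair_matches_cap_formula():
    atoms = [
        carbon(1, (0, 0, 0)),
        AtomRecord(2, "OG", "O", "", np.array([2.5, 0.0, 0.0])),
    ]
    result = shrake_rupley(atoms)
    a1, a2 = two_sphere_sasa(1.70 + 1.4, 1.52 + 1.4, 2.5)
    assert result.per_atom[0] == pytest.approx(a1, rel=0.01)
    assert result.per_atom[1] == pytest.approx(a2, rel=0.01)


def test_unknown_element_is_a_hard_error_naming_the_atom():
    selenium = AtomRecord(7, "SE", "SE", "", np.zeros(3))
    with pytest.raises(SurfaceError, match="SE"):
        shrake_rupley([carbon(1, (0, 0, 0)), selenium])
    with pytest.raises(SurfaceError):
        shrake_rupley([])


def test_quadrature_converged_at_default_point_count():
    model, _ = generate_domain(SyntheticDomainSpec(seed=9, noise_sigma=0.2))
    atoms = model.atoms()
    coarse = shrake_rupley(atoms, n_points=960).total
    fine = shrake_rupley(atoms, n_points=3840).total
    assert abs(coarse - fine) / fine <= 0.01


def test_sasa_cross_checked_against_independent_implementation():
    """Totals agree with biotite's Shrake–Rupley on identical radii."""
    struc = pytest.importorskip("biotite.structure")
    model, _ = generate_domain(SyntheticDomainSpec(seed=2))
    atoms = model.atoms()
    ours = shrake_rupley(atoms, n_points=960).total
    arr = struc.AtomArray(len(atoms))
    arr.coord = np.vstack([a.coords for a in atoms]).astype(np.float32)
    arr.set_annotation("element", np.array([a.element for a in atoms]))
    radii = np.array([DEFAULT_RADII[a.element] for a in atoms])
    theirs = float(struc.sasa(arr, probe_radius=1.4, vdw_radii=radii, point_number=960).sum())
    assert ours == pytest.approx(theirs, rel=0.01)


def test_buried_surface_two_sphere_system():
    a, b = [carbon(1, (0, 0, 0))], [carbon(2, (2.0, 0, 0))]
    r = 1.70 + 1.40
    a1, a2 = two_sphere_sasa(r, r, 2.0)
    lost = (4 * np.pi * r**2 - a1) + (4 * np.pi * r**2 - a2)
    assert buried_surface(a, b) == pytest.approx(lost, rel=0.01)
    assert buried_surface(a, [carbon(2, (50, 0, 0))]) == pytest.approx(0.0, abs=1e-9)


def test_buried_surface_symmetric_nonnegative_and_guarded():
    model = generate_heterodimer(
        SyntheticDomainSpec(seed=1), SyntheticDomainSpec(seed=2), interface_gap=5.0
    )
    dom_a = Domain("A", model.chains[0].residues)
    dom_b = Domain("B", model.chains[1].residues)
    ab = buried_surface(dom_a, dom_b)
    ba = buried_surface(dom_b, dom_a)
    assert ab == pytest.approx(ba, abs=1e-9)
    assert ab > 0
    with pytest.raises(SurfaceError):
        buried_surface(dom_a, dom_a)


def test_mean_bfactor_examples_and_union_identity():
    atoms = [carbon(i, (3.8 * i, 0, 0), b) for i, b in enumerate([10.0, 20.0, 30.0])]
    summary = mean_bfactor(atoms, label="triplet")
    assert summary.mean_b == pytest.approx(20.0)
    assert summary.n_atoms == 3
    flat = [carbon(i, (3.8 * i, 0, 0), 42.0) for i in range(5)]
    assert mean_bfactor(flat).mean_b == pytest.approx(42.0)
    union = mean_bfactor(atoms + flat)
    weighted = (3 * 20.0 + 5 * 42.0) / 8
    assert union.mean_b == pytest.approx(weighted)
    with pytest.raises(SurfaceError):
        mean_bfactor([])


def test_mean_bfactor_accepts_model_and_domain(baseline_domain):
    model, _ = generate_domain(SyntheticDomainSpec(seed=1, b_profile="sheet_gradient"))
    whole = mean_bfactor(model, label="whole")
    dom = mean_bfactor(domain_from_model(model), label="domain")
    assert whole.mean_b == pytest.approx(dom.mean_b)
    b_values = [a.b_factor for a in model.atoms()]
    assert min(b_values) <= whole.mean_b <= max(b_values)


def _residue_with_atom(seq_number, xyz):
    from strandslip import Residue

    res = Residue("A", seq_number, "", "ALA")
    res.atoms.append(carbon(seq_number, xyz))
    return res


def test_crystal_contacts_by_distance_cutoff():
    near_a = [_residue_with_atom(1, (0, 0, 0)), _residue_with_atom(2, (10, 0, 0))]
    near_b = [_residue_with_atom(11, (3.0, 0, 0)), _residue_with_atom(12, (100, 0, 0))]
    contacts = crystal_contacts(near_a, near_b, cutoff=4.0)
    assert len(contacts) == 1
    ra, rb = contacts[0]
    assert (ra.seq_number, rb.seq_number) == (1, 11)
    assert crystal_contacts(near_a, [_residue_with_atom(9, (500, 0, 0))]) == []
    with pytest.raises(SurfaceError):
        crystal_contacts(near_a, near_a)


def test_interface_shrinks_as_domains_separate():
    spec_a, spec_b = SyntheticDomainSpec(seed=1), SyntheticDomainSpec(seed=2)
    areas = []
    for gap in (4.0, 6.0, 8.0, 12.0, 20.0):
        model = generate_heterodimer(spec_a, spec_b, interface_gap=gap)
        areas.append(
            buried_surface(
                Domain("A", model.chains[0].residues), Domain("B", model.chains[1].residues)
            )
        )
    assert all(x >= y - 1e-9 for x, y in zip(areas, areas[1:]))
    assert areas[0] > 0
    assert areas[-1] == pytest.approx(0.0, abs=1e-9)
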