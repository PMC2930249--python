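import numpy as np
import pytest

from strandslip import (
    Domain,
    Residue,
    AtomRecord,
    call_segments,
    chemical_correspondence,
    dual_rmsd,
    register_profile,
    topological_alignment,
)
from strandslip.correspondence import CorrespondenceError
from strandslip.slippage import ProfileEntry, RegisterShiftProfile, profile_to_frame

from conftest import domain_from_model, make_twin_pair, random_rotation
from strandslip import SyntheticDomainSpec, generate_domain


def test_identical_domains_give_zero_dual_rmsd(baseline_domain):
    dual = dual_rmsd(baseline_domain, baseline_domain)
    assert dual.rmsd_topological == pytest.approx(0.0, abs=1e-9)
    assert dual.rmsd_chemical == pytest.approx(0.0, abs=1e-9)
    assert dual.n_topological == dual.n_chemical == len(baseline_domain)


def test_noiseless_shift_splits_the_two_rmsds():
    dom_a, dom_b, _ = make_twin_pair(seed=1, shift_segments=[(27, 32, 2)])
    dual = dual_rmsd(dom_a, dom_b)
    assert dual.rmsd_topological == pytest.approx(0.0, abs=1e-9)
    assert dual.rmsd_chemical > 1.0


def test_chemical_rmsd_closed_form_over_shifted_segment():
    """Within the slipped strand, chemical partners are k axial rises apart."""
    k = 2
    dom_a, dom_b, truth = make_twin_pair(seed=8, shift_segments=[(27, 32, k)])
    chem = chemical_correspondence(dom_a, dom_b)
    topo, sup = topological_alignment(dom_a, dom_b)
    res_a = chem._res_a
    in_zone = [
        (i, j) for i, j in chem.pairs if res_a[i].seq_number in truth.profile_offsets
    ]
    coords_a = np.vstack([chem._res_a[i].ca.coords for i, _ in in_zone])
    coords_b = np.vstack([chem._res_b[j].ca.coords for _, j in in_zone])
    from strandslip import rmsd_under_transform

    segment_rmsd = rmsd_under_transform(coords_a, coords_b, sup)
    assert segment_rmsd == pytest.approx(k * 3.3, rel=0.05)


def test_profile_zero_when_correspondences_agree(baseline_domain):
    chem = chemical_correspondence(baseline_domain, baseline_domain)
    topo, _ = topological_alignment(baseline_domain, baseline_domain)
    profile = register_profile(chem, topo)
    assert np.all(profile.offsets() == 0)
    assert profile.n_missing == 0
    assert call_segments(profile) == []


def test_profile_offsets_match_generator_ground_truth():
    dom_a, dom_b, truth = make_twin_pair(seed=3, shift_segments=[(20, 35, 2)])
    chem = chemical_correspondence(dom_a, dom_b)
    topo, _ = topological_alignment(dom_a, dom_b)
    profile = register_profile(chem, topo)
    measured = {
        e.residue.seq_number: e.offset for e in profile.entries if e.offset != 0
    }
    assert measured == truth.profile_offsets


def test_two_segments_of_opposite_sign_recovered_exactly():
    segments_spec = [(20, 28, 2), (53, 60, -1)]
    dom_a, dom_b, truth = make_twin_pair(seed=6, shift_segments=segments_spec, strand_length=12)
    chem = chemical_correspondence(dom_a, dom_b)
    topo, _ = topological_alignment(dom_a, dom_b)
    segments = call_segments(register_profile(chem, topo))
    assert len(segments) == 2
    expected = {}
    for seq_num, k in truth.profile_offsets.items():
        expected.setdefault(k, []).append(seq_num)
    by_offset = {s.offset: s for s in segments}
    assert set(by_offset) == set(expected)
    for k, nums in expected.items():
        seg = by_offset[k]
        assert seg.start_residue.seq_number == min(nums)
        assert seg.end_residue.seq_number == max(nums)


def _profile_from_offsets(offsets, rng):
    entries = []
    for idx, off in enumerate(offsets):
        if off is None:
            continue
        res = Residue("A", idx + 1, "", "ALA")
        res.atoms.append(AtomRecord(idx + 1, "CA", "C", "", rng.normal(size=3)))
        entries.append(
            ProfileEntry(
                residue=res,
                topological_partner=res,
                chemical_partner=res,
                offset=off,
                displacement=abs(off) * 3.3,
                index_a=idx,
            )
        )
    return RegisterShiftProfile(entries=entries, n_missing=offsets.count(None))


def test_call_segments_forced_examples(rng):
    profile = _profile_from_offsets([0, 0, 2, 2, 2, 2, 0], rng)
    segments = call_segments(profile, min_run=3)
    assert len(segments) == 1
    seg = segments[0]
    assert (seg.offset, seg.length) == (2, 4)
    assert seg.start_residue.seq_number == 3 and seg.end_residue.seq_number == 6
    # shorter than min_run: not called
    assert call_segments(_profile_from_offsets([0, 2, 2, 0, 0, 0], rng), min_run=3) == []
    # a gap (missing residue) breaks the run
    broken = _profile_from_offsets([2, 2, None, 2, 2], rng)
    assert call_segments(broken, min_run=3) == []
    assert call_segments(broken, min_run=2)[0].length == 2


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=60, derandomize=True)
@given(
    offsets=st.lists(
        st.one_of(st.integers(min_value=-3, max_value=3), st.none()),
        min_size=1,
        max_size=40,
    ),
    min_run=st.integers(min_value=1, max_value=5),
)
def test_call_segments_partition_property(offsets, min_run):
    """Called segments are disjoint, long enough, and constant in offset."""
    if all(o is None for o in offsets):
        return
    profile = _profile_from_offsets(offsets, np.random.default_rng(0))
    segments = call_segments(profile, min_run=min_run)
    covered = set()
    by_num = {e.residue.seq_number: e.offset for e in profile.entries}
    for seg in segments:
        span = range(seg.start_residue.seq_number, seg.end_residue.seq_number + 1)
        assert seg.length == len(span) >= min_run
        assert seg.offset != 0
        for num in span:
            assert num not in covered
            covered.add(num)
            assert by_num[num] == seg.offset


def test_segments_never_overlap(rng):
    offsets = [0, 1, 1, 1, -2, -2, -2, 0, 3, 3, 3, 3]
    segments = call_segments(_profile_from_offsets(offsets, rng), min_run=3)
    claimed = []
    for seg in segments:
        span = set(range(seg.start_residue.seq_number, seg.end_residue.seq_number + 1))
        assert not any(span & other for other in claimed)
        claimed.append(span)
    assert len(segments) == 3


def test_chemical_rmsd_dominates_topological_under_any_shift():
    for seed, sigma in [(1, 0.0), (2, 0.25), (3, 0.5)]:
        dom_a, dom_b, _ = make_twin_pair(seed=seed, shift_segments=[(27, 32, 2)], noise_sigma=sigma)
        dual = dual_rmsd(dom_a, dom_b)
        assert dual.rmsd_chemical >= dual.rmsd_topological


def test_dual_rmsd_invariant_to_rigid_pretransform(rng):
    dom_a, dom_b, _ = make_twin_pair(seed=12, shift_segments=[(27, 32, 2)], noise_sigma=0.1)
    before = dual_rmsd(dom_a, dom_b)
    rot = random_rotation(rng)
    shift = np.array([12.0, -7.0, 30.0])
    for res in dom_b.residues:
        for atom in res.atoms:
            atom.coords = rot @ atom.coords + shift
    after = dual_rmsd(dom_a, dom_b)
    assert after.rmsd_topological == pytest.approx(before.rmsd_topological, abs=1e-6)
    assert after.rmsd_chemical == pytest.approx(before.rmsd_chemical, abs=1e-6)


def test_refit_chemical_flag_lowers_the_chemical_rmsd():
    dom_a, dom_b, _ = make_twin_pair(seed=2, shift_segments=[(27, 32, 2)])
    shared_frame = dual_rmsd(dom_a, dom_b)
    refit = dual_rmsd(dom_a, dom_b, refit_chemical=True)
    assert refit.rmsd_chemical <= shared_frame.rmsd_chemical + 1e-9


def test_profile_requires_shared_domains_and_coverage(baseline_domain):
    dom_a, dom_b, _ = make_twin_pair(seed=4, shift_segments=[])
    chem = chemical_correspondence(dom_a, dom_b)
    topo, _ = topological_alignment(baseline_domain, baseline_domain)
    with pytest.raises(CorrespondenceError):
        register_profile(chem, topo)


def test_profile_frame_has_one_row_per_entry():
    dom_a, dom_b, _ = make_twin_pair(seed=5, shift_segments=[(27, 32, 2)])
    chem = chemical_correspondence(dom_a, dom_b)
    topo, _ = topological_alignment(dom_a, dom_b)
    profile = register_profile(chem, topo)
    frame = profile_to_frame(profile)
    assert list(frame.columns) == [
        "residue", "topological_partner", "chemical_partner", "offset", "displacement_A",
    ]
    assert len(frame) == len(profile.entries)
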