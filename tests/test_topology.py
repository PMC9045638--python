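"""Geometry of the dimer collective variables and descriptors."""

import numpy as np
import pytest

from spcdimer.topology import (DimerTopology, FrameGeometry, center_of_mass,
                               com_distance, compute_phi1_phi2, crossing_angle,
                               dihedral_angle, is_bound, min_distance,
                               residue_contact_matrix, wrap_angle,
                               batch_crossing_angles, batch_min_distances)
from spcdimer.toyhelix import (DEFAULT_TEMPLATES, pose_frame, pose_from_cvs,
                               solve_template)

from conftest import random_rotation


def reference_dihedral(p1, p2, p3, p4):
    """Independent formula: atan2 of cross products, no shared code path."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    return -np.arctan2(y, x)


class TestCenterOfMass:
    def test_uniform_symmetric_pair(self):
        com = center_of_mass(np.array([[0., 0, 0], [2, 0, 0]]))
        assert np.allclose(com, [1, 0, 0])

    def test_weighted_pair(self):
        com = center_of_mass(np.array([[0., 0, 0], [2, 0, 0]]), masses=[1., 3.])
        assert np.allclose(com, [1.5, 0, 0])

    def test_single_bead_identity(self):
        assert np.allclose(center_of_mass(np.array([[1., 2, 3]])), [1, 2, 3])

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError):
            center_of_mass(np.empty((0, 3)))


class TestDihedral:
    def test_planar_cis_is_zero(self):
        p = [np.array(x, float) for x in
             [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]]]
        assert abs(dihedral_angle(*p)) < 1e-12

    def test_planar_trans_is_pi(self):
        p = [np.array(x, float) for x in
             [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]]]
        assert abs(dihedral_angle(*p)) == pytest.approx(np.pi)

    def test_matches_independent_formula(self, rng):
        for _ in range(200):
            pts = rng.standard_normal((4, 3)) * 2.0
            want = reference_dihedral(*pts)
            got = dihedral_angle(*pts)
            assert wrap_angle(got - want) == pytest.approx(0.0, abs=1e-10)

    def test_mirror_flips_sign(self, rng):
        for _ in range(50):
            pts = rng.standard_normal((4, 3))
            a = dihedral_angle(*pts)
            if abs(abs(a) - np.pi) < 1e-6:
                continue  # sign of +/-pi is a wrap convention, not a flip
            b = dihedral_angle(*(-pts))
            assert b == pytest.approx(-a, abs=1e-9)

    def test_degenerate_collinear_raises(self):
        p1, p2, p3 = np.zeros(3), np.array([1., 0, 0]), np.array([2., 0, 0])
        with pytest.raises(ValueError):
            dihedral_angle(p1, p2, p3, np.array([3., 1, 0]))


def _demo_frame(topo, template_idx=0, phi1=1.0, phi2=-2.0, d=1.3):
    pose = pose_from_cvs(phi1, phi2, d, DEFAULT_TEMPLATES[template_idx], topo)
    return pose_frame(pose, topo)


class TestInterfaceDihedrals:
    def test_monomer_swap_exchanges_angles(self, topo):
        frame = _demo_frame(topo)
        a1, a2 = compute_phi1_phi2(frame, topo)
        b1, b2 = compute_phi1_phi2(frame.swapped(), topo)
        assert a1 == pytest.approx(b2, abs=1e-12)
        assert a2 == pytest.approx(b1, abs=1e-12)

    @pytest.mark.parametrize("template", DEFAULT_TEMPLATES, ids=lambda t: t.name)
    def test_planted_pose_recovers_inputs(self, topo, template):
        want = (np.radians(60.0), np.radians(-120.0), 1.4)
        pose = pose_from_cvs(*want, template, topo)
        frame = pose_frame(pose, topo)
        got1, got2 = compute_phi1_phi2(frame, topo)
        assert wrap_angle(got1 - want[0]) == pytest.approx(0.0, abs=1e-6)
        assert wrap_angle(got2 - want[1]) == pytest.approx(0.0, abs=1e-6)
        assert com_distance(frame, topo) == pytest.approx(want[2], abs=1e-6)


class TestDistances:
    def test_com_distance_offset_convention(self, topo):
        frame = _demo_frame(topo)
        shifted = FrameGeometry(frame.coords_a,
                                frame.coords_a + np.array([4.5, 0, 0]))
        assert com_distance(shifted, topo) == pytest.approx(4.5, abs=1e-12)

    def test_com_distance_self_is_zero(self, topo):
        frame = _demo_frame(topo)
        dup = FrameGeometry(frame.coords_a, frame.coords_a.copy())
        assert com_distance(dup, topo) == 0.0

    def test_translation_invariance(self, topo):
        frame = _demo_frame(topo)
        moved = FrameGeometry(frame.coords_a + 3.0, frame.coords_b + 3.0)
        assert com_distance(moved, topo) == pytest.approx(
            com_distance(frame, topo), abs=1e-12)

    def test_min_distance_constructed_pair(self, topo):
        # engineered frame: one bead placed exactly 0.45 nm beyond the
        # most extreme monomer-1 bead; every other cross pair is >= 0.45 nm
        frame = _demo_frame(topo)
        cb = frame.coords_a + np.array([0, 0, 50.0])
        seg = topo.bead_indices(topo.groups["helical_segment"])
        bead = seg[np.argmax(frame.coords_a[seg, 0])]
        cb[bead] = frame.coords_a[bead] + np.array([0.45, 0, 0])
        built = FrameGeometry(frame.coords_a, cb)
        assert min_distance(built, topo) == pytest.approx(0.45, abs=1e-12)

    def test_min_distance_far_apart(self, topo):
        frame = _demo_frame(topo)
        far = FrameGeometry(frame.coords_a,
                            frame.coords_a + np.array([0, 0, 50.0]))
        seg = topo.bead_indices(topo.groups["helical_segment"])
        pa = far.coords_a[seg]
        pb = far.coords_b[seg]
        want = np.sqrt(((pa[:, None] - pb[None]) ** 2).sum(-1)).min()
        assert min_distance(far, topo) == pytest.approx(want, abs=1e-12)

    def test_min_distance_swap_symmetric(self, topo):
        frame = _demo_frame(topo)
        assert min_distance(frame, topo) == pytest.approx(
            min_distance(frame.swapped(), topo), abs=1e-14)

    def test_min_distance_bounded_by_any_pair(self, topo):
        frame = _demo_frame(topo)
        seg = topo.bead_indices(topo.groups["helical_segment"])
        pair = np.linalg.norm(frame.coords_a[seg[0]] - frame.coords_b[seg[-1]])
        assert min_distance(frame, topo) <= pair + 1e-12

    def test_empty_selection_raises(self, topo):
        with pytest.raises(ValueError):
            min_distance(_demo_frame(topo), topo, selection_a=())


class TestBoundCriterion:
    @pytest.mark.parametrize("d_min,expected",
                             [(0.60, True), (0.601, False), (0.45, True)])
    def test_cutoff_boundary(self, d_min, expected):
        assert is_bound(d_min) is expected

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            is_bound(-0.1)


class TestCrossingAngle:
    def test_parallel_axes_zero(self, topo):
        frame = _demo_frame(topo)
        dup = FrameGeometry(frame.coords_a,
                            frame.coords_a + np.array([2.0, 0, 0]))
        assert crossing_angle(dup, topo) == pytest.approx(0.0, abs=1e-9)

    def test_antiparallel_axes_180(self, topo):
        frame = _demo_frame(topo)
        flipped = -frame.coords_a  # point inversion reverses the axis exactly
        dup = FrameGeometry(frame.coords_a, flipped + np.array([2.0, 0, 0]))
        assert crossing_angle(dup, topo) == pytest.approx(180.0, abs=1e-9)

    def test_constructed_24_6_degrees(self, topo, rng):
        frame = _demo_frame(topo)
        psi = np.radians(24.6)
        rot = np.array([[np.cos(psi), 0, np.sin(psi)],
                        [0, 1, 0],
                        [-np.sin(psi), 0, np.cos(psi)]])
        # the axis of monomer 1 must be aligned with z before tilting by psi
        from spcdimer.topology import _helix_axis
        axis = _helix_axis(frame.coords_a, topo)
        axis /= np.linalg.norm(axis)
        align = _rotation_onto_z(axis)
        ca = frame.coords_a @ align.T
        cb = ca @ rot.T + np.array([2.0, 0, 0])
        assert crossing_angle(FrameGeometry(ca, cb), topo) == pytest.approx(
            24.6, abs=1e-9)


def _rotation_onto_z(v):
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        return np.eye(3)
    axis /= s
    c = v @ z
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


class TestContacts:
    def test_threshold_boundary(self, topo):
        frame = _demo_frame(topo)
        near = FrameGeometry(frame.coords_a,
                             frame.coords_a + np.array([0.59, 0, 0]))
        far = FrameGeometry(frame.coords_a,
                            frame.coords_a + np.array([50.0, 0, 0]))
        assert residue_contact_matrix(near, topo).any()
        assert not residue_contact_matrix(far, topo).any()

    def test_swap_transposes(self, topo):
        frame = _demo_frame(topo)
        m = residue_contact_matrix(frame, topo)
        ms = residue_contact_matrix(frame.swapped(), topo)
        assert np.array_equal(ms, m.T)


class TestRigidMotionInvariance:
    def test_all_descriptors_invariant(self, topo, rng):
        frame = _demo_frame(topo)
        base = (compute_phi1_phi2(frame, topo), com_distance(frame, topo),
                min_distance(frame, topo), crossing_angle(frame, topo))
        for _ in range(10):
            rot = random_rotation(rng)
            t = rng.standard_normal(3) * 5
            moved = FrameGeometry(frame.coords_a @ rot.T + t,
                                  frame.coords_b @ rot.T + t)
            got = (compute_phi1_phi2(moved, topo), com_distance(moved, topo),
                   min_distance(moved, topo), crossing_angle(moved, topo))
            assert got[0][0] == pytest.approx(base[0][0], abs=1e-9)
            assert got[0][1] == pytest.approx(base[0][1], abs=1e-9)
            assert got[1] == pytest.approx(base[1], abs=1e-9)
            assert got[2] == pytest.approx(base[2], abs=1e-9)
            assert got[3] == pytest.approx(base[3], abs=1e-9)


class TestBatchHelpers:
    def test_batch_matches_scalar(self, topo):
        frames = [_demo_frame(topo, i, 0.3 * i, -0.5, 1.2 + 0.2 * i)
                  for i in range(3)]
        coords = np.stack([[f.coords_a, f.coords_b] for f in frames])
        dmin = batch_min_distances(coords, topo)
        psi = batch_crossing_angles(coords, topo)
        for i, f in enumerate(frames):
            assert dmin[i] == pytest.approx(min_distance(f, topo), abs=1e-12)
            assert psi[i] == pytest.approx(crossing_angle(f, topo), abs=1e-9)


class TestDihedralProperties:
    """Hypothesis-driven invariants of the torsion angle."""

    from hypothesis import given, settings, strategies as st

    coords = st.lists(st.floats(-5, 5, allow_nan=False), min_size=12,
                      max_size=12)

    @given(coords)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rigid_translation_invariance(self, flat):
        pts = np.array(flat).reshape(4, 3)
        try:
            base = dihedral_angle(*pts)
        except ValueError:
            return  # degenerate quadruple: contract covered elsewhere
        moved = pts + np.array([1.7, -2.2, 0.9])
        assert dihedral_angle(*moved) == pytest.approx(base, abs=1e-8)

    @given(coords)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_range_is_half_open_interval(self, flat):
        pts = np.array(flat).reshape(4, 3)
        try:
            a = dihedral_angle(*pts)
        except ValueError:
            return
        assert -np.pi < a <= np.pi


def test_wrap_angle_range():
    a = wrap_angle(np.array([-np.pi, np.pi, 3 * np.pi, -3 * np.pi, 0.0]))
    assert np.all(a > -np.pi - 1e-15) and np.all(a <= np.pi + 1e-15)
    assert wrap_angle(-np.pi) == pytest.approx(np.pi)


def test_topology_group_bounds():
    with pytest.raises(ValueError):
        DimerTopology(n_residues_per_monomer=20)  # default groups exceed 20
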