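"""Superposition, twist decomposition, PF assignment and lattice contacts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import doubletlattice as dl
from doubletlattice.lattice_geometry import kabsch, twist_about_axis

Z_AXIS = dl.LatticeAxis([0, 0, 1], [0, 0, 0])


def asym_points():
    return np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 5.0, 0.0],
                     [1.0, 2.0, 7.0]])


class TestSuperpose:
    def test_identity(self):
        P = asym_points()
        t, rmsd = kabsch(P, P)
        assert rmsd < 1e-12
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0, atol=1e-12)

    def test_pure_translation(self):
        P = asym_points()
        t, rmsd = kabsch(P, P + [1.0, 2.0, 3.0])
        assert rmsd < 1e-12
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, [1, 2, 3], atol=1e-12)

    def test_90_degree_recovery(self):
        P = asym_points()
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t, rmsd = kabsch(P, P @ R.T)
        assert rmsd < 1e-9
        angle = np.degrees(np.linalg.norm(
            Rotation.from_matrix(t.rotation).as_rotvec()))
        assert angle == pytest.approx(90.0, abs=1e-9)

    def test_collinear_pairing_rejected(self):
        P = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch(P, P)

    def test_mismatched_counts_rejected(self, template_alpha, template_beta):
        with pytest.raises(ValueError, match="equal atom counts"):
            dl.superpose(template_alpha.subset(np.arange(10)), template_beta)

    def test_no_reflection(self):
        P = asym_points()
        t, _ = kabsch(P, P * [-1, 1, 1])  # mirrored target
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_random_rigid_motion_recovered(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(12, 3)) * 10
        R = Rotation.random(random_state=int(seed % 2 ** 30)).as_matrix()
        shift = rng.normal(size=3) * 5
        t, rmsd = kabsch(P, P @ R.T + shift)
        assert rmsd < 1e-8
        assert np.allclose(t.rotation, R, atol=1e-8)


class TestRigidTransform:
    def test_inverse_round_trip(self):
        R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        t = dl.RigidTransform(R, [1.0, -2.0, 3.0])
        pts = asym_points()
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_improper_rotation_rejected(self):
        with pytest.raises(ValueError):
            dl.RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestTwistDecomposition:
    def test_rotation_about_axis_is_full_twist(self):
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        twist, _, dev = twist_about_axis(dl.RigidTransform(R, np.zeros(3)),
                                         Z_AXIS)
        assert twist == pytest.approx(30.0, abs=1e-9)
        assert dev == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_rotation_has_zero_twist(self):
        R = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        twist, _, dev = twist_about_axis(dl.RigidTransform(R, np.zeros(3)),
                                         Z_AXIS)
        assert twist == pytest.approx(0.0, abs=1e-9)
        assert dev == pytest.approx(90.0, abs=1e-6)

    def test_coaxial_additivity(self):
        t1 = dl.RigidTransform(
            Rotation.from_euler("z", 20, degrees=True).as_matrix(), np.zeros(3))
        t2 = dl.RigidTransform(
            Rotation.from_euler("z", 10, degrees=True).as_matrix(), np.zeros(3))
        twist, _, _ = twist_about_axis(t1.compose(t2), Z_AXIS)
        assert twist == pytest.approx(30.0, abs=1e-9)

    def test_near_identity_flagged_zero(self):
        twist, _, dev = twist_about_axis(dl.RigidTransform.identity(), Z_AXIS)
        assert twist == 0.0 and dev == 0.0

    def test_screw_shift_along_axis(self):
        R = Rotation.from_euler("z", 27.7, degrees=True).as_matrix()
        t = dl.RigidTransform(R, [0.0, 0.0, 9.23])
        _, z_shift, _ = twist_about_axis(t, Z_AXIS)
        assert z_shift == pytest.approx(9.23, abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_grid_search_oracle(self, seed):
        """Twist equals the angle minimising residual swing (brute force)."""
        R = Rotation.random(random_state=int(seed % 2 ** 30)).as_matrix()
        t = dl.RigidTransform(R, np.zeros(3))
        twist, _, _ = twist_about_axis(t, Z_AXIS)

        def residual(a):
            Rt = Rotation.from_euler("z", -a, degrees=True).as_matrix()
            return np.degrees(np.linalg.norm(
                Rotation.from_matrix(Rt @ R).as_rotvec()))

        coarse = np.arange(-180.0, 180.0, 0.1)
        res = [residual(a) for a in coarse]
        a0 = coarse[int(np.argmin(res))]
        fine = np.arange(a0 - 0.1, a0 + 0.1, 0.001)
        best = fine[int(np.argmin([residual(a) for a in fine]))]
        delta = (twist - best + 180) % 360 - 180
        assert abs(delta) < 0.01


class TestAxisEstimation:
    def test_lattice_built_along_z(self, singlet13):
        axis = dl.estimate_axis(singlet13)
        assert np.allclose(axis.direction, [0, 0, 1], atol=1e-6)

    def test_rotated_lattice_axis_follows(self, singlet13):
        R = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        rotated = singlet13.with_coords(singlet13.coords @ R.T)
        axis = dl.estimate_axis(rotated)
        expected = R @ np.array([0, 0, 1.0])
        assert np.allclose(axis.direction, expected, atol=1e-6)

    def test_single_dimer_rejected(self, singlet13, singlet13_assignment):
        chains = singlet13_assignment.chains_of_pf["A1"][:2]
        dimer = singlet13.subset(np.isin(singlet13.chain_ids, chains))
        with pytest.raises(ValueError):
            dl.estimate_axis(dimer)

    def test_sign_points_beta_to_alpha(self, singlet13):
        # plus end up: alpha sits above beta in the generator
        axis = dl.estimate_axis(singlet13)
        assert axis.direction[2] > 0


class TestPFAssignment:
    def test_closed_13(self, singlet13_assignment):
        a = singlet13_assignment
        assert len(a.pf_order["A"]) == 13
        assert bool(a.closed["A"])

    def test_open_arc(self):
        m = dl.build_singlet(dl.LatticeSpec(n_pf=15, n_repeats=2, open_arc=10))
        a = dl.assign_pfs(m)
        assert len(a.pf_order["A"]) == 10
        assert not a.closed["A"]

    def test_doublet_13_plus_10(self, doublet_assignment):
        a = doublet_assignment
        assert len(a.pf_order["A"]) == 13
        assert len(a.pf_order["B"]) == 10
        assert bool(a.closed["A"]) and not a.closed["B"]

    def test_doublet_labels_match_ground_truth(self, doublet,
                                               doublet_assignment):
        gt = doublet.metadata["ground_truth"]
        a = doublet_assignment
        # B arc labelled B1..B10 in construction order from the junction
        for c, meta in gt.items():
            if meta["tubule"] == "B":
                assert a.pf_of_chain[c] == f"B{meta['pf'] + 1}"
        # junction construction pair carries labels A10/A11
        junction = set(doublet.metadata["junction"]["a_pf_pair"])
        got = {a.pf_of_chain[c] for c, meta in gt.items()
               if meta["tubule"] == "A" and meta["pf"] in junction}
        assert got == {"A10", "A11"}

    def test_every_chain_assigned_once(self, doublet, doublet_assignment):
        a = doublet_assignment
        assert set(a.pf_of_chain) == set(doublet.chains)
        listed = [c for pf in a.chains_of_pf.values() for c in pf]
        assert sorted(listed) == sorted(doublet.chains)

    def test_too_few_dimers_rejected(self, template_alpha):
        with pytest.raises(ValueError):
            dl.assign_pfs(template_alpha)


class TestPairGeometry:
    def test_ideal_13_pf_pair(self, singlet13, singlet13_assignment):
        g = dl.pf_pair_geometry(singlet13, singlet13_assignment, "A1", "A2")
        assert abs(g.angle_deg) == pytest.approx(360.0 / 13, abs=1e-6)
        assert g.theoretical_pf_number == pytest.approx(13.0, abs=1e-6)
        assert abs(g.z_shift) == pytest.approx(3 * 40.0 / 13, abs=1e-6)
        assert g.pf_class == 13
        assert g.axis_deviation_deg < 1e-6

    def test_15_pf_arithmetic(self):
        m = dl.build_singlet(dl.LatticeSpec(n_pf=15, n_repeats=2))
        a = dl.assign_pfs(m)
        g = dl.pf_pair_geometry(m, a, *a.adjacent_pairs("A")[0])
        assert abs(g.angle_deg) == pytest.approx(24.0, abs=1e-6)
        assert g.theoretical_pf_number == pytest.approx(15.0, abs=1e-6)

    def test_antisymmetry(self, singlet13, singlet13_assignment):
        g1 = dl.pf_pair_geometry(singlet13, singlet13_assignment, "A1", "A2")
        g2 = dl.pf_pair_geometry(singlet13, singlet13_assignment, "A2", "A1")
        assert g1.angle_deg == pytest.approx(-g2.angle_deg, abs=1e-9)

    def test_scale_invariance(self, singlet13, singlet13_assignment):
        scaled = singlet13.with_coords(singlet13.coords * 1.7)
        a = dl.assign_pfs(scaled, cluster_cutoff=25.0)
        pair = a.adjacent_pairs("A")[0]
        g = dl.pf_pair_geometry(scaled, a, *pair)
        assert g.theoretical_pf_number == pytest.approx(13.0, abs=1e-6)

    def test_non_adjacent_rejected(self, singlet13, singlet13_assignment):
        with pytest.raises(ValueError, match="not adjacent"):
            dl.pf_pair_geometry(singlet13, singlet13_assignment, "A1", "A5")


class TestLatticeContacts:
    def test_exactly_one_seam_in_closed_b_lattice(self, singlet13,
                                                  singlet13_assignment):
        contacts = dl.classify_lattice_contacts(singlet13,
                                                singlet13_assignment)
        seams = [c for c in contacts if c.register == "seam"]
        assert len(seams) == 1

    def test_seam_count_independent_of_anchor(self, singlet13):
        """Rotating the lattice (hence relabelling PF 1) keeps one seam."""
        R = Rotation.from_euler("z", 97.0, degrees=True).as_matrix()
        rotated = singlet13.with_coords(singlet13.coords @ R.T)
        a = dl.assign_pfs(rotated)
        contacts = dl.classify_lattice_contacts(rotated, a)
        assert sum(c.register == "seam" for c in contacts) == 1

    def test_two_pf_toy_seam(self, template_alpha, template_beta):
        """Alpha axially aligned with the neighbour's beta -> seam."""
        spec = dl.LatticeSpec(n_pf=13, n_repeats=2, stagger=40.0, open_arc=5)
        m = dl.build_singlet(spec, template_alpha, template_beta)
        a = dl.assign_pfs(m)
        contacts = dl.classify_lattice_contacts(m, a)
        assert all(c.register == "seam" for c in contacts)

    def test_missing_labels_error(self, singlet13, singlet13_assignment):
        stripped = singlet13.copy()
        stripped.metadata = {}
        a = dl.assign_pfs(stripped)
        a.alpha_beta = {}
        with pytest.raises(ValueError, match="alpha/beta"):
            dl.classify_lattice_contacts(stripped, a)


class TestLatticeReport:
    def test_uniform_lattice_rows_identical(self, singlet13,
                                            singlet13_assignment):
        rep = dl.lattice_report(singlet13, singlet13_assignment)
        assert len(rep) == 13
        assert (rep.pf_class == 13).all()
        summary = dl.lattice_summary(rep)
        assert summary.loc["A", "min"] == summary.loc["A", "max"] == 13

    def test_per_pair_twist_list_recovered(self):
        twists = [26.0, 28.0, 27.0, 29.0, 26.5, 28.5, 27.2, 27.8,
                  27.0, 28.0, 26.8, 28.2, 360.0 - sum([26.0, 28.0, 27.0,
                                                       29.0, 26.5, 28.5,
                                                       27.2, 27.8, 27.0,
                                                       28.0, 26.8, 28.2])]
        m = dl.build_singlet(dl.LatticeSpec(n_pf=13, n_repeats=2,
                                            twist_deg=twists))
        a = dl.assign_pfs(m)
        rep = dl.lattice_report(m, a)
        measured = sorted(round(abs(x), 6) for x in rep.angle_deg)
        assert measured == sorted(round(t, 6) for t in twists)

    def test_doublet_report_covers_both_tubules(self, doublet,
                                                doublet_assignment):
        rep = dl.lattice_report(doublet, doublet_assignment)
        assert (rep.tubule == "A").sum() == 13   # closed ring: 13 pairs
        assert (rep.tubule == "B").sum() == 9    # open arc: 9 pairs
        b_rows = rep[rep.tubule == "B"]
        assert np.allclose(np.abs(b_rows.angle_deg), 24.0, atol=1e-6)
        assert (b_rows.pf_class == 15).all()
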