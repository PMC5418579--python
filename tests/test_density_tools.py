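"""Density simulation, calibration, difference maps, register, subvolumes."""

import numpy as np
import pytest

import doubletlattice as dl
from doubletlattice.density_tools import footprint_mask, gaussian_sigma

from conftest import single_atom


def fourier_render(model, like, resolution):
    """Independent oracle: render the same Gaussian model in Fourier space."""
    nz, ny, nx = like.shape
    v = like.voxel_size
    sigma = gaussian_sigma(resolution)
    kx = np.fft.fftfreq(nx, d=v)
    ky = np.fft.fftfreq(ny, d=v)
    kz = np.fft.fftfreq(nz, d=v)
    F = np.zeros((nz, ny, nx), dtype=complex)
    weights = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}
    for (x, y, z), el in zip(model.coords, model.elements):
        u = np.array([x, y, z]) - like.origin
        ez = np.exp(-2j * np.pi * kz * u[2])
        ey = np.exp(-2j * np.pi * ky * u[1])
        ex = np.exp(-2j * np.pi * kx * u[0])
        F += weights[str(el)] * (ez[:, None, None] * ey[None, :, None]
                                 * ex[None, None, :])
    k2 = (kz[:, None, None] ** 2 + ky[None, :, None] ** 2
          + kx[None, None, :] ** 2)
    F *= np.exp(-2 * np.pi ** 2 * sigma ** 2 * k2)
    vals = np.fft.ifftn(F).real * v ** 3 / v ** 3  # density * voxel volume
    return vals / v ** 3 * v ** 3


class TestSimulateDensity:
    def test_single_atom_peak_and_integral(self):
        m = single_atom("C", (10.0, 12.0, 14.0))
        g = dl.simulate_density(m, 6.0, 1.5, pad=10.0)
        peak = np.unravel_index(np.argmax(g.values), g.shape)
        assert np.allclose(g.world_coords(np.array(peak)), [10, 12, 14],
                           atol=1.5)
        assert g.values.sum() == pytest.approx(6.0, rel=1e-3)

    def test_linearity(self, template_alpha):
        shifted = template_alpha.with_coords(template_alpha.coords
                                             + [12.0, 0, 0])
        shifted.chain_ids = np.array(["B"] * len(shifted), dtype=object)
        both = dl.StructureModel.concat([template_alpha, shifted])
        g_both = dl.simulate_density(both, 8.0, 2.0, pad=14.0)
        g_a = dl.simulate_on_grid(template_alpha, g_both, 8.0)
        g_b = dl.simulate_on_grid(shifted, g_both, 8.0)
        assert np.allclose(g_both.values, g_a.values + g_b.values, atol=1e-6)

    def test_matches_fourier_space_oracle(self, template_alpha):
        g = dl.simulate_density(template_alpha, 6.0, 2.0, pad=16.0)
        oracle = fourier_render(template_alpha, g, 6.0)
        assert dl.real_space_cc(g.values, oracle) >= 0.99

    def test_undersampled_rejected(self, template_alpha):
        with pytest.raises(ValueError, match="ndersampled"):
            dl.simulate_density(template_alpha, 3.0, 2.0)


class TestRealSpaceCC:
    def test_self_correlation_one(self):
        g = dl.DensityGrid(np.random.default_rng(0).normal(
            size=(8, 8, 8)).astype(np.float32), 1.0)
        assert dl.real_space_cc(g, g) == pytest.approx(1.0)

    def test_negation_minus_one(self):
        g = dl.DensityGrid(np.random.default_rng(0).normal(
            size=(8, 8, 8)).astype(np.float32), 1.0)
        neg = dl.DensityGrid(-g.values, 1.0)
        assert dl.real_space_cc(g, neg) == pytest.approx(-1.0)

    def test_noise_attenuation_closed_form(self, template_alpha):
        """cc(noisy, clean) ~ 1/sqrt(1 + sigma^2/s^2); at sigma = s: 1/sqrt2."""
        g = dl.simulate_density(template_alpha, 8.0, 2.0, pad=10.0)
        s = float(g.values.std())
        ccs = [dl.real_space_cc(dl.add_noise(g, s, seed=k), g)
               for k in range(5)]
        assert np.mean(ccs) == pytest.approx(1 / np.sqrt(2), abs=0.05)

    def test_zero_variance_rejected(self):
        g = dl.DensityGrid(np.ones((5, 5, 5), np.float32), 1.0)
        with pytest.raises(ValueError, match="variance"):
            dl.real_space_cc(g, g)

    def test_shape_mismatch_rejected(self):
        a = dl.DensityGrid(np.zeros((4, 4, 4), np.float32), 1.0)
        b = dl.DensityGrid(np.zeros((5, 4, 4), np.float32), 1.0)
        with pytest.raises(ValueError, match="resample"):
            dl.real_space_cc(a, b)


@pytest.fixture(scope="module")
def small_lattice():
    return dl.build_singlet(dl.LatticeSpec(n_pf=13, n_repeats=1))


class TestCalibration:

    def test_self_consistent_scale(self, small_lattice):
        g = dl.simulate_density(small_lattice, 6.0, 1.395, pad=10.0)
        cal = dl.calibrate_voxel_size(g, small_lattice, 1.395, 6.0,
                                      scan=0.01, step=0.002)
        assert cal.scale == pytest.approx(1.0, abs=2e-3)

    def test_recovers_mislabeled_pixel_size(self, small_lattice):
        """A 1.375 A/px map labelled 1.395 A/px calibrates back to 1.375."""
        g = dl.simulate_density(small_lattice, 6.0, 1.375, pad=10.0)
        mislabelled = dl.DensityGrid(g.values, 1.395,
                                     g.origin * (1.395 / 1.375))
        cal = dl.calibrate_voxel_size(mislabelled, small_lattice, 1.395, 6.0)
        assert cal.voxel_size == pytest.approx(1.375, abs=0.002)
        assert not cal.at_scan_edge

    def test_flat_map_rejected(self, small_lattice):
        flat = dl.DensityGrid(np.zeros((40, 40, 40), np.float32), 1.395,
                              origin=(-20, -20, -20))
        with pytest.raises(ValueError):
            dl.calibrate_voxel_size(flat, small_lattice, 1.395, 6.0,
                                    scan=0.004, step=0.002)


class TestDifferenceMap:
    def test_identity_is_bitwise_zero(self, doublet_map):
        diff = dl.difference_map(doublet_map, doublet_map)
        assert np.all(diff.values == 0)

    def test_affine_scaling_absorbed(self, doublet_map):
        scaled = dl.DensityGrid(2.0 * doublet_map.values + 5.0,
                                doublet_map.voxel_size, doublet_map.origin)
        diff = dl.difference_map(scaled, doublet_map)
        assert np.max(np.abs(diff.values)) < 1e-4

    def test_planted_mips_recovered(self, singlet13):
        sim = dl.simulate_density(singlet13, 8.0, 3.0, pad=30.0)
        amp = 0.8
        descriptors = [
            dl.MipDescriptor(kind="blob", position=(0, 0, 100),
                             amplitude=amp, sigma=6.0),
            dl.MipDescriptor(kind="filament", position=(85, 25, 40),
                             end=(85, 25, 160), amplitude=amp, sigma=4.0),
        ]
        exp, mask = dl.plant_mips(sim, descriptors)
        diff = dl.difference_map(exp, sim)
        recovered = (diff.values[mask] >= 0.5 * amp).mean()
        false_pos = ((diff.values >= 0.5 * amp) & ~mask).sum() / (~mask).sum()
        assert recovered >= 0.90
        assert false_pos <= 0.01

    def test_degenerate_scaling_rejected(self):
        flat = dl.DensityGrid(np.ones((5, 5, 5), np.float32), 1.0)
        with pytest.raises(ValueError):
            dl.difference_map(flat, flat)


class TestRegisterAssignment:
    def test_noiseless_all_correct(self, doublet, doublet_assignment,
                                   doublet_map):
        ra = dl.assign_alpha_beta_register(doublet_map, doublet,
                                           doublet_assignment)
        assert ra.n_register0() == 23
        assert len(ra.register) == 23
        assert not ra.ambiguous

    def test_shifted_model_prefers_shifted_register(self, doublet,
                                                    doublet_assignment,
                                                    doublet_map):
        """Feeding dimers displaced by -40 A makes +4nm the better register."""
        n = doublet_assignment.axis.direction
        wrong = doublet.with_coords(doublet.coords - 40.0 * n)
        ra = dl.assign_alpha_beta_register(doublet_map, wrong,
                                           doublet_assignment)
        assert ra.n_register0() == 0

    def test_symmetric_template_is_ambiguous(self, template_alpha):
        """With alpha == beta the two registers nearly tie (residual
        confidence comes only from edge truncation of the lattice)."""
        spec = dl.LatticeSpec(n_pf=13, n_repeats=2)
        m = dl.build_singlet(spec, template_alpha, template_alpha)
        a = dl.assign_pfs(m)
        g = dl.simulate_density(m, 8.0, 3.0, pad=45.0)
        ra = dl.assign_alpha_beta_register(g, m, a,
                                           ambiguity_threshold=0.01)
        assert np.median(list(ra.confidence.values())) < 0.005
        assert len(ra.ambiguous) >= 12

    def test_mask_outside_map_rejected(self):
        m = dl.build_singlet(dl.LatticeSpec(n_pf=13, n_repeats=1))
        a = dl.assign_pfs(m)
        tight = dl.simulate_density(m, 8.0, 3.0, pad=5.0)
        with pytest.raises(ValueError, match="padded"):
            dl.assign_alpha_beta_register(tight, m, a)


class TestSubvolumes:
    def test_identity_transforms_equal_raw_crops(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(24, 24, 24)).astype(np.float32)
        g = dl.DensityGrid(vals, 2.0, origin=(-22, -22, -22))
        items = [("c", np.array([0.0, 0.0, 0.0]), np.eye(3))]
        sv = dl.extract_subvolumes(g, items, box_size=9)
        crop = vals[7:16, 7:16, 7:16]
        assert np.allclose(sv.subvolumes[0].values, crop, atol=1e-6)

    def test_rotated_copy_recovered(self, template_alpha):
        from scipy.spatial.transform import Rotation
        g = dl.simulate_density(template_alpha, 8.0, 2.0, pad=30.0)
        R = Rotation.from_euler("z", 35, degrees=True).as_matrix()
        rotated = template_alpha.with_coords(
            (template_alpha.coords - template_alpha.centroid()) @ R.T
            + template_alpha.centroid())
        g_rot = dl.simulate_on_grid(rotated, g, 8.0)
        center = template_alpha.centroid()
        box = 17
        ref = dl.extract_subvolumes(g, [("r", center, np.eye(3))], box)
        sub = dl.extract_subvolumes(g_rot, [("m", center, R)], box)
        assert dl.real_space_cc(sub.subvolumes[0].values,
                                ref.subvolumes[0].values) >= 0.98

    def test_23_dimers_of_doublet(self, doublet, doublet_assignment,
                                  doublet_map):
        items = []
        for t in doublet_assignment.tubules:
            for pf in doublet_assignment.pf_order[t]:
                chains = doublet_assignment.chains_of_pf[pf][:2]
                dimer = doublet.subset(np.isin(doublet.chain_ids, chains))
                items.append((pf, dimer.centroid(), np.eye(3)))
        sv = dl.extract_subvolumes(doublet_map, items, box_size=24)
        assert len(sv) == 23

    def test_box_larger_than_map_rejected(self, doublet_map):
        with pytest.raises(ValueError, match="box"):
            dl.extract_subvolumes(doublet_map, [], box_size=10_000)

    def test_edge_box_skipped_with_warning(self):
        g = dl.DensityGrid(np.zeros((16, 16, 16), np.float32), 1.0)
        with pytest.warns(UserWarning, match="skipped"):
            sv = dl.extract_subvolumes(
                g, [("edge", np.array([0.0, 0.0, 0.0]), np.eye(3))], 9)
        assert len(sv) == 0


class TestAveraging:
    def make_set(self, grids):
        return dl.SubvolumeSet(grids,
                               [dl.RigidTransform.identity()] * len(grids),
                               [str(i) for i in range(len(grids))],
                               grids[0].shape[0])

    def test_identical_inputs_average_exactly(self, template_alpha):
        g = dl.simulate_density(template_alpha, 8.0, 2.0, pad=8.0)
        avg = dl.average_subvolumes(self.make_set([g.copy() for _ in range(4)]))
        assert np.allclose(avg.values, g.values, atol=1e-6)

    def test_noise_reduced_by_sqrt_n(self, template_alpha):
        g = dl.simulate_density(template_alpha, 8.0, 2.0, pad=8.0)
        sigma, N = 0.3, 16
        noisy = [dl.add_noise(g, sigma, seed=100 + i) for i in range(N)]
        avg = dl.average_subvolumes(self.make_set(noisy))
        resid_std = float((avg.values - g.values).std())
        assert resid_std == pytest.approx(sigma / np.sqrt(N), rel=0.10)

    def test_cc_improves_with_n(self, template_alpha):
        g = dl.simulate_density(template_alpha, 8.0, 2.0, pad=8.0)
        sigma = float(g.values.std()) * 2
        ccs = []
        for N in (2, 8, 32):
            noisy = [dl.add_noise(g, sigma, seed=500 + i) for i in range(N)]
            avg = dl.average_subvolumes(self.make_set(noisy))
            ccs.append(dl.real_space_cc(avg, g))
        assert ccs[0] < ccs[1] < ccs[2]

    def test_refinement_recovers_shifted_copies(self, template_alpha):
        g = dl.simulate_density(template_alpha, 8.0, 2.0, pad=12.0)
        vals = g.values
        shifted = [dl.DensityGrid(np.roll(vals, s, axis=(0, 1, 2)),
                                  2.0, g.origin)
                   for s in [(0, 0, 0), (2, 0, -1), (-1, 2, 0), (0, -2, 2)]]
        blurred = dl.average_subvolumes(self.make_set(shifted))
        refined = dl.average_subvolumes(self.make_set(shifted), refine=True)
        cc_blurred = dl.real_space_cc(blurred.values, vals)
        cc_refined = dl.real_space_cc(refined.values, vals)
        assert cc_refined > cc_blurred

    def test_single_subvolume_rejected(self, template_alpha):
        g = dl.simulate_density(template_alpha, 8.0, 2.0, pad=8.0)
        with pytest.raises(ValueError):
            dl.average_subvolumes(self.make_set([g]))
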