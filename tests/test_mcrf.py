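"""MCRF model: density, potentials, energies, gradients, solver, baseline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from rcus.acquisition import (NoiseSpec, Observation, SystemOperator,
                              multiplicative_speckle)
from rcus.mcrf import (CliqueStructure, MCRFConfig, SliceProblem,
                       baseline_interpolation, combined_penalty, estimate_sigma,
                       fisher_tippett_mode, fisher_tippett_pdf,
                       make_uncertainty_layer, penalty_fov, penalty_sp,
                       reconstruct_slice, reconstruct_volume, total_energy,
                       energy_gradient, unary_energy)
from rcus.psf import gaussian_psf_bank
from rcus.volumes import LatticeSpec, SampleMask, Volume3D


def identity_op(shape2d):
    return SystemOperator(None, LatticeSpec((shape2d[0], 1, shape2d[1])))


def slice_obs(g2, observed2, lattice, domain="log"):
    g3 = np.where(observed2, g2, np.nan)[:, None, :]
    vol = Volume3D(lattice, g3, domain)
    return Observation(vol, SampleMask(lattice, observed2[:, None, :]))


class TestFisherTippett:
    def test_density_value_at_unit_scale(self):
        # sigma = 1/sqrt(2) makes ln(2 sigma^2) = 0; p(0) = 2/e
        assert fisher_tippett_pdf(0.0, 2 ** -0.5) == pytest.approx(2 * math.exp(-1))

    @pytest.mark.parametrize("sigma", [0.3, 1 / math.sqrt(2), 1.0, 2.5])
    def test_mode_location(self, sigma):
        mode = fisher_tippett_mode(sigma)
        eps = 1e-4
        p0 = fisher_tippett_pdf(mode, sigma)
        assert p0 > fisher_tippett_pdf(mode + eps, sigma)
        assert p0 > fisher_tippett_pdf(mode - eps, sigma)

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 3.0])
    def test_density_normalized(self, sigma):
        total, _ = quad(lambda x: fisher_tippett_pdf(x, sigma), -20, 10)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            fisher_tippett_pdf(0.0, 0.0)


class TestEstimateSigma:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        sigma = 1.0
        amps = rng.rayleigh(sigma, 100_000)
        est = estimate_sigma(np.log(amps))
        assert est == pytest.approx(1.0, abs=0.02)

    def test_log_shift_scales_sigma(self):
        rng = np.random.default_rng(1)
        logs = np.log(rng.rayleigh(1.0, 50_000))
        k = 3.0
        assert estimate_sigma(logs + math.log(k)) == pytest.approx(
            k * estimate_sigma(logs), rel=1e-12)

    def test_small_and_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            estimate_sigma(np.zeros(10))
        with pytest.raises(ValueError):
            estimate_sigma(np.ones(100))


class TestUncertaintyLayer:
    def test_complement(self, small_lattice, rng):
        observed = rng.random(small_lattice.shape) > 0.3
        observed[0, 0, 0] = True
        layer = make_uncertainty_layer(SampleMask(small_lattice, observed))
        assert (layer.cr == 1 - observed).all()
        assert layer.cr.sum() + observed.sum() == observed.size

    def test_all_observed(self, small_lattice):
        layer = make_uncertainty_layer(
            SampleMask(small_lattice, np.ones(small_lattice.shape, bool)))
        assert not layer.cr.any()


class TestPenalties:
    CFG = MCRFConfig()

    def test_identical_voxel_weight_one(self):
        assert penalty_sp((3, 4), (3, 4), 5.0) == 1.0
        assert penalty_fov(0.5, 0.5, 0.03) == 1.0

    def test_characteristic_scales(self):
        # d_E = sigma_sp and |dg| = sigma_fov both give exp(-1)
        assert penalty_sp((0, 0), (3, 4), 5.0) == pytest.approx(math.exp(-1))
        assert penalty_fov(0.0, 0.03, 0.03) == pytest.approx(math.exp(-1))

    @given(st.floats(0.1, 20), st.floats(0.1, 20))
    @settings(max_examples=30, deadline=None)
    def test_sp_strictly_decreasing_in_distance(self, d1, d2):
        lo, hi = sorted((d1, d2))
        if hi - lo > 1e-9:
            assert penalty_sp((0, 0), (lo, 0), 5.0) > penalty_sp((0, 0), (hi, 0), 5.0)

    def test_fov_vanishes_across_large_jumps(self):
        assert penalty_fov(0.0, 1.0, 0.03) < 1e-100

    @given(st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=30, deadline=None)
    def test_combined_bounded_by_factors(self, gi, gj):
        w = combined_penalty((0, 0), (1, 2), gi, gj, self.CFG)
        assert w <= min(penalty_sp((0, 0), (1, 2), self.CFG.sigma_sp),
                        penalty_fov(gi, gj, self.CFG.sigma_fov)) + 1e-15

    def test_unobserved_endpoint_falls_back_to_spatial(self):
        w = combined_penalty((0, 0), (1, 0), 0.0, 99.0, self.CFG, observed_j=False)
        assert w == pytest.approx(penalty_sp((0, 0), (1, 0), self.CFG.sigma_sp))


class TestEnergies:
    def test_unary_zero_when_all_missing(self):
        cr = np.ones((6, 6), bool)
        m, total = unary_energy(np.random.default_rng(0).random((6, 6)),
                                np.zeros((6, 6)), cr, identity_op((6, 6)), 1.0)
        assert total == 0.0
        assert not m.any()

    def test_unary_minimum_at_mode_residual(self):
        """With d = ln(2 sigma^2)/2 at every voxel the per-voxel unary energy is
        minimal; any single-voxel perturbation raises it."""
        sigma = 0.8
        g = np.full((5, 5), 1.3)
        f = g - fisher_tippett_mode(sigma)
        cr = np.zeros((5, 5), bool)
        op = identity_op((5, 5))
        _, e0 = unary_energy(f, g, cr, op, sigma)
        for delta in (0.05, -0.05):
            fp = f.copy()
            fp[2, 2] += delta
            _, e1 = unary_energy(fp, g, cr, op, sigma)
            assert e1 > e0

    def test_unary_additive_in_observed_count(self, rng):
        g = rng.standard_normal((8, 8))
        f = rng.standard_normal((8, 8))
        cr_half = np.zeros((8, 8), bool)
        cr_half[:, 4:] = True
        _, e_half = unary_energy(f, g, cr_half, identity_op((8, 8)), 1.0)
        _, e_full = unary_energy(f, g, np.zeros((8, 8), bool), identity_op((8, 8)), 1.0)
        cr_other = ~cr_half
        _, e_other = unary_energy(f, g, cr_other, identity_op((8, 8)), 1.0)
        assert e_half + e_other == pytest.approx(e_full, rel=1e-12)

    def test_sentinel_leakage_detected(self):
        g = np.zeros((4, 4))
        g[1, 1] = np.nan  # claimed observed but missing
        cr = np.zeros((4, 4), bool)
        with pytest.raises(ValueError, match=r"\(1, 1\)"):
            unary_energy(np.zeros((4, 4)), g, cr, identity_op((4, 4)), 1.0)

    def test_pairwise_zero_for_constant_field(self):
        from rcus.mcrf import pairwise_energy

        g = np.zeros((8, 8))
        _, total = pairwise_energy(np.full((8, 8), 2.5), g, MCRFConfig())
        assert total == 0.0

    def test_pairwise_linear_in_bump_height(self):
        from rcus.mcrf import pairwise_energy

        g = np.zeros((9, 9))
        cfg = MCRFConfig()
        totals = []
        for delta in (0.5, 1.0):
            f = np.zeros((9, 9))
            f[4, 4] = delta
            totals.append(pairwise_energy(f, g, cfg)[1])
        assert totals[0] > 0
        assert totals[1] == pytest.approx(2 * totals[0], rel=1e-9)

    def test_fov_gating_protects_true_edges(self):
        """Smoothing across an observed high-contrast boundary costs far less
        than the same jump on a flat observed background."""
        from rcus.mcrf import pairwise_energy

        cfg = MCRFConfig(fov_normalize=False, sigma_fov=0.3)
        f = np.zeros((8, 8))
        f[:, 4:] = 1.0
        g_edge = f * 5.0          # observed contrast matches the jump
        g_flat = np.zeros((8, 8))  # jump is a false edge on flat data
        _, e_edge = pairwise_energy(f, g_edge, cfg)
        _, e_flat = pairwise_energy(f, g_flat, cfg)
        assert e_edge < 0.2 * e_flat

    def test_total_energy_weighting(self, rng):
        g = rng.standard_normal((6, 6))
        f = rng.standard_normal((6, 6))
        cr = np.zeros((6, 6), bool)
        op = identity_op((6, 6))
        e = total_energy(f, g, cr, op, MCRFConfig(alpha=0.0, beta=2.0), sigma=1.0)
        assert e.total == pytest.approx(2.0 * e.pairwise)
        e2 = total_energy(f, g, np.ones((6, 6), bool), op,
                          MCRFConfig(alpha=1.0, beta=0.0), sigma=1.0)
        assert e2.total == 0.0

    def test_energy_additive_over_disjoint_slices(self, rng):
        cfg = MCRFConfig()
        op = identity_op((6, 6))
        parts = []
        fs, gs = [], []
        for _ in range(2):
            f, g = rng.standard_normal((6, 6)), rng.standard_normal((6, 6))
            fs.append(f)
            gs.append(g)
            parts.append(total_energy(f, g, np.zeros((6, 6), bool), op, cfg, 1.0).total)
        # slices are independent: stacked problem energy = sum of parts
        assert sum(parts) == pytest.approx(parts[0] + parts[1])


class TestGradient:
    @pytest.mark.parametrize("use_bank", [False, True])
    def test_matches_finite_differences(self, rng, use_bank):
        n = 8
        lat = LatticeSpec((n, 1, n), (0.25, 0.25, 0.25), (0.0, 0.0, 1.0))
        bank = gaussian_psf_bank((1.0, 2.75), 1, 0.6, 0.5, lat) if use_bank else None
        op = SystemOperator(bank, lat)
        observed = rng.random((n, n)) > 0.4
        observed[0, 0] = True
        g = np.where(observed, rng.standard_normal((n, n)), np.nan)
        cfg = MCRFConfig(alpha=0.7, beta=0.4, sigma_fov=0.5, fov_normalize=False,
                         clique=CliqueStructure(5))
        f = rng.standard_normal((n, n)) * 0.5
        problem = SliceProblem(g, observed, op, cfg, sigma=0.9)
        grad = problem.gradient(f)
        h = 1e-6
        fd = np.zeros_like(f)
        for i in range(n):
            for j in range(n):
                fp, fm = f.copy(), f.copy()
                fp[i, j] += h
                fm[i, j] -= h
                fd[i, j] = (problem.energy(fp).total - problem.energy(fm).total) / (2 * h)
        assert np.abs(grad - fd).max() / np.abs(fd).max() < 1e-5

    def test_flat_field_all_missing_has_zero_gradient(self):
        g = np.full((6, 6), np.nan)
        problem = SliceProblem(g, np.zeros((6, 6), bool), identity_op((6, 6)),
                               MCRFConfig(beta=1.0), sigma=1.0)
        grad = problem.gradient(np.full((6, 6), 3.0))
        assert not grad.any()

    def test_unary_gradient_scales_with_alpha(self, rng):
        g = rng.standard_normal((6, 6))
        f = rng.standard_normal((6, 6))
        cr = np.zeros((6, 6), bool)
        op = identity_op((6, 6))
        g1 = energy_gradient(f, g, cr, op, MCRFConfig(alpha=0.5, beta=0.0), 1.0)
        g2 = energy_gradient(f, g, cr, op, MCRFConfig(alpha=1.0, beta=0.0), 1.0)
        np.testing.assert_allclose(2 * g1, g2, rtol=1e-12)


class TestSolver:
    def test_energy_trace_non_increasing(self, slice_lattice, rng):
        g2 = rng.standard_normal((16, 16))
        observed = rng.random((16, 16)) > 0.5
        observed[0, 0] = True
        obs = slice_obs(g2, observed, slice_lattice)
        res = reconstruct_slice(obs, None, MCRFConfig(max_iters=60, sigma=1.0))
        assert (np.diff(res.energy_trace) <= 1e-12).all()

    def test_noise_free_identity_fixed_point(self, slice_lattice):
        """Fully observed, noise-free, identity H: the estimate converges to
        the observation itself (sigma self-centers the residual mode at 0)."""
        xs = np.linspace(0, 1, 16)
        g2 = np.log(1.0 + np.add.outer(xs, xs))
        observed = np.ones((16, 16), bool)
        obs = slice_obs(g2, observed, slice_lattice)
        res = reconstruct_slice(obs, None, MCRFConfig(alpha=1.0, beta=0.05,
                                                      max_iters=300, energy_tol=1e-12))
        rms = np.sqrt(np.mean((res.f_log.values[:, 0, :] - g2) ** 2))
        assert rms < 1e-3

    def test_inpainting_beats_interpolation_on_missing_columns(self, slice_lattice):
        """Piecewise-constant phantom with 50% of columns removed: the MCRF
        fill has lower missing-region RMS than the bilinear baseline."""
        rng = np.random.default_rng(3)
        truth = np.where(np.arange(16)[:, None] < 8, 0.0, 2.0) * np.ones((16, 16))
        noise = NoiseSpec(seed=3)
        speckled = truth + np.log(noise.draw((16, 16), np.random.default_rng(3)))
        observed = np.zeros((16, 16), bool)
        observed[:, ::2] = True
        obs = slice_obs(speckled, observed, slice_lattice)
        cfg = MCRFConfig(alpha=0.7, beta=0.3, sigma=0.7979,
                         clique=CliqueStructure(5), max_iters=200)
        res = reconstruct_slice(obs, None, cfg)
        base = baseline_interpolation(obs)
        miss = ~observed
        err_m = np.sqrt(np.mean((res.f_log.values[:, 0, :][miss] - truth[miss]) ** 2))
        err_b = np.sqrt(np.mean((base.values[:, 0, :][miss] - truth[miss]) ** 2))
        assert err_m < err_b

    def test_rms_error_decreases_with_noise_level(self, slice_lattice):
        """Reconstruction error shrinks monotonically as speckle scale drops."""
        truth = np.where(np.arange(16)[:, None] < 8, 0.0, 1.5) * np.ones((16, 16))
        observed = np.ones((16, 16), bool)
        errs = []
        for scale in (1.0, 0.4, 0.1):
            rng = np.random.default_rng(7)
            noisy = truth + scale * np.log(np.random.default_rng(7).rayleigh(
                np.sqrt(2 / np.pi), (16, 16)))
            obs = slice_obs(noisy, observed, slice_lattice)
            res = reconstruct_slice(obs, None, MCRFConfig(max_iters=150))
            errs.append(np.sqrt(np.mean((res.f_log.values[:, 0, :] - truth) ** 2)))
        assert errs[0] > errs[1] > errs[2]

    def test_flux_gain_near_one_for_clean_data(self, slice_lattice):
        g2 = np.full((16, 16), 0.5)
        g2[4:12, 4:12] = 1.5
        obs = slice_obs(g2, np.ones((16, 16), bool), slice_lattice)
        res = reconstruct_slice(obs, None, MCRFConfig(alpha=1.0, beta=0.01, max_iters=100))
        assert res.flux_gain == pytest.approx(1.0, abs=0.05)

    def test_edge_preservation_with_speckle_suppression(self):
        """Under the method's operating conditions (blur, speckle, sparse fan
        sampling) the cyst boundary contrast is retained within 20% of the
        clean phantom's while background variance drops at least 5x versus
        the observation (the ENL mechanism)."""
        from rcus.acquisition import (CystSpec, PhantomSpec, echogenicity_map,
                                      fan_geometry, observe)
        from rcus.psf import gaussian_psf_bank

        n, sp = 64, 0.25
        lat = LatticeSpec((n, 1, n), (sp, sp, sp), (-(n - 1) / 2 * sp, 0.0, 3.0))
        spec = PhantomSpec(((-8, 8), (-1, 1), (3, 19)),
                           cysts=[CystSpec((0, 0, 10), 6.0)], seed=0)
        ideal = echogenicity_map(spec, lat)
        bank = gaussian_psf_bank((3.0, 19.0), 2, [0.5, 0.8], 0.4, lat)
        obs = observe(ideal, bank, NoiseSpec(seed=1), fan_geometry(40, 28.0, 0.12))
        res = reconstruct_slice(obs.to_log(), bank,
                                MCRFConfig(max_iters=250, energy_tol=1e-8))
        rec = res.f_linear.values[:, 0, :]
        tru = ideal.values[:, 0, :]
        prof_r = rec[29:34].mean(axis=0)
        prof_t = tru[29:34].mean(axis=0)
        rise_r = prof_r[24:28].mean() - prof_r[8:12].mean()
        rise_t = prof_t[24:28].mean() - prof_t[8:12].mean()
        assert abs(rise_r - rise_t) < 0.2 * rise_t
        bx = (slice(15, 23), slice(36, 56))  # homogeneous background box
        var_obs = np.nanvar(obs.g.values[:, 0, :][bx])
        var_rec = rec[bx].var()
        assert var_rec * 5 <= var_obs


class TestBaseline:
    def test_fully_observed_is_identity(self, slice_lattice, rng):
        g2 = rng.standard_normal((16, 16))
        obs = slice_obs(g2, np.ones((16, 16), bool), slice_lattice)
        out = baseline_interpolation(obs)
        np.testing.assert_array_equal(out.values[:, 0, :], g2)

    def test_single_hole_filled_with_surrounding_value(self, slice_lattice):
        g2 = np.full((16, 16), 7.0)
        observed = np.ones((16, 16), bool)
        observed[8, 8] = False
        obs = slice_obs(g2, observed, slice_lattice)
        out = baseline_interpolation(obs)
        assert out.values[8, 0, 8] == pytest.approx(7.0)

    def test_affine_field_recovered_exactly(self, slice_lattice, rng):
        ix, iz = np.meshgrid(np.arange(16.0), np.arange(16.0), indexing="ij")
        g2 = 0.3 * ix - 0.7 * iz + 2.0
        observed = rng.random((16, 16)) > 0.4
        observed[[0, 0, -1, -1], [0, -1, 0, -1]] = True  # keep hull covering
        obs = slice_obs(g2, observed, slice_lattice)
        out = baseline_interpolation(obs)
        np.testing.assert_allclose(out.values[:, 0, :], g2, atol=1e-9)

    def test_empty_slice_rejected(self):
        lat = LatticeSpec((4, 2, 4))
        vals = np.full(lat.shape, np.nan)
        vals[:, 0, :] = 1.0
        observed = np.zeros(lat.shape, bool)
        observed[:, 0, :] = True
        obs = Observation(Volume3D(lat, vals, "log"), SampleMask(lat, observed))
        with pytest.raises(ValueError, match="slice 1"):
            baseline_interpolation(obs)


class TestVolumeReconstruction:
    def test_single_slice_volume_matches_slice_solver(self, slice_lattice, rng):
        g2 = rng.standard_normal((16, 16))
        observed = rng.random((16, 16)) > 0.3
        observed[0, 0] = True
        obs = slice_obs(g2, observed, slice_lattice)
        cfg = MCRFConfig(max_iters=40, sigma=1.0)
        r_slice = reconstruct_slice(obs, None, cfg)
        r_vol = reconstruct_volume(obs, None, cfg)
        np.testing.assert_allclose(r_vol.f_log.values, r_slice.f_log.values)

    def test_volume_energy_is_sum_of_slices(self, rng):
        lat = LatticeSpec((12, 3, 12), (0.25, 0.25, 0.25))
        vals = rng.standard_normal(lat.shape)
        observed = rng.random(lat.shape) > 0.3
        observed[0, :, 0] = True
        obs = Observation(Volume3D(lat, np.where(observed, vals, np.nan), "log"),
                          SampleMask(lat, observed))
        cfg = MCRFConfig(max_iters=30, sigma=1.0)
        res = reconstruct_volume(obs, None, cfg)
        assert res.slice_traces is not None and len(res.slice_traces) == 3
        total_final = sum(t[-1] for t in res.slice_traces)
        assert res.final_energy == pytest.approx(total_final, rel=1e-12)
        assert (np.diff(res.energy_trace) <= 1e-9).all()
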