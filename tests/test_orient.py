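"""Correlation-maximization engine: slices, polar resampling, normalization,
FFT in-plane search, global assignment, merging, and the CM loop."""

import numpy as np
import pytest

from spirecon.geometry import (
    euler_to_matrix,
    ewald_qmap,
    rotation_angle_between,
    sample_orientation_grid,
)
from spirecon.orient import (
    CMConfig,
    PolarSlice,
    best_orientation,
    cartesian_to_polar,
    extract_slice,
    inplane_correlate,
    merge_volume,
    normalize_polar,
    normalize_rings,
    run_cm,
)
from spirecon.scatter import FourierVolume
from spirecon.simulate import SimulationParams, bin2x2, bin2x2_arrays, simulate_pattern

R_IDX = np.arange(2, 14)
N_THETA = 128


def _polar_pattern(counts, mask, r_idx=R_IDX, n_theta=N_THETA):
    polar = cartesian_to_polar(counts, ~mask, r_idx, n_theta)
    return normalize_polar(polar)


@pytest.fixture(scope="module")
def noiseless_pattern(blob_model, geom64):
    params = SimulationParams(2e15, poisson=False)
    return bin2x2(simulate_pattern(blob_model, geom64, params, (0.8, 1.2, 2.5)))


class TestExtractSlice:
    def test_exact_on_linear_field(self, geom64):
        """Trilinear interpolation reproduces a linear ramp f(q) = a q_x exactly."""
        geom_b = geom64.binned(2)
        dim, dq = 64, geom_b.center_q_pitch / 2
        ax = (np.arange(dim) - dim // 2) * dq
        ramp = np.broadcast_to(3.0 * ax[:, None, None], (dim,) * 3).copy()
        vol = FourierVolume(dimension=dim, voxel_pitch_q=dq, intensity=ramp,
                           weight=np.ones((dim,) * 3),
                           missing_mask=np.zeros((dim,) * 3, bool))
        sl, ok = extract_slice(vol, (0.0, 0.0, 0.0), geom_b)
        q = ewald_qmap(geom_b)
        assert np.allclose(sl[ok], 3.0 * q[..., 0][ok], atol=1e-9)

    def test_matches_noiseless_simulated_pattern(self, blob_model, geom64,
                                                 ref_volume, noiseless_pattern):
        """A reference-volume slice reproduces the simulated pattern ring-wise
        (Pearson > 0.99 inside the usable band)."""
        geom_b = geom64.binned(2)
        sl, ok = extract_slice(ref_volume, (0.8, 1.2, 2.5), geom_b)
        q = np.linalg.norm(ewald_qmap(geom_b), axis=-1) / geom_b.center_q_pitch
        for r in range(3, 13):
            sel = (np.abs(q - r) < 0.5) & ok
            a, b = noiseless_pattern.counts[sel], sl[sel]
            cc = np.corrcoef(a, b)[0, 1]
            assert cc > 0.99

    def test_gamma_is_an_in_plane_shift(self, ref_volume, geom64):
        """Slice at (a, b, gamma=k dtheta) equals the gamma=0 slice circularly
        shifted by k azimuth samples (up to interpolation error)."""
        geom_b = geom64.binned(2)
        k = 10
        gamma = 2 * np.pi * k / N_THETA
        base = extract_polar(ref_volume, (0.9, 0.7, 0.0), geom_b)
        rot = extract_polar(ref_volume, (0.9, 0.7, gamma), geom_b)
        shifted = np.roll(base, -k, axis=1)
        err = np.abs(rot - shifted).max() / np.abs(base).max()
        assert err < 0.01


def extract_polar(volume, euler, geom_b, r_idx=R_IDX, n_theta=N_THETA):
    from spirecon.geometry import polar_qmap
    from spirecon._interp import trilinear

    vals, valid = volume.matching_values()
    q = polar_qmap(geom_b, r_idx, n_theta)
    coords = volume.q_to_voxel(q @ euler_to_matrix(euler).T)
    out, _ = trilinear(vals, None if valid.all() else valid, coords)
    return out


class TestCartesianToPolar:
    def test_radially_symmetric_slice_gives_constant_rings(self):
        n = 32
        c = (n - 1) / 2
        yy, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
        rr = np.hypot(yy, xx)
        polar = cartesian_to_polar(np.exp(-rr / 10), None, np.arange(2, 12), 64)
        spread = polar.values.std(axis=1) / polar.values.mean(axis=1)
        assert (spread < 0.01).all()

    def test_off_axis_spot_lands_at_its_polar_coordinates(self):
        n, r0, k0, n_theta = 32, 8.0, 24, 96
        c = (n - 1) / 2
        theta0 = 2 * np.pi * k0 / n_theta
        yy, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
        spot = np.exp(-((xx - r0 * np.cos(theta0)) ** 2
                        + (yy - r0 * np.sin(theta0)) ** 2) / 2.0)
        polar = cartesian_to_polar(spot, None, np.arange(2, 14), n_theta)
        ring, azim = np.unravel_index(np.argmax(polar.values), polar.values.shape)
        assert abs(polar.r_indices[ring] - r0) <= 1
        assert min(abs(azim - k0), n_theta - abs(azim - k0)) <= 1

    def test_rotation_becomes_circular_shift(self):
        """An image built as g(theta - k dtheta) yields the polar array of
        g(theta) circularly shifted by k samples."""
        n, n_theta, k = 32, 64, 7
        c = (n - 1) / 2
        yy, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
        theta = np.arctan2(yy, xx)
        rr = np.hypot(yy, xx)

        def image(shift):
            return np.cos(3 * (theta - shift)) * np.exp(-((rr - 8) / 6) ** 2)

        base = cartesian_to_polar(image(0.0), None, np.arange(3, 12), n_theta)
        rot = cartesian_to_polar(image(2 * np.pi * k / n_theta), None,
                                 np.arange(3, 12), n_theta)
        # bilinear resampling error differs between the two samplings (~3%)
        err = np.abs(rot.values - np.roll(base.values, k, axis=1)).max()
        assert err < 0.05 * np.abs(base.values).max()

    def test_out_of_grid_ring_rejected(self):
        with pytest.raises(ValueError):
            cartesian_to_polar(np.ones((16, 16)), None, np.arange(2, 12), 32)


class TestNormalizeRings:
    def test_zero_mean_unit_variance(self):
        rng = np.random.default_rng(0)
        vals = rng.random((5, 64)) * 100 + 7
        out, ok = normalize_rings(vals, np.ones_like(vals, bool))
        assert ok.all()
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(out.var(axis=1), 1.0, atol=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.random((4, 32))
        valid = np.ones_like(vals, bool)
        a, _ = normalize_rings(vals, valid)
        b, _ = normalize_rings(2.5 * vals + 11.0, valid)
        assert np.allclose(a, b, atol=1e-10)

    def test_matches_scalar_oracle_with_outlier(self):
        ring = np.array([1.0, 1.0, 1.0, 9.0])
        out, ok = normalize_rings(ring[None], np.ones((1, 4), bool))
        mu, sd = ring.mean(), ring.std()
        assert ok[0]
        assert np.allclose(out[0], (ring - mu) / sd)

    def test_constant_ring_flagged_invalid(self):
        vals = np.vstack([np.full(16, 3.0), np.arange(16.0)])
        _, ok = normalize_rings(vals, np.ones_like(vals, bool))
        assert not ok[0] and ok[1]

    def test_invalid_samples_excluded_from_statistics(self):
        vals = np.array([[1.0, 2.0, 3.0, 1000.0]])
        valid = np.array([[True, True, True, False]])
        out, ok = normalize_rings(vals, valid)
        assert ok[0]
        assert np.allclose(out[0, :3].mean(), 0.0, atol=1e-12)
        assert out[0, 3] == 0.0


class TestInplaneCorrelate:
    def _normalized(self, rng, n_rings=6, n_theta=64):
        vals = rng.random((n_rings, n_theta))
        return normalize_polar(PolarSlice(vals, np.ones_like(vals, bool),
                                          np.arange(2, 2 + n_rings)))

    def test_self_correlation_is_unity_at_zero(self):
        pol = self._normalized(np.random.default_rng(0))
        gamma, c_max, _ = inplane_correlate(pol, pol)
        assert gamma == pytest.approx(0.0, abs=1e-9)
        assert c_max == pytest.approx(1.0, abs=1e-6)

    def test_pure_rotation_recovered_exactly(self):
        """If the reference ring set is the pattern advanced by k azimuth
        samples (S[t] = M[t-k], i.e. M[t] = S[t+k]), gamma_best = 2 pi k / n."""
        pol = self._normalized(np.random.default_rng(1))
        k = 13
        shifted = PolarSlice(np.roll(pol.values, k, axis=1), pol.valid, pol.r_indices)
        gamma, _, _ = inplane_correlate(pol, shifted, parabolic=False)
        assert gamma == pytest.approx(2 * np.pi * k / pol.n_theta, abs=1e-12)

    def test_curve_equals_brute_force_shift_and_dot(self):
        """The FFT curve matches the O(n_theta^2 N_r) direct loop to 1e-8."""
        rng = np.random.default_rng(2)
        a, b = self._normalized(rng), self._normalized(rng)
        _, _, curve = inplane_correlate(a, b)
        n_theta, n_rings = a.n_theta, len(a.r_indices)
        brute = np.array([
            sum((a.values[r] * np.roll(b.values[r], -k)).sum()
                for r in range(n_rings)) / (n_theta * n_rings)
            for k in range(n_theta)
        ])
        assert np.abs(curve - brute).max() < 1e-8

    def test_no_common_rings_raises(self):
        pol = self._normalized(np.random.default_rng(3))
        dead = PolarSlice(pol.values, np.zeros_like(pol.valid), pol.r_indices)
        with pytest.raises(ValueError):
            inplane_correlate(pol, dead)


class TestBestOrientation:
    def test_recovers_simulation_orientation(self, blob_model, geom64,
                                             ref_volume, noiseless_pattern):
        """Noiseless pattern + true-model reference: recovered orientation
        within 1.5 delta_beta geodesic of the truth."""
        geom_b = geom64.binned(2)
        pol = _polar_pattern(noiseless_pattern.counts, noiseless_pattern.mask)
        grid = sample_orientation_grid(0.1)
        e_hat, c = best_orientation(pol, ref_volume, grid, geom_b)
        dev = rotation_angle_between(euler_to_matrix((0.8, 1.2, 2.5)),
                                     euler_to_matrix(e_hat))
        assert dev <= 1.5 * 0.1 * 180 / np.pi
        assert c > 0.9

    def test_noise_pattern_scores_below_matched_pattern(self, geom64, ref_volume,
                                                        noiseless_pattern):
        geom_b = geom64.binned(2)
        grid = sample_orientation_grid(0.3)
        rng = np.random.default_rng(4)
        noise = rng.random(noiseless_pattern.counts.shape)
        mask = np.zeros(noise.shape, bool)
        _, c_noise = best_orientation(_polar_pattern(noise, mask),
                                      ref_volume, grid, geom_b)
        pol = _polar_pattern(noiseless_pattern.counts, noiseless_pattern.mask)
        _, c_match = best_orientation(pol, ref_volume, grid, geom_b)
        assert c_noise < c_match

    def test_single_direction_grid_degenerate(self, geom64, ref_volume,
                                              noiseless_pattern):
        from spirecon.geometry import OrientationGrid

        geom_b = geom64.binned(2)
        grid = OrientationGrid(0.1, np.array([0.8]), np.array([1.2]))
        pol = _polar_pattern(noiseless_pattern.counts, noiseless_pattern.mask)
        e_hat, _ = best_orientation(pol, ref_volume, grid, geom_b)
        assert e_hat[0] == 0.8 and e_hat[1] == 1.2


class TestMergeVolume:
    def test_uniform_pattern_populates_an_ewald_cap(self, geom64):
        geom_b = geom64.binned(2)
        pat = np.full((32, 32), 7.0)
        mask = np.zeros((32, 32), bool)
        vol = merge_volume(pat, mask, [(0.0, 0.0, 0.0)], geom_b, 64)
        filled = vol.intensity[~vol.missing_mask]
        assert len(filled) > 0
        assert np.allclose(filled, 7.0, atol=1e-6)

    def test_mean_not_sum_of_identical_patterns(self, geom64):
        geom_b = geom64.binned(2)
        rng = np.random.default_rng(5)
        pat = rng.random((32, 32))
        mask = np.zeros((32, 32), bool)
        one = merge_volume(pat, mask, [(0.1, 0.2, 0.3)], geom_b, 64)
        two = merge_volume(np.stack([pat, pat]), mask,
                           [(0.1, 0.2, 0.3)] * 2, geom_b, 64)
        assert np.allclose(one.intensity, two.intensity, atol=1e-9)
        assert np.array_equal(one.missing_mask, two.missing_mask)

    def test_true_orientation_merge_matches_reference_intensity(
            self, small_nf):
        """All 500 noiseless patterns merged at true orientations correlate
        > 0.95 with |F|^2 of the true model in every measured-band shell."""
        from spirecon.metrics import cc_shell

        pb, mb = bin2x2_arrays(small_nf.stack.patterns, small_nf.stack.mask)
        geom_b = small_nf.geom.binned(2)
        vol = merge_volume(pb, mb, small_nf.stack.eulers, geom_b,
                           small_nf.truth_volume.dimension,
                           small_nf.truth_volume.voxel_pitch_q)
        curve = cc_shell(vol, small_nf.truth_volume)
        # measured band: rings 3..13 of the binned pattern = voxel shells 6..26
        assert np.nanmin(curve.values[6:27]) > 0.95

    def test_friedel_mates_agree_without_symmetrized_deposit(self, small_nf):
        """Merged intensity obeys I(q) = I(-q) statistically even when each
        pixel is deposited only at +Rq."""
        sub = small_nf.stack.subset(np.arange(200))
        pb, mb = bin2x2_arrays(sub.patterns, sub.mask)
        geom_b = small_nf.geom.binned(2)
        vol = merge_volume(pb, mb, sub.eulers, geom_b, 64, friedel=False)
        inten = vol.intensity
        meas = ~vol.missing_mask
        inv = np.roll(inten[::-1, ::-1, ::-1], (1, 1, 1), axis=(0, 1, 2))
        minv = np.roll(meas[::-1, ::-1, ::-1], (1, 1, 1), axis=(0, 1, 2))
        both = meas & minv
        cc = np.corrcoef(inten[both], inv[both])[0, 1]
        assert cc > 0.9


class TestRunCM:
    def test_zero_iterations_single_assignment_pass(self, small_nf):
        """max_iters = 0 still assigns every pattern once against the initial
        reference volume."""
        sub_stack = small_nf.stack.subset(np.arange(40))
        cfg = CMConfig(delta_beta=0.2, refine_delta_beta=None, max_iters=0)
        state = run_cm(sub_stack, cfg, reference=small_nf.truth_volume)
        assert state.n_iterations == 1
        assert len(state.cc_mean_trace) == 1
        devs = [rotation_angle_between(euler_to_matrix(t), euler_to_matrix(a))
                for t, a in zip(sub_stack.eulers, state.assigned_eulers)]
        assert np.median(devs) < 3 * 0.2 * 180 / np.pi

    def test_cc_values_in_range(self, cm_small_accuracy):
        cc = cm_small_accuracy.cc_per_pattern
        assert ((cc >= -1 - 1e-9) & (cc <= 1 + 1e-9)).all()

    def test_trace_non_decreasing_after_second_iteration(self, cm_convergence_pair):
        """CC_mean plateaus monotonically (tolerance 1e-3) past iteration 2."""
        for state in cm_convergence_pair:
            trace = state.cc_mean_trace
            for a, b in zip(trace[1:], trace[2:]):
                assert b >= a - 1e-3

    def test_pm_reference_beats_random_start_accuracy(self, small_nf,
                                                      cm_convergence_pair):
        pm, rand = cm_convergence_pair
        assert max(pm.cc_mean_trace) >= max(rand.cc_mean_trace) - 1e-3
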