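"""Vascular quantification: skeletons, flow, Murray fits, profiles, FSC, RI."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.ndimage import gaussian_filter

from lensulm.grids import ScalarVolume, VolumeGrid
from lensulm.phantoms import generate_physio, make_vessel_tree
from lensulm.quantify import (
    GatedCurve,
    VelocityProfile,
    adjacent_voxel_ttest,
    extract_velocity_profile,
    fourier_shell_correlation,
    gated_velocity_curve,
    murray_fit,
    resistivity_index,
    segment_flow_rate,
    skeletonize_radii,
)
from lensulm.ulm import Localization, MicrobubbleTrack


class TestSkeleton:
    def test_empty_density_empty_skeleton(self):
        grid = VolumeGrid((0, 0, 0), (1, 1, 1), (10, 10, 10))
        sk = skeletonize_radii(ScalarVolume(grid, np.zeros((10, 10, 10))))
        assert sk.n_points == 0

    def test_cylinder_radius_within_half_voxel(self):
        grid = VolumeGrid((0, 0, 0), (1, 1, 1), (40, 25, 25))
        xx, yy, zz = np.meshgrid(*[np.arange(s) for s in (40, 25, 25)], indexing="ij")
        mask = (yy - 12) ** 2 + (zz - 12) ** 2 <= 10**2
        sk = skeletonize_radii(ScalarVolume(grid, mask.astype(float)))
        interior = (sk.points[:, 0] > 5) & (sk.points[:, 0] < 35)
        assert interior.sum() > 10
        np.testing.assert_allclose(sk.radius[interior], 10.0, atol=0.6)

    def test_adjacency_symmetric_and_inside_mask(self):
        grid = VolumeGrid((0, 0, 0), (1, 1, 1), (20, 9, 9))
        xx, yy, zz = np.meshgrid(*[np.arange(s) for s in (20, 9, 9)], indexing="ij")
        mask = (yy - 4) ** 2 + (zz - 4) ** 2 <= 9
        sk = skeletonize_radii(ScalarVolume(grid, mask.astype(float)))
        assert all(i < j for i, j in sk.adjacency)
        idx = np.round(sk.points).astype(int)
        assert mask[tuple(idx.T)].all()


class TestFlowRate:
    @staticmethod
    def profile(vmax, radius):
        return VelocityProfile(
            np.array([0.0]), [np.array([vmax])], vmax, radius, 0.0, True
        )

    def test_closed_form_75(self):
        # v_max 70.1 mm/s in an 870 um tube is 75 mL/h
        q = segment_flow_rate(self.profile(70.1, 0.435))
        assert q == pytest.approx(75.0, rel=0.01)

    def test_zero_vmax_rejected(self):
        with pytest.raises(ValueError):
            segment_flow_rate(self.profile(0.0, 0.4))

    def test_linear_in_vmax(self):
        q1 = segment_flow_rate(self.profile(50.0, 0.4))
        q2 = segment_flow_rate(self.profile(100.0, 0.4))
        assert q2 == pytest.approx(2 * q1)

    def test_failed_fit_rejected(self):
        p = VelocityProfile(np.array([0.0]), [np.array([1.0])], np.nan, np.nan, 0.0, False)
        with pytest.raises(ValueError):
            segment_flow_rate(p)


class TestMurray:
    def test_exact_cubic(self):
        r = np.array([0.1, 0.2, 0.3, 0.5, 0.8])
        fit = murray_fit(list(zip(r, 7.0 * r**3)))
        assert fit.exponent == pytest.approx(3.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.prefactor == pytest.approx(7.0, rel=1e-9)

    def test_recovery_with_flow_noise(self):
        # 10% multiplicative flow noise: exponent recovered with small bias
        # and bounded spread; oracle cross-check by brute-force grid search
        # on one realization
        rng = np.random.default_rng(99)
        exps = []
        for seed in range(100):
            tree = make_vessel_tree(6, 0.6, 2.5, seed=seed)
            r, q = tree.segment_radii_flows()
            q = q * (1 + 0.1 * rng.standard_normal(len(q)))
            if np.any(q <= 0):
                continue
            exps.append(murray_fit(list(zip(r, q))).exponent)
        exps = np.asarray(exps)
        assert abs(exps.mean() - 2.5) < 0.05
        assert exps.std() < 0.15

        tree = make_vessel_tree(6, 0.6, 2.5, seed=0)
        r, q = tree.segment_radii_flows()
        q = q * (1 + 0.1 * np.random.default_rng(7).standard_normal(len(q)))
        fit = murray_fit(list(zip(r, q)))
        grid = np.arange(1.5, 3.5, 0.001)
        lr, lq = np.log(r), np.log(q)
        sse = [np.sum((lq - (x * lr + (lq - x * lr).mean())) ** 2) for x in grid]
        assert fit.exponent == pytest.approx(grid[int(np.argmin(sse))], abs=0.002)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            murray_fit([(0.1, 1.0), (0.2, 2.0)])
        with pytest.raises(ValueError):
            murray_fit([(0.1, 1.0), (-0.2, 2.0), (0.3, 3.0)])


def tracks_in_tube(vmax, radius, rng, n_tracks=40, steps=20, noise=0.0):
    """Synthetic tracks riding Poiseuille streamlines along x at z = 50."""
    dt = 1 / 312.5
    tracks = []
    for tid in range(n_tracks):
        frac = np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        y, z = frac * radius * np.cos(phi), 50.0 + frac * radius * np.sin(phi)
        v = vmax * (1 - frac**2)
        x0 = rng.uniform(-10, 0)
        pts = np.column_stack(
            [x0 + v * dt * np.arange(steps), np.full(steps, y), np.full(steps, z)]
        )
        if noise:
            pts = pts + rng.normal(0, noise, pts.shape)
        locs = [Localization(tuple(p), f, 1.0, 0.9) for f, p in enumerate(pts)]
        vel = np.diff(pts, axis=0) / dt
        tracks.append(MicrobubbleTrack(locs, vel, tid))
    return tracks


class TestVelocityProfile:
    def test_noise_free_parabola_recovered(self, rng):
        tracks = tracks_in_tube(70.0, 0.435, rng)
        prof = extract_velocity_profile(
            tracks,
            np.array([0.0, 0.0, 50.0]),
            np.array([1.0, 0, 0]),
            np.array([0.0, 0, 1.0]),
            slab_thickness=20.0,
            min_track_steps=5,
        )
        assert prof.fit_ok
        assert prof.fitted_vmax == pytest.approx(70.0, rel=1e-3)
        assert prof.fitted_radius == pytest.approx(0.435, rel=1e-2)

    def test_noisy_vmax_within_ten_percent(self, rng):
        tracks = tracks_in_tube(93.5, 0.435, rng, n_tracks=60, noise=0.03)
        prof = extract_velocity_profile(
            tracks,
            np.array([0.0, 0.0, 50.0]),
            np.array([1.0, 0, 0]),
            np.array([0.0, 0, 1.0]),
            slab_thickness=20.0,
            min_track_steps=5,
        )
        assert prof.fit_ok
        assert prof.fitted_vmax == pytest.approx(93.5, rel=0.10)

    def test_too_few_tracks_flagged(self, rng):
        tracks = tracks_in_tube(70.0, 0.435, rng, n_tracks=2)
        prof = extract_velocity_profile(
            tracks,
            np.array([0.0, 0.0, 50.0]),
            np.array([1.0, 0, 0]),
            np.array([0.0, 0, 1.0]),
            slab_thickness=20.0,
        )
        assert not prof.fit_ok


class TestTTest:
    def test_null_calibration(self):
        # same-distribution bins: p below 0.05 in about 5% of repetitions
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            a, b = rng.normal(50, 5, (2, 100))
            prof = VelocityProfile(np.array([0.0, 1.0]), [a, b], 50.0, 1.0, 0.0, True)
            out = adjacent_voxel_ttest(prof)
            if out[0]["p"] < 0.05:
                hits += 1
        assert 0.03 < hits / n_rep < 0.07

    def test_power_against_closed_form(self):
        rng = np.random.default_rng(5)
        a = rng.normal(50, 5, 30)
        b = rng.normal(80, 5, 30)
        prof = VelocityProfile(np.array([0.0, 1.0]), [a, b], 80.0, 1.0, 0.0, True)
        out = adjacent_voxel_ttest(prof)
        assert out[0]["p"] < 1e-6
        # closed-form pooled t statistic
        sp2 = ((29 * a.var(ddof=1)) + 29 * b.var(ddof=1)) / 58
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 30))
        p_oracle = 2 * sps.t.sf(abs(t), 58)
        assert out[0]["p"] == pytest.approx(p_oracle, rel=1e-9)

    def test_identical_samples_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        prof = VelocityProfile(np.array([0.0, 1.0]), [a, a.copy()], 3.0, 1.0, 0.0, True)
        out = adjacent_voxel_ttest(prof)
        assert out[0]["p"] == 1.0

    def test_underfilled_bin_skipped(self):
        prof = VelocityProfile(
            np.array([0.0, 1.0]), [np.array([1.0]), np.array([1.0, 2.0])], 2.0, 1.0, 0.0, True
        )
        out = adjacent_voxel_ttest(prof)
        assert out[0]["skipped"]


class TestFSC:
    grid = VolumeGrid((0, 0, 0), (0.2, 0.2, 0.2), (48, 48, 48))

    def test_self_correlation_is_unity(self, rng):
        v = ScalarVolume(self.grid, rng.normal(size=(48, 48, 48)))
        res = fourier_shell_correlation(v, v)
        valid = res.shell_counts > 0
        np.testing.assert_allclose(res.fsc[valid], 1.0, atol=1e-9)

    def test_independent_noise_uncorrelated(self, rng):
        a = ScalarVolume(self.grid, rng.normal(size=(48, 48, 48)))
        b = ScalarVolume(self.grid, rng.normal(size=(48, 48, 48)))
        res = fourier_shell_correlation(a, b)
        m = res.shell_counts > 20
        bound = 3.0 / np.sqrt(res.shell_counts[m])
        assert np.all(np.abs(res.fsc[m]) < np.maximum(bound, 0.35))

    def test_scale_invariance(self, rng):
        a = ScalarVolume(self.grid, rng.normal(size=(48, 48, 48)))
        b = ScalarVolume(self.grid, gaussian_filter(rng.normal(size=(48, 48, 48)), 1.0))
        r1 = fourier_shell_correlation(a, b)
        r2 = fourier_shell_correlation(a.copy_with(5.0 * a.values), b)
        valid = r1.shell_counts > 0
        np.testing.assert_allclose(r1.fsc[valid], r2.fsc[valid], atol=1e-9)

    def test_known_cutoff_recovered(self, rng):
        # shared signal band-limited at f_c plus independent noise: the
        # crossing sits near the imposed cutoff (checked against direct
        # spectral inspection)
        n, sp = 48, 0.2
        f_c = 1.2  # cycles/mm, well below Nyquist 2.5
        sig = rng.normal(size=(n, n, n))
        F = np.fft.fftn(sig)
        fr = [np.fft.fftfreq(n, d=sp)] * 3
        fx, fy, fz = np.meshgrid(*fr, indexing="ij")
        F[np.sqrt(fx**2 + fy**2 + fz**2) > f_c] = 0.0
        s = np.real(np.fft.ifftn(F))
        s *= 10.0 / s.std()
        a = ScalarVolume(self.grid, s + rng.normal(size=(n, n, n)))
        b = ScalarVolume(self.grid, s + rng.normal(size=(n, n, n)))
        res = fourier_shell_correlation(a, b)
        assert res.resolution_mm is not None
        assert 1.0 / res.resolution_mm == pytest.approx(f_c, rel=0.15)


class TestGatedDynamics:
    @staticmethod
    def physio_and_tracks(rng, modulation=None, duration=10.0):
        physio = generate_physio(60.0, 12.0, duration, seed=3, rr_jitter=0.0)
        dt = 1 / 312.5
        n = int(duration / dt) - 10
        times = np.arange(n) * dt
        prev, rr = physio.rr_interval_of(times)
        speeds = np.full(n, 100.0)
        if modulation is not None:
            phase = (times - prev) / rr
            speeds = modulation(phase)
        pts = np.column_stack([np.cumsum(speeds) * dt, np.zeros(n), np.full(n, 50.0)])
        locs = [Localization(tuple(p), f, 1.0, 0.9) for f, p in enumerate(pts)]
        vel = np.column_stack([speeds[:-1], np.zeros((n - 1, 2))])
        return physio, [MicrobubbleTrack(locs, vel, 0)], times

    def test_constant_flow_flat_curve(self, rng):
        physio, tracks, times = self.physio_and_tracks(rng)
        curve = gated_velocity_curve(tracks, physio, times, n_bins=8)
        filled = np.isfinite(curve.velocity)
        np.testing.assert_allclose(curve.velocity[filled], 100.0, rtol=1e-6)

    def test_sinusoidal_modulation_recovered(self, rng):
        mod = lambda ph: 100.0 + 50.0 * np.sin(2 * np.pi * ph)
        physio, tracks, times = self.physio_and_tracks(rng, mod, duration=20.0)
        curve = gated_velocity_curve(tracks, physio, times, n_bins=10)
        expected = mod((curve.phase / 100.0))
        filled = np.isfinite(curve.velocity)
        np.testing.assert_allclose(curve.velocity[filled], expected[filled], rtol=0.05)

    def test_single_bin_equals_overall_mean(self, rng):
        physio, tracks, times = self.physio_and_tracks(rng)
        curve = gated_velocity_curve(tracks, physio, times, n_bins=1)
        assert curve.velocity[0] == pytest.approx(100.0, rel=1e-6)


class TestResistivityIndex:
    def test_constant_curve_zero(self):
        c = GatedCurve(np.array([25.0, 75.0]), np.array([80.0, 80.0]))
        assert resistivity_index(c) == 0.0

    def test_standard_value(self):
        c = GatedCurve(np.array([25.0, 75.0]), np.array([100.0, 40.0]))
        assert resistivity_index(c) == pytest.approx(0.6)

    def test_zero_diastolic_gives_unity(self):
        c = GatedCurve(np.array([25.0, 75.0]), np.array([90.0, 0.0]))
        assert resistivity_index(c) == pytest.approx(1.0)

    def test_zero_peak_rejected(self):
        c = GatedCurve(np.array([25.0, 75.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            resistivity_index(c)
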