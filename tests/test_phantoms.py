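"""Phantoms, microbubble kinematics, RF synthesis and physiology traces."""

import numpy as np
import pytest

from lensulm.arrays import SequenceSpec
from lensulm.motion import RigidTransform
from lensulm.phantoms import (
    MBPopulation,
    advect_microbubbles,
    apply_rigid_motion,
    block_frame_times,
    generate_physio,
    make_tube_phantom,
    make_vessel_tree,
    poiseuille_vmax,
    population_window,
    simulate_rf,
)
from lensulm.quantify import murray_fit


class TestTubePhantom:
    def test_poiseuille_vmax_closed_form(self):
        # 75 mL/h through an 870 um tube: v_max = 2 Q / (pi R^2)
        q_mm3s = 75.0 * 1000 / 3600
        expected = 2 * q_mm3s / (np.pi * 0.435**2)
        assert poiseuille_vmax(75.0, 0.435) == pytest.approx(expected)
        assert expected == pytest.approx(70.1, abs=0.2)

    def test_zero_flow_is_static(self):
        ph = make_tube_phantom(0.87, 0.0)
        assert ph.vmax() == 0.0
        pop = advect_microbubbles(ph, 1.0, np.arange(5) * 1e-3, seed=0)
        for bid in np.unique(pop.ids):
            pos = pop.positions[pop.ids == bid]
            assert np.allclose(np.diff(pos, axis=0), 0.0, atol=1e-12)

    def test_twisted_geometry_depth_range(self):
        ph = make_tube_phantom(0.87, 200.0, "twisted")
        assert len(ph.segments) == 2
        z = np.concatenate([line.points[:, 2] for line, _ in ph.segments])
        assert z.min() <= 42.5
        assert z.max() >= 79.5

    def test_bubbles_stay_inside_lumen(self):
        ph = make_tube_phantom(0.87, 100.0, depth=60.0, length=20.0)
        line, radius = ph.segments[0]
        pop = advect_microbubbles(ph, 0.5, np.arange(50) * 3.2e-3, seed=1)
        # straight tube along x at (y, z) = (0, 60)
        d = np.hypot(pop.positions[:, 1], pop.positions[:, 2] - 60.0)
        assert np.all(d <= radius + 1e-9)

    def test_centerline_displacement_matches_poiseuille(self):
        ph = make_tube_phantom(0.87, 75.0, depth=60.0, length=30.0)
        dt = 3.2e-3
        pop = advect_microbubbles(ph, 0.5, np.arange(100) * dt, seed=3)
        vmax = ph.vmax()
        for bid in np.unique(pop.ids):
            m = pop.ids == bid
            pos = pop.positions[m]
            if len(pos) < 2:
                continue
            step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
            rho = np.hypot(pos[0, 1], pos[0, 2] - 60.0)
            expected = vmax * (1 - (rho / 0.435) ** 2) * dt
            np.testing.assert_allclose(step, expected, rtol=1e-6)

    def test_no_arrivals_exactly_at_wall(self):
        ph = make_tube_phantom(0.87, 75.0)
        pop = advect_microbubbles(ph, 2.0, np.arange(30) * 3.2e-3, seed=2)
        speeds = np.linalg.norm(pop.velocities, axis=1)
        assert np.all(speeds > 0)


class TestVesselTree:
    def test_single_generation_single_segment(self):
        tree = make_vessel_tree(1, 0.6, 3.0, seed=0)
        assert len(tree.edges) == 1

    @pytest.mark.parametrize("x", [2.0, 2.5, 3.0, 3.5])
    def test_branching_identity(self, x):
        tree = make_vessel_tree(5, 0.6, x, seed=4)
        children = {}
        for p, c, r, q in tree.edges:
            children.setdefault(p, []).append((r, q))
        radius_of_child_node = {c: r for p, c, r, q in tree.edges}
        flow_of_child_node = {c: q for p, c, r, q in tree.edges}
        for node, kids in children.items():
            if node in radius_of_child_node and len(kids) == 2:
                rp = radius_of_child_node[node]
                assert rp**x == pytest.approx(sum(r**x for r, _ in kids), abs=1e-9)
                assert flow_of_child_node[node] == pytest.approx(
                    sum(q for _, q in kids), abs=1e-9
                )

    def test_noise_free_cubic_fit(self):
        tree = make_vessel_tree(6, 0.6, 3.0, seed=1)
        fit = murray_fit(list(zip(*tree.segment_radii_flows())))
        assert fit.exponent == pytest.approx(3.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_given_seed(self):
        t1 = make_vessel_tree(4, 0.6, 2.5, seed=9)
        t2 = make_vessel_tree(4, 0.6, 2.5, seed=9)
        np.testing.assert_array_equal(t1.nodes, t2.nodes)
        assert t1.edges == t2.edges

    def test_tree_bubbles_inside_segments(self):
        tree = make_vessel_tree(3, 0.6, 3.0, seed=2)
        pop = advect_microbubbles(tree, 2.0, np.arange(40) * 3.2e-3, seed=3)
        assert len(pop.positions) > 0
        # every bubble within the max segment radius of some segment line
        for p in pop.positions:
            dmin = np.inf
            for a, c, r, q in tree.edges:
                pa, pc = tree.nodes[a], tree.nodes[c]
                t = np.clip(np.dot(p - pa, pc - pa) / np.dot(pc - pa, pc - pa), 0, 1)
                dmin = min(dmin, np.linalg.norm(p - (pa + t * (pc - pa))) - r)
            assert dmin <= 1e-6


class TestSimulateRF:
    def make_seq(self, n_tx=1, vpb=1):
        return SequenceSpec(
            n_transmits_per_volume=n_tx,
            transmit_element_indices=tuple(range(n_tx)),
            volumes_per_block=vpb,
        )

    def test_no_bubbles_zero_block(self, full_layout):
        pop = MBPopulation(
            np.array([0.0]), np.empty(0, int), np.empty(0, int),
            np.empty((0, 3)), np.empty((0, 3)), {},
        )
        blocks = simulate_rf(full_layout, self.make_seq(), pop, max_depth=50.0)
        assert np.all(blocks[0].samples == 0)

    def test_echo_at_two_way_transit_time(self, single_unlensed):
        # static bubble at 40 mm on the axis of an unlensed element: the
        # echo envelope peaks at 2 * 40 mm / 1540 m/s = 51.95 us
        pop = MBPopulation(
            np.array([0.0]), np.array([0]), np.array([0]),
            np.array([[0.0, 0.0, 40.0]]), np.zeros((1, 3)), {0: 1.0},
        )
        blocks = simulate_rf(single_unlensed, self.make_seq(), pop, max_depth=50.0)
        rf = blocks[0].samples[:, 0, 0]
        t_peak = np.argmax(np.abs(rf)) / blocks[0].fs
        assert t_peak == pytest.approx(2 * 40.0 / 1.54e6, abs=1.0 / blocks[0].fs)

    def test_sampling_rate_two_per_wavelength(self, single_unlensed):
        pop = MBPopulation(
            np.array([0.0]), np.array([0]), np.array([0]),
            np.array([[0.0, 0.0, 30.0]]), np.zeros((1, 3)), {0: 1.0},
        )
        blocks = simulate_rf(single_unlensed, self.make_seq(), pop, max_depth=40.0)
        assert blocks[0].fs == pytest.approx(2e6)

    def test_linearity_in_bubbles(self, single_unlensed):
        def pop_of(positions):
            n = len(positions)
            return MBPopulation(
                np.array([0.0]), np.zeros(n, int), np.arange(n),
                np.asarray(positions), np.zeros((n, 3)),
                {i: 1.0 for i in range(n)},
            )

        a = simulate_rf(single_unlensed, self.make_seq(), pop_of([[0, 0, 30.0]]), max_depth=45.0)[0]
        b = simulate_rf(single_unlensed, self.make_seq(), pop_of([[5.0, 1.0, 38.0]]), max_depth=45.0)[0]
        ab = simulate_rf(
            single_unlensed, self.make_seq(), pop_of([[0, 0, 30.0], [5.0, 1.0, 38.0]]), max_depth=45.0
        )[0]
        num = np.abs(ab.samples - a.samples - b.samples).max()
        assert num / np.abs(ab.samples).max() < 1e-6

    def test_deterministic_under_seed(self, single_unlensed):
        pop = MBPopulation(
            np.array([0.0]), np.array([0]), np.array([0]),
            np.array([[0.0, 0.0, 30.0]]), np.zeros((1, 3)), {0: 1.0},
        )
        b1 = simulate_rf(single_unlensed, self.make_seq(), pop, noise_snr_dB=20.0, seed=7, max_depth=40.0)[0]
        b2 = simulate_rf(single_unlensed, self.make_seq(), pop, noise_snr_dB=20.0, seed=7, max_depth=40.0)[0]
        np.testing.assert_array_equal(b1.samples, b2.samples)


class TestRigidMotionOnPopulations:
    def make_pop(self, rng):
        n = 30
        return MBPopulation(
            np.arange(10) * 1e-3,
            rng.integers(0, 10, n),
            np.arange(n),
            rng.uniform(-10, 10, (n, 3)) + [0, 0, 40],
            rng.normal(size=(n, 3)),
            {},
        )

    def test_identity_unchanged(self, rng):
        pop = self.make_pop(rng)
        out = apply_rigid_motion(pop, [RigidTransform()], volumes_per_block=10)
        np.testing.assert_allclose(out.positions, pop.positions)

    def test_translation_offsets_all_points(self, rng):
        pop = self.make_pop(rng)
        tr = RigidTransform(translation=(1.0, 2.0, 3.0))
        out = apply_rigid_motion(pop, [tr], volumes_per_block=10)
        np.testing.assert_allclose(out.positions - pop.positions, [[1, 2, 3]] * 30)

    def test_rotation_then_inverse_restores(self, rng):
        pop = self.make_pop(rng)
        tr = RigidTransform(rotation=(np.radians(5), 0, 0), center=(0, 0, 40))
        moved = apply_rigid_motion(pop, [tr], volumes_per_block=10)
        back = apply_rigid_motion(moved, [tr.inverse()], volumes_per_block=10)
        np.testing.assert_allclose(back.positions, pop.positions, atol=1e-9)


class TestPhysio:
    def test_r_peak_count(self):
        tr = generate_physio(60.0, 15.0, 10.0, seed=0)
        assert abs(len(tr.r_peak_times) - 10) <= 1
        assert np.all(np.diff(tr.r_peak_times) > 0)

    def test_full_quantile_every_peak_triggers(self):
        tr = generate_physio(80.0, 12.0, 8.0, seed=1, resp_quantile=1.0)
        np.testing.assert_array_equal(tr.trigger_times(), tr.r_peak_times)

    def test_trigger_count_matches_brute_force(self):
        tr = generate_physio(75.0, 14.0, 20.0, seed=2, resp_quantile=0.4)
        brute = sum(
            1
            for t in tr.r_peak_times
            if any(a <= t <= b for a, b in tr.low_resp_windows)
        )
        assert len(tr.trigger_times()) == brute

    def test_windows_non_overlapping(self):
        tr = generate_physio(70.0, 10.0, 15.0, seed=3)
        w = tr.low_resp_windows
        assert all(w[i][1] < w[i + 1][0] for i in range(len(w) - 1))


class TestHelpers:
    def test_block_frame_times_gap(self):
        seq = SequenceSpec(volumes_per_block=4, block_period=0.3)
        t = block_frame_times(seq, 2)
        dt = 1 / seq.volume_rate
        assert len(t) == 8
        assert t[4] - t[3] == pytest.approx(dt + 0.3)
        np.testing.assert_allclose(np.diff(t[:4]), dt)

    def test_population_window_reindexes(self, rng):
        pop = MBPopulation(
            np.arange(10) * 1e-3,
            np.repeat(np.arange(10), 2),
            np.tile([0, 1], 10),
            rng.uniform(size=(20, 3)),
            np.zeros((20, 3)),
            {0: 1.0, 1: 0.5},
        )
        sub = population_window(pop, 4, 7)
        assert sub.n_frames == 3
        assert set(sub.frame_indices) == {0, 1, 2}
        np.testing.assert_allclose(
            sub.positions, pop.positions[(pop.frame_indices >= 4) & (pop.frame_indices < 7)]
        )
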