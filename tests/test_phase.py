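"""Phase mapping, PS detection oracle equivalence, trajectory linking,
rotation counting and RD classification."""

import numpy as np
import pytest

from afconcord import phase, tissue
from afconcord.phase import PSPoint, PSTrajectory


def brute_force_ps(phase_frame, conductive, dx=0.5):
    """Independent plaquette line-integral implementation (explicit loop)."""
    ny, nx = phase_frame.shape
    hits = []

    def wrap(a):
        return (a + np.pi) % (2 * np.pi) - np.pi

    for iy in range(ny - 1):
        for ix in range(nx - 1):
            corners = [(iy, ix), (iy, ix + 1), (iy + 1, ix + 1), (iy + 1, ix)]
            if not all(conductive[c] and np.isfinite(phase_frame[c])
                       for c in corners):
                continue
            total = 0.0
            for k in range(4):
                a = phase_frame[corners[k]]
                b = phase_frame[corners[(k + 1) % 4]]
                total += wrap(b - a)
            if abs(total) > np.pi:
                hits.append(((ix + 0.5) * dx, (iy + 0.5) * dx,
                             int(np.sign(total))))
    return sorted(hits)


def vortex_field(ny, nx, y0, x0, charge=1):
    yy, xx = np.mgrid[0:ny, 0:nx]
    return charge * np.arctan2(yy - y0, xx - x0)


class TestComputePhase:
    def test_cosine_phase_slope(self):
        t = np.arange(0, 400.0, 1.0)
        T = 100.0
        V = np.cos(2 * np.pi * t / T)[:, None, None] * np.ones((1, 4, 4))
        ph, valid = phase.compute_phase(V)
        assert valid.all()
        slope = np.diff(np.unwrap(ph[:, 2, 2])).mean()
        assert slope == pytest.approx(2 * np.pi / T, rel=0.01)

    def test_constant_node_masked(self):
        V = np.random.default_rng(0).standard_normal((64, 3, 3))
        V[:, 1, 1] = -80.0
        ph, valid = phase.compute_phase(V)
        assert not valid[1, 1]
        assert np.isnan(ph[:, 1, 1]).all()
        assert valid[0, 0]

    def test_delay_embedding_agrees_on_cycle_rate(self):
        t = np.arange(0, 600.0, 1.0)
        V = np.cos(2 * np.pi * t / 120.0)[:, None, None] * np.ones((1, 3, 3))
        ph, _ = phase.compute_phase(V, method="delay")
        slope = np.diff(np.unwrap(ph[:, 1, 1])).mean()
        assert slope == pytest.approx(2 * np.pi / 120.0, rel=0.05)

    def test_paced_cable_phase_lag(self, surrogate_params):
        # two nodes along a paced cable differ in phase by
        # 2*pi * activation-time difference / period
        strip = tissue.TissueGrid.uniform(100, 5, d_long=0.1, anisotropy=1.0)
        s = np.zeros((5, 100), dtype=bool)
        s[:, :2] = True
        stims = [(1.0 + k * 150.0, 2.0, s, 40.0) for k in range(5)]
        res = tissue.simulate(strip, surrogate_params, stims, t_end=760.0,
                              dt_save=1.0)
        ph, _ = phase.compute_phase(res.V)
        at = tissue.activation_times(res.V[res.t > 300.0], res.t[res.t > 300.0])
        n1, n2 = (2, 30), (2, 60)
        dt_act = at[n2] - at[n1]
        mid = slice(300, 600)  # exactly two pacing cycles
        dphi = np.unwrap(ph[mid, n1[0], n1[1]]) - np.unwrap(ph[mid, n2[0], n2[1]])
        measured = np.mean((dphi + np.pi) % (2 * np.pi) - np.pi)
        expected = 2 * np.pi * dt_act / 150.0
        assert measured == pytest.approx(expected, rel=0.05, abs=0.05)


class TestDetectPS:
    def test_analytic_vortex(self):
        ph = vortex_field(20, 20, 9.3, 10.2)
        pts = phase.detect_phase_singularities(ph, np.ones((20, 20), bool),
                                               dx=0.5)
        assert len(pts) == 1
        assert pts[0].chirality == 1
        assert pts[0].x == pytest.approx(10.0 * 0.5, abs=0.5)
        assert pts[0].y == pytest.approx(9.0 * 0.5, abs=0.5)

    def test_uniform_phase_no_ps(self):
        pts = phase.detect_phase_singularities(np.full((12, 12), 0.7),
                                               np.ones((12, 12), bool))
        assert pts == []

    def test_vortex_antivortex_pair_charges_cancel(self):
        ph = vortex_field(24, 24, 11.5, 6.5) - vortex_field(24, 24, 11.5, 17.5)
        ph = (ph + np.pi) % (2 * np.pi) - np.pi
        pts = phase.detect_phase_singularities(ph, np.ones((24, 24), bool))
        assert len(pts) == 2
        assert sum(p.chirality for p in pts) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_seeded_fields(self, seed):
        rng = np.random.default_rng(seed)
        ny = nx = 24
        ph = np.zeros((ny, nx))
        for _ in range(rng.integers(1, 4)):
            ph = ph + vortex_field(ny, nx, rng.uniform(3, ny - 3) + 0.5,
                                   rng.uniform(3, nx - 3) + 0.5,
                                   charge=int(rng.choice([-1, 1])))
        ph = (ph + np.pi) % (2 * np.pi) - np.pi
        cond = np.ones((ny, nx), bool)
        got = sorted((p.x, p.y, p.chirality)
                     for p in phase.detect_phase_singularities(ph, cond))
        assert got == brute_force_ps(ph, cond)


class TestLinking:
    @staticmethod
    def frames_from(points_per_frame):
        return [[PSPoint(t=float(t), x=x, y=y, chirality=c)
                 for (x, y, c) in pts]
                for t, pts in enumerate(points_per_frame)]

    def test_single_stationary_ps(self):
        frames = self.frames_from([[(5.0, 5.0, 1)]] * 100)
        trajs = phase.link_trajectories(frames)
        assert len(trajs) == 1
        assert len(trajs[0].points) == 100

    def test_two_distant_ps_never_merge(self):
        frames = self.frames_from([[(2.0, 2.0, 1), (40.0, 40.0, 1)]] * 50)
        trajs = phase.link_trajectories(frames)
        assert len(trajs) == 2
        assert all(len(tr.points) == 50 for tr in trajs)

    def test_opposite_chirality_not_linked(self):
        frames = self.frames_from([[(5.0, 5.0, 1)], [(5.0, 5.0, -1)]])
        trajs = phase.link_trajectories(frames)
        assert len(trajs) == 2

    def test_gap_bridging_matches_exhaustive_assignment(self):
        # a PS drifting 0.2 mm/frame with one dropped frame must remain a
        # single track; brute-force check over all frame-to-frame pairings
        pts = [(1.0 + 0.2 * k, 3.0, 1) for k in range(20)]
        per_frame = [[p] for p in pts]
        per_frame[10] = []  # missing detection
        trajs = phase.link_trajectories(self.frames_from(per_frame),
                                        v_max=3.0, max_gap=5.0)
        assert len(trajs) == 1
        assert len(trajs[0].points) == 19
        # exhaustive oracle: with one detection per frame and a step well
        # within v_max*dt, the only consistent assignment is one chain
        for a, b in zip(trajs[0].points, trajs[0].points[1:]):
            assert abs(b.x - a.x) <= 3.0 * (b.t - a.t) + 1e-12

    def test_gap_longer_than_max_gap_splits(self):
        per_frame = [[(1.0, 1.0, 1)]] * 5 + [[]] * 30 + [[(1.0, 1.0, 1)]] * 5
        trajs = phase.link_trajectories(self.frames_from(per_frame),
                                        max_gap=10.0)
        assert len(trajs) == 2


class TestRotationsAndClassification:
    @staticmethod
    def rotating_phase(ny, nx, n_frames, period, y0, x0):
        base = vortex_field(ny, nx, y0, x0)
        out = np.empty((n_frames, ny, nx))
        for k in range(n_frames):
            out[k] = (base + 2 * np.pi * k / period + np.pi) \
                % (2 * np.pi) - np.pi
        return out

    def test_three_periods_count_three_rotations(self):
        period = 100
        ph = self.rotating_phase(20, 20, 3 * period + 1, period, 9.5, 9.5)
        t = np.arange(ph.shape[0], dtype=float)
        traj = PSTrajectory(points=[
            PSPoint(t=float(k), x=0.5 * 9.5, y=0.5 * 9.5, chirality=1)
            for k in range(ph.shape[0])])
        grid = tissue.TissueGrid.uniform(20, 20)
        rots = phase.count_rotations(traj, ph, t, grid)
        assert rots == pytest.approx(3.0, abs=0.2)

    def test_zero_duration_zero_rotations(self):
        traj = PSTrajectory(points=[PSPoint(t=5.0, x=1.0, y=1.0, chirality=1)])
        grid = tissue.TissueGrid.uniform(10, 10)
        assert phase.count_rotations(traj, np.zeros((3, 10, 10)),
                                     np.arange(3.0), grid) == 0.0

    @pytest.mark.parametrize("duration,period,expected_kept", [
        (250, 100, True),    # 250 ms, 2.5 rotations: RD
        (150, 60, False),    # 150 ms fails the duration criterion
        (300, 260, False),   # 300 ms but ~1.2 rotations fails rotations
    ])
    def test_duration_and_rotation_criteria(self, duration, period,
                                            expected_kept):
        n_frames = duration + 1
        ph = self.rotating_phase(20, 20, n_frames, period, 9.5, 9.5)
        t = np.arange(n_frames, dtype=float)
        traj = PSTrajectory(points=[
            PSPoint(t=float(k), x=0.5 * 9.5, y=0.5 * 9.5, chirality=1)
            for k in range(n_frames)])
        grid = tissue.TissueGrid.uniform(20, 20)
        rds = phase.classify_rds([traj], grid, ph, t)
        assert bool(rds) == expected_kept

    def test_unconfined_trajectory_rejected(self):
        n_frames = 300
        ph = self.rotating_phase(90, 90, n_frames, 100, 45.0, 45.0)
        t = np.arange(n_frames, dtype=float)
        # trajectory sweeping 40 mm across the sheet: not spatially confined
        traj = PSTrajectory(points=[
            PSPoint(t=float(k), x=2.0 + 40.0 * k / n_frames, y=22.5,
                    chirality=1) for k in range(n_frames)])
        grid = tissue.TissueGrid.uniform(90, 90)
        assert phase.classify_rds([traj], grid, ph, t) == []

    def test_loop_around_obstacle_rejected(self):
        grid = tissue.TissueGrid.uniform(40, 40)
        cond = grid.conductive.copy()
        cond[17:23, 17:23] = False  # 36-node obstacle
        grid = tissue.TissueGrid(nx=40, ny=40, dx=grid.dx,
                                 d_long=grid.d_long, d_trans=grid.d_trans,
                                 conductive=cond)
        n_frames = 301
        ph = self.rotating_phase(40, 40, n_frames, 120, 19.5, 19.5)
        t = np.arange(n_frames, dtype=float)
        # circular trajectory of radius 5 mm around the obstacle center
        traj = PSTrajectory(points=[
            PSPoint(t=float(k),
                    x=10.0 + 5.0 * np.cos(2 * np.pi * k / 100),
                    y=10.0 + 5.0 * np.sin(2 * np.pi * k / 100),
                    chirality=1) for k in range(n_frames)])
        assert phase.classify_rds([traj], grid, ph, t) == []


class TestHistogramAndCycleLength:
    def test_histogram_counts_conserved(self):
        grid = tissue.TissueGrid.uniform(30, 30)
        t1 = PSTrajectory(points=[PSPoint(t=k, x=5.0, y=5.0, chirality=1)
                                  for k in range(50)])
        t2 = PSTrajectory(points=[PSPoint(t=k, x=10.0 + 0.1 * k, y=8.0,
                                          chirality=-1) for k in range(80)])
        hist = phase.ps_histogram([t1, t2], grid)
        assert hist.sum() == 130
        assert hist[10, 10] == 50  # node (y=5mm, x=5mm)

    def test_empty_input_zero_map(self):
        grid = tissue.TissueGrid.uniform(10, 10)
        assert phase.ps_histogram([], grid).sum() == 0

    def test_stationary_ps_single_maximum(self):
        grid = tissue.TissueGrid.uniform(30, 30)
        t1 = PSTrajectory(points=[PSPoint(t=k, x=7.0, y=7.0, chirality=1)
                                  for k in range(40)])
        hist = phase.ps_histogram([t1], grid)
        assert phase.histogram_maxima(hist) == [(14, 14)]

    def test_paced_cycle_length(self, surrogate_params):
        strip = tissue.TissueGrid.uniform(60, 5, d_long=0.1, anisotropy=1.0)
        s = np.zeros((5, 60), dtype=bool)
        s[:, :2] = True
        stims = [(1.0 + 200.0 * k, 2.0, s, 40.0) for k in range(4)]
        res = tissue.simulate(strip, surrogate_params, stims, t_end=850.0,
                              dt_save=1.0)
        roi = np.zeros((5, 60), dtype=bool)
        roi[2, 20:40] = True
        cl = phase.mean_cycle_length(res, roi)
        assert cl == pytest.approx(200.0, abs=1.5)

    def test_quiescent_raises(self, surrogate_params):
        strip = tissue.TissueGrid.uniform(30, 5)
        res = tissue.simulate(strip, surrogate_params, t_end=300.0)
        with pytest.raises(ValueError, match="insufficient activations"):
            phase.mean_cycle_length(res, np.ones((5, 30), dtype=bool))

    def test_spiral_cl_consistent_with_rotation_period(self, spiral_episode,
                                                       spiral_grid,
                                                       spiral_analysis):
        trajs, ph, rds = spiral_analysis
        assert rds
        rd = max(rds, key=lambda r: r.duration)
        cx, cy = rd.trajectory.centroid()
        roi = np.zeros((spiral_grid.ny, spiral_grid.nx), dtype=bool)
        iy, ix = int(cy / 0.5), int(cx / 0.5)
        roi[max(0, iy - 10):iy + 10, max(0, ix - 10):ix + 10] = True
        cl = phase.mean_cycle_length(spiral_episode, roi)
        period = rd.duration / rd.rotations
        assert cl == pytest.approx(period, rel=0.05)


class TestChargeConservation:
    def test_total_chirality_steps_are_physical(self, spiral_episode,
                                                spiral_grid):
        ph, valid = phase.compute_phase(spiral_episode.V)
        totals = []
        for k in range(200, 1000, 2):
            pts = phase.detect_phase_singularities(
                ph[k], spiral_grid.conductive & valid, dx=spiral_grid.dx,
                t=float(spiral_episode.t[k]))
            totals.append(sum(p.chirality for p in pts))
        steps = np.abs(np.diff(totals))
        # pair creation/annihilation (2) or boundary entry/exit (1)
        assert steps.max() <= 2
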