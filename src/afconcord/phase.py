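"""Phase mapping, phase-singularity tracking and reentrant-driver
classification.

The instantaneous phase of each node's voltage is computed from the
analytic signal of the mean-subtracted trace (time-delay embedding is
available as an alternative).  Phase singularities (PS) — the organizing
centers of rotors — are detected as plaquettes around which the wrapped
phase winds by ±2π, linked frame-to-frame into trajectories, and
classified as reentrant drivers (RDs) when the trajectory is spatially
confined, persists at least two rotations and at least 200 ms, and does
not merely encircle a non-conductive obstacle (macro-reentry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import hilbert
from scipy.spatial import Delaunay, QhullError

from .tissue import SimulationResult, TissueGrid

#: RD acceptance criteria (duration ms, rotations, confinement mm).
RD_MIN_DURATION_MS = 200.0
RD_MIN_ROTATIONS = 2.0
RD_CONFINEMENT_MAX_MM = 15.0
#: obstacle components larger than this many nodes count as macro-reentry
#: anchors when encircled.
OBSTACLE_MIN_NODES = 4


@dataclass(frozen=True)
class PSPoint:
    t: float          # ms
    x: float          # mm
    y: float          # mm
    chirality: int    # +1 counter-clockwise, -1 clockwise


@dataclass
class PSTrajectory:
    """Time-ordered linked PS track."""

    points: list = field(default_factory=list)

    @property
    def t_start(self) -> float:
        return self.points[0].t

    @property
    def t_end(self) -> float:
        return self.points[-1].t

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def chirality(self) -> int:
        return self.points[0].chirality

    def centroid(self) -> tuple[float, float]:
        xs = np.array([p.x for p in self.points])
        ys = np.array([p.y for p in self.points])
        return float(xs.mean()), float(ys.mean())

    @property
    def confinement_radius(self) -> float:
        cx, cy = self.centroid()
        return float(max(np.hypot(p.x - cx, p.y - cy) for p in self.points))


@dataclass
class ReentrantDriver:
    """A PS trajectory meeting the RD duration/rotation/confinement criteria."""

    trajectory: PSTrajectory
    region_id: int = 0
    duration: float = 0.0
    rotations: float = 0.0
    confinement_radius: float = 0.0
    encircles_obstacle: bool = False


# ---------------------------------------------------------------------------
# Phase computation
# ---------------------------------------------------------------------------

def compute_phase(V: np.ndarray, method: str = "hilbert",
                  delay_samples: int | None = None):
    """Per-node instantaneous phase in (-pi, pi].

    Parameters
    ----------
    V : (time, ny, nx) voltage array (>= 2 activation cycles recommended).
    method : "hilbert" (analytic signal of the mean-subtracted trace) or
        "delay" (time-delay embedding; ``delay_samples`` defaults to a
        quarter of the dominant cycle estimated from the mean trace).

    Returns
    -------
    phase : (time, ny, nx) array, NaN on constant (masked) nodes.
    valid : (ny, nx) bool mask of nodes with a defined phase.
    """
    V = np.asarray(V, dtype=float)
    vm = V - V.mean(axis=0, keepdims=True)
    amp = np.ptp(V, axis=0)
    valid = amp > 1e-9
    if method == "hilbert":
        analytic = hilbert(vm, axis=0)
        phase = np.angle(analytic)
    elif method == "delay":
        if delay_samples is None:
            delay_samples = max(1, _dominant_period_samples(vm) // 4)
        past = np.empty_like(vm)
        past[delay_samples:] = vm[:-delay_samples]
        past[:delay_samples] = vm[0]
        # (past, now) ordering keeps phase increasing through the cycle,
        # matching the analytic-signal convention
        phase = np.arctan2(past, vm)
    else:
        raise ValueError(f"unknown phase method {method!r}")
    phase[:, ~valid] = np.nan
    return phase, valid


def _dominant_period_samples(vm: np.ndarray) -> int:
    trace = vm.mean(axis=(1, 2))
    spec = np.abs(np.fft.rfft(trace - trace.mean()))
    if spec.size <= 1:
        return 4
    k = int(np.argmax(spec[1:])) + 1
    return max(4, int(round(trace.size / k)))


# ---------------------------------------------------------------------------
# PS detection and linking
# ---------------------------------------------------------------------------

def _wrap(dphi: np.ndarray) -> np.ndarray:
    return (dphi + np.pi) % (2 * np.pi) - np.pi


def detect_phase_singularities(phase_frame: np.ndarray, conductive: np.ndarray,
                               dx: float = 0.5, t: float = 0.0) -> list[PSPoint]:
    """PS detections in one phase frame by plaquette topological charge.

    For every 2x2 plaquette of conductive, phase-valid nodes the wrapped
    phase differences are summed counter-clockwise; a total of ±2π marks a
    singularity at the plaquette center with chirality = the winding sign.
    """
    ph = np.asarray(phase_frame, dtype=float)
    ok = np.asarray(conductive, dtype=bool) & np.isfinite(ph)
    p00 = ph[:-1, :-1]
    p01 = ph[:-1, 1:]
    p11 = ph[1:, 1:]
    p10 = ph[1:, :-1]
    # counter-clockwise loop in (x, y): (0,0)->(1,0)->(1,1)->(0,1)->(0,0)
    circ = (_wrap(p01 - p00) + _wrap(p11 - p01)
            + _wrap(p10 - p11) + _wrap(p00 - p10))
    all_ok = ok[:-1, :-1] & ok[:-1, 1:] & ok[1:, 1:] & ok[1:, :-1]
    hits = all_ok & (np.abs(circ) > np.pi)  # |sum| == 2*pi up to rounding
    iys, ixs = np.nonzero(hits)
    out = []
    for iy, ix in zip(iys, ixs):
        out.append(PSPoint(t=float(t), x=(ix + 0.5) * dx, y=(iy + 0.5) * dx,
                           chirality=int(np.sign(circ[iy, ix]))))
    return out


def link_trajectories(ps_frames: list[list[PSPoint]], v_max: float = 3.0,
                      max_gap: float = 20.0) -> list[PSTrajectory]:
    """Greedy nearest-neighbor linking of per-frame PS detections.

    Matches require equal chirality and a step distance within
    ``v_max * dt_elapsed``; a track may bridge up to ``max_gap`` ms of
    missing detections.  Ties are broken by smaller distance, then by the
    lower (y, x) of the detection — fully deterministic.
    """
    open_tracks: list[PSTrajectory] = []
    done: list[PSTrajectory] = []
    for frame in ps_frames:
        if not frame:
            continue
        t_now = frame[0].t
        # expire stale tracks
        still = []
        for tr in open_tracks:
            if t_now - tr.t_end > max_gap:
                done.append(tr)
            else:
                still.append(tr)
        open_tracks = still

        detections = sorted(frame, key=lambda p: (p.y, p.x))
        pairs = []
        for di, det in enumerate(detections):
            for ti, tr in enumerate(open_tracks):
                if tr.chirality != det.chirality:
                    continue
                head = tr.points[-1]
                dt_el = t_now - head.t
                dist = float(np.hypot(det.x - head.x, det.y - head.y))
                if dist <= v_max * dt_el + 1e-12:
                    pairs.append((dist, det.y, det.x, di, ti))
        pairs.sort()
        used_d, used_t = set(), set()
        for dist, _, _, di, ti in pairs:
            if di in used_d or ti in used_t:
                continue
            open_tracks[ti].points.append(detections[di])
            used_d.add(di)
            used_t.add(ti)
        for di, det in enumerate(detections):
            if di not in used_d:
                open_tracks.append(PSTrajectory(points=[det]))
    done.extend(open_tracks)
    done.sort(key=lambda tr: (tr.t_start, tr.points[0].y, tr.points[0].x))
    return done


def detect_and_link(result: SimulationResult, grid: TissueGrid,
                    v_max: float = 3.0, max_gap: float = 20.0,
                    method: str = "hilbert"):
    """Full phase pipeline: phase → per-frame PS → linked trajectories."""
    phase, valid = compute_phase(result.V, method=method)
    frames = [detect_phase_singularities(phase[k], grid.conductive & valid,
                                         dx=grid.dx, t=float(result.t[k]))
              for k in range(phase.shape[0])]
    trajs = link_trajectories(frames, v_max=v_max, max_gap=max_gap)
    return trajs, phase


# ---------------------------------------------------------------------------
# Rotation counting and RD classification
# ---------------------------------------------------------------------------

def count_rotations(traj: PSTrajectory, phase: np.ndarray, t: np.ndarray,
                    grid: TissueGrid) -> float:
    """Rotations = |unwrapped phase accrual| / 2π at the node nearest the
    trajectory centroid over the trajectory's lifetime.

    Falls back to the nearest phase-valid conductive node if the centroid
    node is masked.
    """
    if traj.duration <= 0:
        return 0.0
    cx, cy = traj.centroid()
    iy, ix = _nearest_valid_node(phase, grid, cx, cy)
    sel = (t >= traj.t_start) & (t <= traj.t_end)
    seg = phase[sel, iy, ix]
    if seg.size < 2:
        return 0.0
    unwrapped = np.unwrap(seg)
    return float(abs(unwrapped[-1] - unwrapped[0]) / (2 * np.pi))


def _nearest_valid_node(phase: np.ndarray, grid: TissueGrid,
                        x_mm: float, y_mm: float) -> tuple[int, int]:
    valid = grid.conductive & np.isfinite(phase[0])
    if not valid.any():
        raise ValueError("no phase-valid nodes")
    iys, ixs = np.nonzero(valid)
    d2 = (ixs * grid.dx - x_mm) ** 2 + (iys * grid.dx - y_mm) ** 2
    k = int(np.argmin(d2))
    return int(iys[k]), int(ixs[k])


def _encircles_obstacle(traj: PSTrajectory, grid: TissueGrid) -> bool:
    """True when the trajectory's convex hull contains a node of a
    non-conductive component larger than OBSTACLE_MIN_NODES."""
    obstacles, n_comp = ndimage.label(~grid.conductive)
    if n_comp == 0:
        return False
    pts = np.array([[p.x, p.y] for p in traj.points])
    if len(pts) < 3 or np.ptp(pts, axis=0).min() < 1e-9:
        return False
    try:
        hull = Delaunay(pts)
    except QhullError:
        return False
    sizes = ndimage.sum_labels(np.ones_like(obstacles), obstacles,
                               index=np.arange(1, n_comp + 1))
    big = {i + 1 for i, s in enumerate(sizes) if s > OBSTACLE_MIN_NODES}
    if not big:
        return False
    iys, ixs = np.nonzero(np.isin(obstacles, list(big)))
    nodes = np.column_stack([ixs * grid.dx, iys * grid.dx])
    return bool(np.any(hull.find_simplex(nodes) >= 0))


def classify_rds(trajectories: list[PSTrajectory], grid: TissueGrid,
                 phase: np.ndarray, t: np.ndarray,
                 min_duration: float = RD_MIN_DURATION_MS,
                 min_rotations: float = RD_MIN_ROTATIONS,
                 confinement_max: float = RD_CONFINEMENT_MAX_MM) -> list[ReentrantDriver]:
    """Keep trajectories that qualify as reentrant drivers.

    Criteria: duration >= 200 ms, rotations >= 2, confinement radius
    <= 15 mm, and not macro-reentry around a non-conductive obstacle.
    """
    from .stats import assign_rd_region

    out = []
    for traj in trajectories:
        dur = traj.duration
        if dur < min_duration:
            continue
        conf = traj.confinement_radius
        if conf > confinement_max:
            continue
        rots = count_rotations(traj, phase, t, grid)
        if rots < min_rotations:
            continue
        if _encircles_obstacle(traj, grid):
            continue
        rd = ReentrantDriver(trajectory=traj, duration=dur, rotations=rots,
                             confinement_radius=conf, encircles_obstacle=False)
        rd.region_id = assign_rd_region(rd, grid)
        out.append(rd)
    return out


def ps_histogram(trajectories: list[PSTrajectory],
                 grid: TissueGrid) -> np.ndarray:
    """Per-node PS occurrence counts over all trajectory points."""
    hist = np.zeros((grid.ny, grid.nx), dtype=np.int64)
    for tr in trajectories:
        for p in tr.points:
            ix = min(max(int(round(p.x / grid.dx)), 0), grid.nx - 1)
            iy = min(max(int(round(p.y / grid.dx)), 0), grid.ny - 1)
            hist[iy, ix] += 1
    return hist


def histogram_maxima(hist: np.ndarray) -> list[tuple[int, int]]:
    """(iy, ix) of strict 8-neighborhood local maxima with nonzero counts."""
    mx = ndimage.maximum_filter(hist, size=3, mode="constant")
    iys, ixs = np.nonzero((hist == mx) & (hist > 0))
    return list(zip(iys.tolist(), ixs.tolist()))


def mean_cycle_length(result: SimulationResult, roi: np.ndarray,
                      threshold: float = -40.0,
                      min_activations: int = 3) -> float:
    """Median over ROI nodes of the mean inter-activation interval (ms).

    ROI is a boolean (ny, nx) mask; nodes need >= ``min_activations``
    upward threshold crossings to contribute.
    """
    V, t = result.V, result.t
    roi = np.asarray(roi, dtype=bool)
    below = V < threshold
    crossings = below[:-1] & ~below[1:]
    cls = []
    iys, ixs = np.nonzero(roi)
    for iy, ix in zip(iys, ixs):
        ks = np.nonzero(crossings[:, iy, ix])[0]
        if ks.size < min_activations:
            continue
        times = t[ks]
        cls.append(np.diff(times).mean())
    if not cls:
        raise ValueError("insufficient activations in ROI for cycle length")
    return float(np.median(cls))
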