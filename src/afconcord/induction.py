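"""Multi-site rapid-pacing AF induction and sustained-AF detection.

Each virtual patient is paced from evenly distributed sites (farthest-point
sampling; 30 by default) with a decremental burst-pacing train, then the
tissue free-runs with no stimulus (2.5 s by default).  Episodes with
sustained activity are passed through the phase pipeline and their
reentrant drivers pooled into the patient's set of RD-harboring regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import phase as phase_mod
from .ionic import IonicParams
from .substrate import VirtualPatient
from .tissue import SimulationResult, activation_counts, simulate


@dataclass(frozen=True)
class PacingProtocol:
    """Decremental burst pacing followed by a free run.

    The cycle-length ramp ends near the tissue's refractory period so the
    final beats produce conduction block and wavebreak on a vulnerable
    substrate.  All values are config-exposed.
    """

    n_sites: int = 30
    beats_per_train: int = 6
    cycle_lengths: tuple = (200.0, 150.0, 120.0)   # ms, strictly decreasing
    stim_amplitude: float = 30.0
    stim_duration: float = 2.0
    stim_radius_mm: float = 1.0
    free_run_ms: float = 2500.0

    def __post_init__(self):
        cls_ = tuple(self.cycle_lengths)
        if any(b >= a for a, b in zip(cls_, cls_[1:])):
            raise ValueError("cycle_lengths must be strictly decreasing")
        if self.free_run_ms < 0:
            raise ValueError("free_run_ms must be >= 0")

    @property
    def pacing_duration(self) -> float:
        return float(self.beats_per_train * sum(self.cycle_lengths))

    def stim_times(self) -> list[float]:
        times, t = [], 1.0
        for cl in self.cycle_lengths:
            for _ in range(self.beats_per_train):
                times.append(t)
                t += cl
        return times


def select_pacing_sites(grid, n: int) -> list[tuple[int, int]]:
    """Evenly distributed conductive (iy, ix) sites by farthest-point
    sampling, seeded at the conductive node nearest the sheet centroid.

    Greedy: each next site maximizes its minimum distance to the chosen
    set; ties resolve to the lowest (y, x).  Deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    iys, ixs = np.nonzero(grid.conductive)
    if n > iys.size:
        raise ValueError("more sites requested than conductive nodes")
    pts = np.column_stack([iys, ixs]).astype(float)
    cy, cx = (grid.ny - 1) / 2.0, (grid.nx - 1) / 2.0
    d2c = (pts[:, 0] - cy) ** 2 + (pts[:, 1] - cx) ** 2
    order = np.lexsort((pts[:, 1], pts[:, 0], d2c))
    chosen = [order[0]]
    mind2 = ((pts - pts[chosen[0]]) ** 2).sum(axis=1)
    for _ in range(1, n):
        best = np.lexsort((pts[:, 1], pts[:, 0], -mind2))[0]
        chosen.append(best)
        d2 = ((pts - pts[best]) ** 2).sum(axis=1)
        np.minimum(mind2, d2, out=mind2)
    return [(int(pts[i, 0]), int(pts[i, 1])) for i in chosen]


def _site_mask(grid, site: tuple[int, int], radius_mm: float) -> np.ndarray:
    iy, ix = site
    yy, xx = np.mgrid[0:grid.ny, 0:grid.nx]
    d = np.hypot((yy - iy) * grid.dx, (xx - ix) * grid.dx)
    return (d <= radius_mm) & grid.conductive


def pace_and_release(grid, ionic_params: IonicParams, site: tuple[int, int],
                     protocol: PacingProtocol, seed: int | None = None,
                     dt_save: float = 1.0) -> SimulationResult:
    """Apply the decremental train at ``site`` then free-run the sheet."""
    if not grid.conductive[site]:
        raise ValueError(f"pacing site {site} is not conductive")
    mask = _site_mask(grid, site, protocol.stim_radius_mm)
    stims = [(t, protocol.stim_duration, mask, protocol.stim_amplitude)
             for t in protocol.stim_times()]
    t_last = stims[-1][0]
    t_end = t_last + protocol.stim_duration + protocol.free_run_ms
    res = simulate(grid, ionic_params, stimuli=stims, t_end=t_end,
                   dt_save=dt_save, seed=seed)
    res.metadata["t_last_stimulus"] = t_last
    res.metadata["site"] = list(site)
    return res


def detect_sustained_af(result: SimulationResult,
                        tail_ms: float = 250.0,
                        min_median_activations: int = 2) -> bool:
    """Sustained activity after pacing ends.

    True iff at least one node activates (upward -40 mV crossing) within
    the final ``tail_ms`` of the free run AND the median per-node
    activation count over the free run is >= ``min_median_activations``.
    """
    t_last = result.metadata.get("t_last_stimulus", 0.0)
    t = result.t
    free = t > t_last + 5.0
    if not free.any() or t[-1] - t_last < 500.0:
        raise ValueError("need at least 500 ms of post-stimulus data")
    V_free = result.V[free]
    counts = activation_counts(V_free)
    tail = t >= t[-1] - tail_ms
    V_tail = result.V[tail]
    tail_active = bool((activation_counts(V_tail) > 0).any())
    return tail_active and float(np.median(counts)) >= min_median_activations


@dataclass
class SiteLog:
    site: tuple[int, int]
    sustained: bool
    n_rds: int = 0
    regions: frozenset = frozenset()
    error: str | None = None


@dataclass
class InductionOutcome:
    """Pooled result of the multi-site protocol on one patient."""

    rd_regions: frozenset
    rds: list = field(default_factory=list)
    site_logs: list = field(default_factory=list)


def induce_all(patient: VirtualPatient, ionic_params: IonicParams,
               protocol: PacingProtocol | None = None,
               phase_method: str = "hilbert") -> InductionOutcome:
    """Run pace-and-release from every site and pool reentrant drivers.

    Only the free-run window of sustained episodes is phase-analyzed.
    Per-site failures are logged, never fatal.
    """
    protocol = protocol or PacingProtocol()
    grid = patient.grid
    sites = select_pacing_sites(grid, protocol.n_sites)
    all_rds, logs = [], []
    regions: set[int] = set()
    for site in sites:
        try:
            res = pace_and_release(grid, ionic_params, site, protocol,
                                   seed=patient.seed)
            sustained = detect_sustained_af(res)
            if not sustained:
                logs.append(SiteLog(site=site, sustained=False))
                continue
            t_last = res.metadata["t_last_stimulus"]
            sel = res.t > t_last + 5.0
            free = SimulationResult(V=res.V[sel], t=res.t[sel],
                                    metadata=dict(res.metadata))
            trajs, ph = phase_mod.detect_and_link(free, grid)
            rds = phase_mod.classify_rds(trajs, grid, ph, free.t)
            site_regions = frozenset(rd.region_id for rd in rds)
            all_rds.extend(rds)
            regions |= site_regions
            logs.append(SiteLog(site=site, sustained=True, n_rds=len(rds),
                                regions=site_regions))
        except Exception as exc:  # pragma: no cover - defensive per spec
            logs.append(SiteLog(site=site, sustained=False, error=str(exc)))
    return InductionOutcome(rd_regions=frozenset(regions), rds=all_rds,
                            site_logs=logs)
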