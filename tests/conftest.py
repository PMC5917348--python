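"""Shared fixtures: spiral and planar episodes, a pinned fibrotic patient.

Heavy simulations are session-scoped and reused across test modules; all
fixtures are deterministic (fixed seeds, fixed protocols).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from afconcord import induction, ionic, phase, pipeline, substrate, tissue

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


# --- cross-field spiral on a homogeneous sheet -----------------------------

SPIRAL_N = 120
SPIRAL_S2_MS = 135.0
SPIRAL_T_END = 1500.0


def cross_field_stimuli(ny: int, nx: int, t_s2: float = SPIRAL_S2_MS):
    """S1 line at the left edge plus a delayed S2 quadrant."""
    s1 = np.zeros((ny, nx), dtype=bool)
    s1[:, :2] = True
    s2 = np.zeros((ny, nx), dtype=bool)
    s2[: ny // 2, : nx // 2] = True
    return [(1.0, 2.0, s1, 40.0), (t_s2, 2.0, s2, 40.0)]


@pytest.fixture(scope="session")
def surrogate_params():
    return ionic.IonicParams(backend="surrogate")


@pytest.fixture(scope="session")
def spiral_grid():
    return tissue.TissueGrid.uniform(SPIRAL_N, SPIRAL_N, dx=0.5,
                                     d_long=0.1, anisotropy=1.0)


@pytest.fixture(scope="session")
def spiral_episode(spiral_grid, surrogate_params):
    """Sustained single-rotor episode initiated by cross-field stimulation."""
    stims = cross_field_stimuli(SPIRAL_N, SPIRAL_N)
    return tissue.simulate(spiral_grid, surrogate_params, stimuli=stims,
                           t_end=SPIRAL_T_END, dt_save=1.0, seed=0)


@pytest.fixture(scope="session")
def spiral_analysis(spiral_episode, spiral_grid):
    """(trajectories, phase array, reentrant drivers) for the spiral."""
    trajs, ph = phase.detect_and_link(spiral_episode, spiral_grid)
    rds = phase.classify_rds(trajs, spiral_grid, ph, spiral_episode.t)
    return trajs, ph, rds


@pytest.fixture(scope="session")
def planar_episode(surrogate_params):
    """Single planar wave on a homogeneous sheet: no reentry."""
    grid = tissue.TissueGrid.uniform(80, 80, dx=0.5, d_long=0.1,
                                     anisotropy=1.0)
    s1 = np.zeros((80, 80), dtype=bool)
    s1[:, :2] = True
    res = tissue.simulate(grid, surrogate_params,
                          stimuli=[(1.0, 2.0, s1, 40.0)],
                          t_end=800.0, dt_save=1.0, seed=0)
    res.metadata["t_last_stimulus"] = 1.0
    return grid, res


# --- pinned fibrotic virtual patient (induction regression) ----------------

PINNED_PATIENT = dict(density=0.30, nx=100, ny=100, seed=7,
                      correlation_length=5.0)
PINNED_PROTOCOL = induction.PacingProtocol(
    n_sites=2, beats_per_train=5, cycle_lengths=(160.0, 130.0, 110.0),
    free_run_ms=1500.0)
#: RD-harboring regions found on first analysis of the pinned fixture.
PINNED_RD_REGIONS = frozenset({2, 5})


@pytest.fixture(scope="session")
def pinned_patient():
    return substrate.make_virtual_patient("pinned", **PINNED_PATIENT)


@pytest.fixture(scope="session")
def pinned_induction(pinned_patient, surrogate_params):
    return induction.induce_all(pinned_patient, surrogate_params,
                                PINNED_PROTOCOL)


# --- small end-to-end pipeline, run twice (determinism checks) -------------

SMALL_PIPELINE_CONFIG = {
    "seed": 11,
    "grid": {"nx": 60, "ny": 60},
    "substrate": {"density": 0.30},
    "protocol": {"n_sites": 2, "beats_per_train": 4,
                 "cycle_lengths": [150.0, 120.0], "free_run_ms": 700.0},
    "ablation": {"rounds": 1},
}


@pytest.fixture(scope="session")
def small_pipeline_runs(tmp_path_factory):
    """The scaled-down workflow executed twice with an identical config."""
    cfg = pipeline.load_config(overrides=SMALL_PIPELINE_CONFIG)
    outs = []
    for name in ("runA", "runB"):
        out = tmp_path_factory.mktemp(name)
        pipeline.run_pipeline(cfg, out)
        outs.append(out)
    return outs[0], outs[1], cfg
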