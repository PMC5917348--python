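"""Virtual ablation of reentrant-driver trajectories.

Lesions render all tissue within a fixed radius (3.5 mm by default) of a
targeted PS trajectory non-conductive, mimicking catheter ablation along
the rotor path.  After ablation the multi-site pacing protocol is
repeated; emergent ("de novo") RD-harboring regions are recorded, and the
acute response of a matched episode is classified as positive on
termination or cycle-length prolongation of more than 10 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .induction import PacingProtocol, detect_sustained_af, induce_all
from .ionic import IonicParams
from .phase import PSTrajectory, mean_cycle_length
from .substrate import VirtualPatient
from .tissue import SimulationResult, TissueGrid

DEFAULT_LESION_RADIUS_MM = 3.5
#: CL prolongation (ms) beyond which a non-terminating response is positive.
POSITIVE_DELTA_CL_MS = 10.0


@dataclass
class AblationPlan:
    """Lesion mask derived from target trajectories."""

    lesion_mask: np.ndarray
    lesion_radius: float = DEFAULT_LESION_RADIUS_MM
    n_targets: int = 0


@dataclass
class AblationOutcome:
    """Acute response of one matched pre/post episode pair."""

    terminated: bool
    cl_pre: float | None = None
    cl_post: float | None = None
    delta_cl: float | None = None
    positive_response: bool = False


def build_lesion_mask(trajectories, grid: TissueGrid,
                      radius: float = DEFAULT_LESION_RADIUS_MM) -> np.ndarray:
    """Union of disks of ``radius`` (mm) around every trajectory point.

    A node is included iff the Euclidean distance from its center to any
    PS point is <= radius; the mask is restricted to currently conductive
    nodes.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    mask = np.zeros((grid.ny, grid.nx), dtype=bool)
    r_nodes = radius / grid.dx
    for traj in trajectories:
        pts = traj.points if isinstance(traj, PSTrajectory) else traj.trajectory.points
        for p in pts:
            fx, fy = p.x / grid.dx, p.y / grid.dx
            x0 = max(0, int(np.ceil(fx - r_nodes)))
            x1 = min(grid.nx - 1, int(np.floor(fx + r_nodes)))
            y0 = max(0, int(np.ceil(fy - r_nodes)))
            y1 = min(grid.ny - 1, int(np.floor(fy + r_nodes)))
            if x1 < x0 or y1 < y0:
                continue
            xs = np.arange(x0, x1 + 1)
            ys = np.arange(y0, y1 + 1)
            d2 = (ys[:, None] - fy) ** 2 + (xs[None, :] - fx) ** 2
            mask[y0:y1 + 1, x0:x1 + 1] |= d2 <= r_nodes ** 2 + 1e-12
    return mask & grid.conductive


def make_plan(trajectories, grid: TissueGrid,
              radius: float = DEFAULT_LESION_RADIUS_MM) -> AblationPlan:
    trajectories = list(trajectories)
    return AblationPlan(lesion_mask=build_lesion_mask(trajectories, grid, radius),
                        lesion_radius=radius, n_targets=len(trajectories))


def ablated_fraction(grid: TissueGrid, mask: np.ndarray) -> float:
    """Percent of (pre-ablation) conductive tissue covered by the mask."""
    n_cond = grid.n_conductive
    if n_cond == 0:
        raise ValueError("grid has no conductive tissue")
    return 100.0 * float((mask & grid.conductive).sum()) / n_cond


def acute_outcome(terminated: bool, cl_pre: float | None = None,
                  cl_post: float | None = None) -> AblationOutcome:
    """Outcome record from termination status and matched cycle lengths.

    Positive response = termination OR cycle-length prolongation strictly
    greater than 10 ms.
    """
    if terminated:
        return AblationOutcome(terminated=True, positive_response=True)
    if cl_pre is None or cl_post is None:
        raise ValueError("non-terminating outcomes need pre/post cycle lengths")
    delta = cl_post - cl_pre
    return AblationOutcome(terminated=False, cl_pre=cl_pre, cl_post=cl_post,
                           delta_cl=delta,
                           positive_response=delta > POSITIVE_DELTA_CL_MS)


def classify_acute_response(pre: SimulationResult, post: SimulationResult,
                            roi: np.ndarray,
                            window_ms: float = 1000.0) -> AblationOutcome:
    """Acute outcome from matched pre/post episodes.

    Termination = no sustained activity post-ablation.  For
    non-terminating episodes the cycle length is measured over the final
    ``window_ms`` of each episode on the same ROI; positive response is
    termination or ΔCL > 10 ms (strict).
    """
    terminated = not detect_sustained_af(post)
    if terminated:
        return acute_outcome(True)
    return acute_outcome(False, _tail_cl(pre, roi, window_ms),
                         _tail_cl(post, roi, window_ms))


def _tail_cl(result: SimulationResult, roi: np.ndarray, window_ms: float) -> float:
    sel = result.t >= result.t[-1] - window_ms
    tail = SimulationResult(V=result.V[sel], t=result.t[sel],
                            metadata=dict(result.metadata))
    return mean_cycle_length(tail, roi)


def reinducibility_study(patient: VirtualPatient, plan: AblationPlan,
                         ionic_params: IonicParams,
                         protocol: PacingProtocol | None = None,
                         rd_regions_pre=frozenset()):
    """Repeat the full pacing protocol on the ablated substrate.

    Returns a dict with ``inducible``, the post-ablation RD-region set,
    the de-novo regions (post \\ pre), and the induction outcome object.
    Macro-reentry around the new lesions is excluded by the RD classifier.
    """
    ablated_grid = patient.grid.with_lesion(plan.lesion_mask)
    ablated_patient = VirtualPatient(patient_id=patient.patient_id,
                                     grid=ablated_grid,
                                     fibrosis_burden=patient.fibrosis_burden,
                                     seed=patient.seed)
    outcome = induce_all(ablated_patient, ionic_params, protocol)
    rd_post = outcome.rd_regions
    return {
        "inducible": any(log.sustained for log in outcome.site_logs),
        "rd_regions_post": rd_post,
        "de_novo_regions": frozenset(rd_post - frozenset(rd_regions_pre)),
        "outcome": outcome,
    }
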