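"""Monodomain propagation on a 2D atrial sheet.

The transmembrane potential diffuses with a per-node anisotropic tensor
built from the local fiber angle and longitudinal/transverse diffusion
coefficients; membrane kinetics come from :mod:`afconcord.ionic`.
Discretization is a conservative finite-volume stencil on a regular grid
(node spacing ``dx``, default 0.5 mm — the same resolution class as the
finite-element meshes used for patient atria).  Faces touching a
non-conductive node (sheet edge, obstacle, ablation lesion) carry zero
flux, which makes lesions true no-flux obstacles and conserves total
voltage exactly when the reaction term is switched off.

Time integration is operator-split explicit: one sparse-matrix diffusion
update followed by one reaction step per dt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import sparse

from .ionic import (IonicParams, _sim_loop, apply_fibrotic_remodeling,
                    rest_vector)


@dataclass
class TissueGrid:
    """Regular 2D sheet with conduction tensors and labels.

    Arrays are (ny, nx), row = y, col = x; physical mm = index * dx.
    """

    nx: int
    ny: int
    dx: float = 0.5
    fiber_angle: np.ndarray = None  # radians
    d_long: np.ndarray = None       # mm^2/ms
    d_trans: np.ndarray = None
    fibrosis: np.ndarray = None     # bool
    conductive: np.ndarray = None   # bool; False = obstacle/lesion
    region_id: np.ndarray = None    # int 1..7, 0 = unassigned

    def __post_init__(self):
        shape = (self.ny, self.nx)
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.fiber_angle is None:
            self.fiber_angle = np.zeros(shape)
        if self.d_long is None:
            self.d_long = np.full(shape, 0.1)
        if self.d_trans is None:
            self.d_trans = 0.25 * self.d_long
        if self.fibrosis is None:
            self.fibrosis = np.zeros(shape, dtype=bool)
        if self.conductive is None:
            self.conductive = np.ones(shape, dtype=bool)
        if self.region_id is None:
            self.region_id = np.zeros(shape, dtype=np.int32)
        for name in ("fiber_angle", "d_long", "d_trans", "fibrosis",
                     "conductive", "region_id"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        cond = self.conductive
        if np.any(self.d_trans[cond] <= 0) or np.any(
                self.d_long[cond] < self.d_trans[cond]):
            raise ValueError("need D_long >= D_trans > 0 on conductive nodes")
        if np.any(self.fibrosis & ~cond):
            raise ValueError("fibrosis labels only allowed on conductive nodes")

    @classmethod
    def uniform(cls, nx: int, ny: int, dx: float = 0.5, d_long: float = 0.1,
                anisotropy: float = 0.25, fiber_angle: float = 0.0) -> "TissueGrid":
        """Homogeneous conductive sheet with constant fiber angle."""
        shape = (ny, nx)
        return cls(nx=nx, ny=ny, dx=dx,
                   fiber_angle=np.full(shape, float(fiber_angle)),
                   d_long=np.full(shape, float(d_long)),
                   d_trans=np.full(shape, float(d_long) * anisotropy))

    def with_fibrosis(self, fibrosis: np.ndarray,
                      d_factor: float = 0.5) -> "TissueGrid":
        """Label fibrotic nodes and slow their conduction by ``d_factor``."""
        fibrosis = np.asarray(fibrosis, dtype=bool) & self.conductive
        scale = np.where(fibrosis, d_factor, 1.0)
        return replace(self, fibrosis=fibrosis,
                       d_long=self.d_long * scale,
                       d_trans=self.d_trans * scale)

    def with_lesion(self, lesion_mask: np.ndarray) -> "TissueGrid":
        """Render masked nodes non-conductive (ablation/obstacle)."""
        lesion = np.asarray(lesion_mask, dtype=bool)
        cond = self.conductive & ~lesion
        return replace(self, conductive=cond, fibrosis=self.fibrosis & cond)

    @property
    def n_conductive(self) -> int:
        return int(self.conductive.sum())

    def node_xy_mm(self, iy: int, ix: int) -> tuple[float, float]:
        return ix * self.dx, iy * self.dx


def _tensor_fields(grid: TissueGrid):
    th = grid.fiber_angle
    c, s = np.cos(th), np.sin(th)
    dl, dt = grid.d_long, grid.d_trans
    dxx = dl * c * c + dt * s * s
    dyy = dl * s * s + dt * c * c
    dxy = (dl - dt) * s * c
    return dxx, dyy, dxy


def diffusion_operator(grid: TissueGrid) -> sparse.csr_matrix:
    """Sparse ∇·(D∇·) over flattened (ny*nx) fields.

    Conservative face-flux form: every interior face flux enters its two
    nodes with opposite signs, so column sums over conductive nodes vanish
    and a uniform field maps to zero.  Faces adjacent to a non-conductive
    node carry zero flux (mirror-method no-flux boundary).
    """
    ny, nx, h = grid.ny, grid.nx, grid.dx
    dxx, dyy, dxy = _tensor_fields(grid)
    cond = grid.conductive
    n = ny * nx
    inv_h2 = 1.0 / (h * h)
    node = np.arange(n).reshape(ny, nx)

    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(v.ravel())

    # --- x-faces: between (iy, ix) and (iy, ix+1) ---
    ok = cond[:, :-1] & cond[:, 1:]
    w = 0.5 * (dxx[:, :-1] + dxx[:, 1:]) * inv_h2 * ok
    a, b = node[:, :-1], node[:, 1:]
    add(a, b, w); add(a, a, -w)
    add(b, a, w); add(b, b, -w)

    # --- y-faces: between (iy, ix) and (iy+1, ix) ---
    ok = cond[:-1, :] & cond[1:, :]
    w = 0.5 * (dyy[:-1, :] + dyy[1:, :]) * inv_h2 * ok
    a, b = node[:-1, :], node[1:, :]
    add(a, b, w); add(a, a, -w)
    add(b, a, w); add(b, b, -w)

    if np.any(dxy != 0.0):
        # mixed-derivative flux terms, conservative face form; cross
        # differences are dropped where a stencil node is non-conductive
        # or off-sheet (one-sided handling at boundaries).
        okc = np.zeros((ny, nx), dtype=bool)
        okc[1:-1, :] = cond[2:, :] & cond[:-2, :]
        # x-face flux += dxy_face * du/dy (averaged over the two face nodes)
        okf = cond[:, :-1] & cond[:, 1:]
        dxyf = 0.5 * (dxy[:, :-1] + dxy[:, 1:]) * inv_h2 / 4.0 * okf
        a, b = node[:, :-1], node[:, 1:]
        for side in (0, 1):  # contributions of each face node's du/dy
            s = node[:, :-1] if side == 0 else node[:, 1:]
            valid = (okc[:, :-1] if side == 0 else okc[:, 1:])
            wc = dxyf * valid
            up = np.where(valid, s + nx, s)  # clamped where weight is zero
            dn = np.where(valid, s - nx, s)
            add(a, up, wc); add(a, dn, -wc)
            add(b, up, -wc); add(b, dn, wc)
        okc2 = np.zeros((ny, nx), dtype=bool)
        okc2[:, 1:-1] = cond[:, 2:] & cond[:, :-2]
        okf = cond[:-1, :] & cond[1:, :]
        dxyf = 0.5 * (dxy[:-1, :] + dxy[1:, :]) * inv_h2 / 4.0 * okf
        a, b = node[:-1, :], node[1:, :]
        for side in (0, 1):
            s = node[:-1, :] if side == 0 else node[1:, :]
            valid = (okc2[:-1, :] if side == 0 else okc2[1:, :])
            wc = dxyf * valid
            rt = np.where(valid, s + 1, s)
            lf = np.where(valid, s - 1, s)
            add(a, rt, wc); add(a, lf, -wc)
            add(b, rt, -wc); add(b, lf, wc)

    L = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n))
    return L.tocsr()


@dataclass
class SimulationResult:
    """Saved voltage movie: V is (time, ny, nx) float32 at dt_save spacing."""

    V: np.ndarray
    t: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.V)):
            raise ValueError("non-finite voltages in result")


class InstabilityError(RuntimeError):
    pass


def stability_dt_max(grid: TissueGrid) -> float:
    dmax = float(max(grid.d_long.max(), grid.d_trans.max()))
    return grid.dx ** 2 / (4.0 * dmax)


def simulate(grid: TissueGrid, ionic_params: IonicParams, stimuli=(),
             t_end: float = 1000.0, dt: float | None = None,
             dt_save: float = 1.0, seed: int | None = None,
             initial_states: np.ndarray | None = None,
             return_states: bool = False,
             fibrotic_params: IonicParams | None = None):
    """Run the monodomain model; deterministic given all arguments.

    Parameters
    ----------
    stimuli : iterable of (t_on, duration, nodes, amplitude)
        ``nodes`` is a boolean (ny, nx) mask or an array of flattened node
        indices; ``amplitude`` a depolarizing current in the backend's
        stimulus units.
    initial_states : optional (n_conductive, n_state) array to continue a
        previous episode.
    return_states : also return the final compact state array.
    fibrotic_params : membrane parameters for fibrosis-labeled nodes.
        Defaults to the fibrotic remodeling of ``ionic_params`` whenever
        the grid carries fibrosis (pass explicitly to override).
    """
    dt = min(ionic_params.dt_max, stability_dt_max(grid)) if dt is None else dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > stability_dt_max(grid) * (1 + 1e-9):
        raise ValueError(
            f"dt={dt} violates diffusion stability bound {stability_dt_max(grid):.4g}")
    if dt > ionic_params.dt_max:
        raise ValueError(f"dt={dt} exceeds backend dt_max {ionic_params.dt_max}")

    ny, nx = grid.ny, grid.nx
    cond_flat = grid.conductive.ravel()
    cond_idx = np.flatnonzero(cond_flat)
    n_cond = cond_idx.size
    L = diffusion_operator(grid)[cond_idx][:, cond_idx]

    rest = rest_vector(ionic_params)
    v_rest = float(rest[0])
    if initial_states is None:
        states = np.tile(rest, (n_cond, 1))
    else:
        states = np.array(initial_states, dtype=float)
        if states.shape != (n_cond, rest.size):
            raise ValueError("initial_states shape mismatch")

    # compile stimuli to compact-node index lists (CSR-like layout)
    pos_of = np.full(ny * nx, -1, dtype=np.int64)
    pos_of[cond_idx] = np.arange(n_cond)
    stim_on, stim_off, stim_amp, node_lists = [], [], [], []
    for (t_on, duration, nodes, amplitude) in stimuli:
        nodes = np.asarray(nodes)
        flat = np.flatnonzero(nodes.ravel()) if nodes.dtype == bool else nodes.ravel()
        comp = pos_of[flat]
        node_lists.append(comp[comp >= 0])
        stim_on.append(float(t_on))
        stim_off.append(float(t_on) + float(duration))
        stim_amp.append(float(amplitude))
    stim_on = np.asarray(stim_on)
    stim_off = np.asarray(stim_off)
    stim_amp = np.asarray(stim_amp)
    stim_indptr = np.zeros(len(node_lists) + 1, dtype=np.int64)
    if node_lists:
        stim_indptr[1:] = np.cumsum([len(c) for c in node_lists])
        stim_nodes = np.concatenate(node_lists).astype(np.int64)
    else:
        stim_nodes = np.empty(0, dtype=np.int64)

    pvec = ionic_params.param_vector()
    fib_compact = grid.fibrosis.ravel()[cond_idx]
    if fibrotic_params is None and fib_compact.any() and not ionic_params.remodeled:
        fibrotic_params = apply_fibrotic_remodeling(ionic_params)
    if fibrotic_params is not None and fib_compact.any():
        if fibrotic_params.backend != ionic_params.backend:
            raise ValueError("fibrotic_params must use the same backend")
        is_fib = fib_compact.astype(np.bool_)
        pvec_fib = fibrotic_params.param_vector()
        if initial_states is None:
            states[is_fib] = rest_vector(fibrotic_params)
    else:
        is_fib = np.zeros(n_cond, dtype=np.bool_)
        pvec_fib = pvec

    n_steps = int(round(t_end / dt))
    save_every = max(1, int(round(dt_save / dt)))
    n_saves = n_steps // save_every + 1
    V_comp = np.empty((n_saves, n_cond), dtype=np.float64)
    t_out = np.empty(n_saves)
    V_comp[0] = states[:, 0]
    t_out[0] = 0.0

    Lc = L.tocsr()
    backend_id = 0 if ionic_params.backend == "surrogate" else 1
    ret = _sim_loop(states, Lc.indptr, Lc.indices, Lc.data, dt, n_steps,
                    save_every, stim_on, stim_off, stim_amp, stim_indptr,
                    stim_nodes, pvec, pvec_fib, is_fib, backend_id,
                    V_comp, t_out)
    if ret < 0:
        k_bad = -ret - 1
        raise InstabilityError(
            f"|V| exceeded 100 mV at t={t_out[k_bad]:.1f} ms; "
            "reduce dt or check parameters")
    k_save = ret

    V_out = np.full((k_save, ny * nx), v_rest, dtype=np.float32)
    V_out[:, cond_idx] = V_comp[:k_save]
    meta = {"backend": ionic_params.backend, "dt": dt, "dt_save": dt_save,
            "t_end": t_end, "seed": seed, "nx": nx, "ny": ny, "dx": grid.dx}
    result = SimulationResult(V=V_out.reshape(k_save, ny, nx),
                              t=t_out[:k_save], metadata=meta)
    if return_states:
        return result, states
    return result


# ---------------------------------------------------------------------------
# Activation utilities and conduction velocity
# ---------------------------------------------------------------------------

def activation_times(V: np.ndarray, t: np.ndarray,
                     threshold: float = -40.0) -> np.ndarray:
    """First upward threshold-crossing time per node (NaN if none).

    Linear interpolation between the bracketing samples.
    """
    below = V < threshold
    cross = below[:-1] & ~below[1:]
    first = np.full(V.shape[1:], np.nan)
    any_cross = cross.any(axis=0)
    ki = np.argmax(cross, axis=0)
    it = np.nonzero(any_cross)
    k = ki[it]
    v0 = V[(k,) + it]
    v1 = V[(k + 1,) + it]
    frac = (threshold - v0) / (v1 - v0)
    first[it] = t[k] + frac * (t[k + 1] - t[k])
    return first


def activation_counts(V: np.ndarray, threshold: float = -40.0) -> np.ndarray:
    """Number of upward threshold crossings per node."""
    below = V < threshold
    return (below[:-1] & ~below[1:]).sum(axis=0)


def measure_cv(grid: TissueGrid, ionic_params: IonicParams,
               direction: str = "x", stim_amplitude: float = 40.0,
               t_end: float | None = None) -> float:
    """Planar-wave conduction velocity (mm/ms) along ``direction``.

    A line stimulus is applied at the low edge; CV is the inverse slope of
    a linear fit of activation time vs distance over the central 50% of
    the sheet, sampled along the propagation axis at mid-height.
    """
    if direction not in ("x", "y"):
        raise ValueError("direction must be 'x' or 'y'")
    ny, nx = grid.ny, grid.nx
    mask = np.zeros((ny, nx), dtype=bool)
    if direction == "x":
        mask[:, :2] = True
        length = nx * grid.dx
    else:
        mask[:2, :] = True
        length = ny * grid.dx
    if t_end is None:
        t_end = max(200.0, length / 0.1)
    res = simulate(grid, ionic_params, stimuli=[(1.0, 2.0, mask, stim_amplitude)],
                   t_end=t_end, dt_save=0.5)
    at = activation_times(res.V, res.t)
    if direction == "x":
        line = at[ny // 2, :]
    else:
        line = at[:, nx // 2]
    npts = line.size
    sl = slice(npts // 4, npts - npts // 4)
    d = np.arange(npts)[sl] * grid.dx
    tt = line[sl]
    if np.any(np.isnan(tt)):
        raise RuntimeError("no propagation: conduction block in CV measurement")
    slope = np.polyfit(d, tt, 1)[0]
    if slope <= 0:
        raise RuntimeError("no propagation: non-positive activation slope")
    return float(1.0 / slope)


def calibrate_cv(grid: TissueGrid, ionic_params: IonicParams,
                 target_cv_long: float, target_cv_trans: float,
                 tol: float = 0.02, max_iter: int = 8) -> tuple[float, float]:
    """Find homogeneous (D_long, D_trans) reproducing target CVs.

    Uses the near-√D scaling of CV: each iteration rescales D by
    (target/measured)^2 and re-measures, stopping within ``tol`` relative
    error.  Raises if the target is unreachable within the bracket
    [1e-4, 10] mm²/ms.
    """
    out = []
    for target, direction in ((target_cv_long, "x"), (target_cv_trans, "y")):
        d = float(grid.d_long[grid.ny // 2, grid.nx // 2]
                  if direction == "x" else grid.d_trans[grid.ny // 2, grid.nx // 2])
        measured = np.nan
        for _ in range(max_iter):
            # CV along one axis depends only on D along that axis
            g2 = TissueGrid.uniform(grid.nx, grid.ny, dx=grid.dx, d_long=d,
                                    anisotropy=1.0)
            try:
                measured = measure_cv(g2, ionic_params, direction=direction)
            except RuntimeError as exc:
                raise RuntimeError(
                    f"calibration bracket failure for target {target} mm/ms: {exc}")
            if abs(measured - target) / target <= tol:
                break
            d *= (target / measured) ** 2
            if not (1e-4 <= d <= 10.0):
                raise RuntimeError(
                    f"calibration bracket failure: target {target} mm/ms "
                    f"needs D={d:.3g} outside [1e-4, 10] "
                    f"(last measured CV {measured:.3g})")
        else:
            raise RuntimeError(
                f"calibration did not converge: target {target}, last {measured}")
        out.append(d)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def save_result(path, result: SimulationResult) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("V", data=result.V.astype(np.float32),
                         compression="gzip", compression_opts=4)
        f.create_dataset("t", data=result.t)
        f.attrs["metadata"] = json.dumps(result.metadata)


def load_result(path) -> SimulationResult:
    with h5py.File(path, "r") as f:
        return SimulationResult(V=f["V"][...], t=f["t"][...],
                                metadata=json.loads(f.attrs["metadata"]))


def save_grid(path, grid: TissueGrid) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["nx"], f.attrs["ny"], f.attrs["dx"] = grid.nx, grid.ny, grid.dx
        for name in ("fiber_angle", "d_long", "d_trans", "fibrosis",
                     "conductive", "region_id"):
            f.create_dataset(name, data=getattr(grid, name))


def load_grid(path) -> TissueGrid:
    with h5py.File(path, "r") as f:
        return TissueGrid(
            nx=int(f.attrs["nx"]), ny=int(f.attrs["ny"]), dx=float(f.attrs["dx"]),
            fiber_angle=f["fiber_angle"][...], d_long=f["d_long"][...],
            d_trans=f["d_trans"][...], fibrosis=f["fibrosis"][...].astype(bool),
            conductive=f["conductive"][...].astype(bool),
            region_id=f["region_id"][...].astype(np.int32))
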