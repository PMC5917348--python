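"""Membrane kinetics for chronic-AF atrial myocytes.

Two backends share one array-level interface:

``full_atrial``
    The Courtemanche–Ramirez–Nattel human atrial ionic model (21 state
    variables) with a chronic-AF remodeling variant applied as named
    conductance multipliers (reduced I_to/I_CaL/I_Kur, increased I_K1 —
    the widely used electrical-remodeling set; all overridable).
``surrogate``
    A Fenton–Karma-style 3-variable excitable medium, used for tissue-scale
    work where the full model is unnecessarily expensive.  Voltage is
    mapped to mV so that all downstream analysis (activation detection,
    phase mapping) is backend-agnostic.

Fibrotic remodeling multiplies I_K1 by 0.5, I_CaL by 0.5 and I_Na by 0.6
on the full backend; on the surrogate the same physiology is mirrored by
reduced excitability (fast inward current x0.6) and recovery-time changes
calibrated to the full backend's fibrotic APD prolongation (see
:meth:`IonicParams.param_vector`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

BACKENDS = ("surrogate", "full_atrial")

#: Default fibrotic conductance scalings (I_K1, I_CaL, I_Na multipliers).
FIBROSIS_SCALINGS = {"s_K1": 0.5, "s_CaL": 0.5, "s_Na": 0.6}

#: Default chronic-AF electrical remodeling multipliers for the full model.
CAF_SCALINGS = {"g_to": 0.5, "g_CaL": 0.3, "g_K1": 2.0, "g_Kur": 0.5}

#: Default surrogate (3-variable) parameters.  Time constants in ms,
#: dimensionless activation variable u in [0, 1].  The recovery constants
#: are tuned for a short, chronic-AF-like action potential that sustains
#: stable spiral-wave reentry on centimeter-scale sheets.
SURROGATE_PARAMS = {
    "tau_d": 0.25,      # fast (Na-like) inward current time scale
    "tau_o": 12.5,      # ungated (K1-like) outward time scale
    "tau_r": 32.0,      # plateau outward (repolarizing) time scale
    "tau_si": 36.0,     # slow (Ca-like) inward time scale
    "tau_vplus": 3.33,  # fast-gate inactivation
    "tau_v1m": 1000.0,  # fast-gate recovery while still depolarized (u >= u_v)
    "tau_v2m": 19.6,    # fast-gate recovery near rest (u < u_v)
    "tau_wplus": 400.0, # slow-gate inactivation (sets plateau rundown)
    "tau_wm": 41.0,     # slow-gate recovery
    "u_c": 0.13,        # excitation threshold
    "u_v": 0.04,
    "u_csi": 0.5,       # graded slow-inward activation midpoint
    "k_si": 10.0,
    "v_rest": -85.0,    # mV at u = 0
    "v_amp": 105.0,     # mV excursion for u = 1
}

#: multiplier on the surrogate's tau_r under fibrotic remodeling, set so
#: the fibrotic/non-fibrotic APD90 ratio matches the full atrial backend
#: under the same -50% I_K1 / -50% I_CaL / -40% I_Na scalings (~1.15).
FIBROSIS_SURROGATE_APD_FACTOR = 1.04

DT_MAX = {"surrogate": 0.1, "full_atrial": 0.02}
N_STATE = {"surrogate": 3, "full_atrial": 21}

_CRN_MULT_KEYS = ("g_Na", "g_K1", "g_to", "g_Kur", "g_Kr", "g_Ks", "g_CaL")


class RemodelingError(ValueError):
    """Raised when fibrotic remodeling would be applied twice."""


@dataclass(frozen=True)
class IonicState:
    """Membrane state: V (mV), gating variables in [0,1], concentrations (mM)."""

    V: float
    gates: np.ndarray
    concentrations: np.ndarray

    def as_vector(self) -> np.ndarray:
        return np.concatenate(([self.V], self.gates, self.concentrations))

    @staticmethod
    def from_vector(vec: np.ndarray, backend: str) -> "IonicState":
        vec = np.asarray(vec, dtype=float)
        if backend == "surrogate":
            return IonicState(V=float(vec[0]), gates=vec[1:3].copy(),
                              concentrations=np.empty(0))
        return IonicState(V=float(vec[0]), gates=vec[1:16].copy(),
                          concentrations=vec[16:21].copy())


@dataclass(frozen=True)
class IonicParams:
    """Backend choice plus conductance scalings.

    ``multipliers`` are cumulative factors applied to the published baseline
    conductances (full backend) or the named surrogate constants.  The
    ``remodeled`` flag guards against compounding the fibrotic x0.5/x0.5/x0.6
    scalings by accident.
    """

    backend: str = "surrogate"
    caf_scalings: dict = field(default_factory=lambda: dict(CAF_SCALINGS))
    fibrosis_scalings: dict = field(default_factory=lambda: dict(FIBROSIS_SCALINGS))
    surrogate: dict = field(default_factory=lambda: dict(SURROGATE_PARAMS))
    remodeled: bool = False

    def __post_init__(self):
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}")
        if any(v <= 0 for v in self.fibrosis_scalings.values()):
            raise ValueError("fibrosis scalings must be strictly positive")

    @property
    def dt_max(self) -> float:
        return DT_MAX[self.backend]

    @property
    def n_state(self) -> int:
        return N_STATE[self.backend]

    def param_vector(self) -> np.ndarray:
        """Flat float64 vector consumed by the jitted kernels."""
        if self.backend == "surrogate":
            p = dict(self.surrogate)
            if self.remodeled:
                fs = self.fibrosis_scalings
                # excitability x s_Na: fast inward current scaled down
                p["tau_d"] = p["tau_d"] / fs["s_Na"]
                # combined s_K1/s_CaL effect: the full backend's fibrotic
                # cell repolarizes ~15% later (I_K1 reduction dominates);
                # mirrored by slowing the plateau outward current
                p["tau_r"] = p["tau_r"] * FIBROSIS_SURROGATE_APD_FACTOR
                # weaker K1-like outward also slows the final phase-4 decay
                p["tau_o"] = p["tau_o"] / fs["s_K1"]
            keys = ("tau_d", "tau_o", "tau_r", "tau_si", "tau_vplus",
                    "tau_v1m", "tau_v2m", "tau_wplus", "tau_wm",
                    "u_c", "u_v", "u_csi", "k_si", "v_rest", "v_amp")
            return np.array([p[k] for k in keys], dtype=np.float64)
        mult = {k: 1.0 for k in _CRN_MULT_KEYS}
        for k, v in self.caf_scalings.items():
            if k not in mult:
                raise ValueError(f"unknown cAF scaling {k!r}")
            mult[k] *= v
        if self.remodeled:
            fs = self.fibrosis_scalings
            mult["g_K1"] *= fs["s_K1"]
            mult["g_CaL"] *= fs["s_CaL"]
            mult["g_Na"] *= fs["s_Na"]
        return np.array([mult[k] for k in _CRN_MULT_KEYS], dtype=np.float64)


def apply_fibrotic_remodeling(params: IonicParams) -> IonicParams:
    """Return the fibrosis-remodeled variant of a non-fibrotic cell.

    Full backend: maximal I_K1 x0.5, I_CaL x0.5, I_Na x0.6, everything else
    untouched.  Calling twice is an error (the scalings must not compound).
    """
    if params.remodeled:
        raise RemodelingError("params already carry fibrotic remodeling")
    return replace(params, remodeled=True)


# ---------------------------------------------------------------------------
# Surrogate (3-variable Fenton–Karma-style) kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fk_rhs_kernel(states, stim, p, out):
    tau_d, tau_o, tau_r, tau_si = p[0], p[1], p[2], p[3]
    tau_vplus, tau_v1m, tau_v2m = p[4], p[5], p[6]
    tau_wplus, tau_wm = p[7], p[8]
    u_c, u_v, u_csi, k_si = p[9], p[10], p[11], p[12]
    v_rest, v_amp = p[13], p[14]
    for i in range(states.shape[0]):
        u = (states[i, 0] - v_rest) / v_amp
        v = states[i, 1]
        w = states[i, 2]
        exc = 1.0 if u >= u_c else 0.0
        j_fi = -v * exc * (u - u_c) * (1.0 - u) / tau_d
        j_so = u * (1.0 - exc) / tau_o + exc / tau_r
        j_si = -w * (math.tanh(k_si * (u - u_csi))
                     - math.tanh(-k_si * u_csi)) / (2.0 * tau_si)
        du = -(j_fi + j_so + j_si) + stim[i] / v_amp
        if exc > 0.0:
            dv = -v / tau_vplus
            dw = -w / tau_wplus
        else:
            tau_vm = tau_v1m if u >= u_v else tau_v2m
            dv = (1.0 - v) / tau_vm
            dw = (1.0 - w) / tau_wm
        out[i, 0] = du * v_amp
        out[i, 1] = dv
        out[i, 2] = dw


@njit(cache=True)
def _fk_gate_decays(p, dt):
    """Constant per-step exponential gate factors (Rush–Larsen) plus the
    slow-inward activation value at rest (subtracted so u = 0 is an exact
    fixed point)."""
    return (math.exp(-dt / p[4]), math.exp(-dt / p[5]),
            math.exp(-dt / p[6]), math.exp(-dt / p[7]),
            math.exp(-dt / p[8]), math.tanh(-p[12] * p[11]))


@njit(cache=True)
def _fk_step_node_fast(s, dt, stim_i, p, decays):
    tau_d, tau_o, tau_r, tau_si = p[0], p[1], p[2], p[3]
    u_c, u_v, u_csi, k_si = p[9], p[10], p[11], p[12]
    v_rest, v_amp = p[13], p[14]
    e_vp, e_v1, e_v2, e_wp, e_wm, si_rest = decays
    u = (s[0] - v_rest) / v_amp
    v = s[1]
    w = s[2]
    if u >= u_c:
        j_fi = -v * (u - u_c) * (1.0 - u) / tau_d
        j_so = 1.0 / tau_r
        v_new = v * e_vp
        w_new = w * e_wp
    else:
        j_fi = 0.0
        j_so = u / tau_o
        e_v = e_v1 if u >= u_v else e_v2
        v_new = 1.0 + (v - 1.0) * e_v
        w_new = 1.0 + (w - 1.0) * e_wm
    j_si = -w * (math.tanh(k_si * (u - u_csi)) - si_rest) / (2.0 * tau_si)
    u_new = u + dt * (-(j_fi + j_so + j_si) + stim_i / v_amp)
    if v_new < 0.0:
        v_new = 0.0
    elif v_new > 1.0:
        v_new = 1.0
    if w_new < 0.0:
        w_new = 0.0
    elif w_new > 1.0:
        w_new = 1.0
    s[0] = v_rest + u_new * v_amp
    s[1] = v_new
    s[2] = w_new


@njit(cache=True)
def _fk_step_kernel(states, dt, stim, p):
    decays = _fk_gate_decays(p, dt)
    for i in range(states.shape[0]):
        _fk_step_node_fast(states[i], dt, stim[i], p, decays)


# ---------------------------------------------------------------------------
# Full atrial (Courtemanche–Ramirez–Nattel) kernels
# ---------------------------------------------------------------------------
# State layout (21):
#  0 V, 1 m, 2 h, 3 j, 4 oa, 5 oi, 6 ua, 7 ui, 8 xr, 9 xs, 10 d, 11 f,
#  12 fca, 13 u, 14 v, 15 w, 16 Na_i, 17 K_i, 18 Ca_i, 19 Ca_up, 20 Ca_rel

_CRN_REST = np.array([
    -81.18, 2.908e-3, 9.649e-1, 9.775e-1, 3.043e-2, 9.992e-1, 4.966e-3,
    9.986e-1, 3.296e-5, 1.869e-2, 1.367e-4, 9.996e-1, 7.755e-1, 0.0, 1.0,
    9.992e-1, 11.17, 139.0, 1.013e-4, 1.488, 1.488,
])

# Quiescent fixed point of the default chronic-AF variant (60 s
# equilibration at dt = 0.02 ms); used as the starting state so that short
# equilibrations land extremely close to rest.
_CRN_REST_CAF = np.array([
    -8.4076452947e+01, 1.8020534333e-03, 9.8146282659e-01, 9.8839823433e-01,
    2.5922851773e-02, 9.9956136591e-01, 3.6779542666e-03, 9.9874397407e-01,
    2.1112827208e-05, 1.6677407084e-02, 9.5188462817e-05, 9.9970464098e-01,
    7.8310157021e-01, 0.0, 1.0, 9.9932398218e-01, 1.1290390754e+01,
    1.3889207085e+02, 9.6940770573e-05, 1.4293380287e+00, 1.4292684866e+00,
])

_R = 8.3143
_T = 310.0
_F = 96.4867
_CM = 100.0
_V_I = 13668.0
_V_UP = 1109.52
_V_REL = 96.48
_KO = 5.4
_NAO = 140.0
_CAO = 1.8


@njit(cache=True)
def _crn_core(y, p, istim, d_out, inf_out, tau_out):
    """Rates for one cell: writes dV & d(conc) into d_out (indices 0,16..20)
    and gate steady states / time constants into inf_out/tau_out (15 each)."""
    g_na = 7.8 * p[0]
    g_k1 = 0.09 * p[1]
    g_to = 0.1652 * p[2]
    s_kur = p[3]
    g_kr = 0.029411765 * p[4]
    g_ks = 0.12941176 * p[5]
    g_cal = 0.12375 * p[6]

    V = y[0]
    m, h, jg = y[1], y[2], y[3]
    oa, oi, ua, ui = y[4], y[5], y[6], y[7]
    xr, xs, d, f, fca = y[8], y[9], y[10], y[11], y[12]
    uu, vv, ww = y[13], y[14], y[15]
    nai, ki, cai, caup, carel = y[16], y[17], y[18], y[19], y[20]

    rtf = _R * _T / _F
    e_na = rtf * math.log(_NAO / nai)
    e_k = rtf * math.log(_KO / ki)
    e_ca = 0.5 * rtf * math.log(_CAO / cai)

    # --- fast sodium ---
    i_na = g_na * m * m * m * h * jg * (V - e_na)
    dv = V + 47.13
    if abs(dv) < 1e-10:
        a_m = 3.2
    else:
        a_m = 0.32 * dv / (1.0 - math.exp(-0.1 * dv))
    b_m = 0.08 * math.exp(-V / 11.0)
    if V >= -40.0:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
        a_j = 0.0
        b_j = (0.3 * math.exp(-2.535e-7 * V)
               / (1.0 + math.exp(-0.1 * (V + 32.0))))
    else:
        a_h = 0.135 * math.exp(-(V + 80.0) / 6.8)
        b_h = 3.56 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.35 * V)
        a_j = ((-1.2714e5 * math.exp(0.2444 * V)
                - 3.474e-5 * math.exp(-0.04391 * V)) * (V + 37.78)
               / (1.0 + math.exp(0.311 * (V + 79.23))))
        b_j = (0.1212 * math.exp(-0.01052 * V)
               / (1.0 + math.exp(-0.1378 * (V + 40.14))))
    inf_out[0] = a_m / (a_m + b_m)
    tau_out[0] = 1.0 / (a_m + b_m)
    inf_out[1] = a_h / (a_h + b_h)
    tau_out[1] = 1.0 / (a_h + b_h)
    inf_out[2] = a_j / (a_j + b_j)
    tau_out[2] = 1.0 / (a_j + b_j)

    # --- inward rectifier ---
    i_k1 = g_k1 * (V - e_k) / (1.0 + math.exp(0.07 * (V + 80.0)))

    # --- transient outward ---
    i_to = g_to * oa * oa * oa * oi * (V - e_k)
    a_oa = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    inf_out[3] = 1.0 / (1.0 + math.exp(-(V + 20.47) / 17.54))
    tau_out[3] = 1.0 / ((a_oa + b_oa) * 3.0)
    a_oi = 1.0 / (18.53 + math.exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + math.exp(-(V + 1.26) / 7.44))
    inf_out[4] = 1.0 / (1.0 + math.exp((V + 43.1) / 5.3))
    tau_out[4] = 1.0 / ((a_oi + b_oi) * 3.0)

    # --- ultrarapid delayed rectifier ---
    g_kur = s_kur * (0.005 + 0.05 / (1.0 + math.exp(-(V - 15.0) / 13.0)))
    i_kur = g_kur * ua * ua * ua * ui * (V - e_k)
    a_ua = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    inf_out[5] = 1.0 / (1.0 + math.exp(-(V + 30.3) / 9.6))
    tau_out[5] = 1.0 / ((a_ua + b_ua) * 3.0)
    a_ui = 1.0 / (21.0 + math.exp(-(V - 185.0) / 28.0))
    b_ui = math.exp((V - 158.0) / 16.0)
    inf_out[6] = 1.0 / (1.0 + math.exp((V - 99.45) / 27.48))
    tau_out[6] = 1.0 / ((a_ui + b_ui) * 3.0)

    # --- rapid delayed rectifier ---
    i_kr = g_kr * xr * (V - e_k) / (1.0 + math.exp((V + 15.0) / 22.4))
    dv = V + 14.1
    if abs(dv) < 1e-10:
        a_xr = 0.0015
    else:
        a_xr = 0.0003 * dv / (1.0 - math.exp(-dv / 5.0))
    dv = V - 3.3328
    if abs(dv) < 1e-10:
        b_xr = 3.7836118e-4
    else:
        b_xr = 7.3898e-5 * dv / (math.exp(dv / 5.1237) - 1.0)
    inf_out[7] = 1.0 / (1.0 + math.exp(-(V + 14.1) / 6.5))
    tau_out[7] = 1.0 / (a_xr + b_xr)

    # --- slow delayed rectifier ---
    i_ks = g_ks * xs * xs * (V - e_k)
    dv = V - 19.9
    if abs(dv) < 1e-10:
        a_xs = 6.8e-4
        b_xs = 3.15e-4
    else:
        a_xs = 4e-5 * dv / (1.0 - math.exp(-dv / 17.0))
        b_xs = 3.5e-5 * dv / (math.exp(dv / 9.0) - 1.0)
    inf_out[8] = 1.0 / math.sqrt(1.0 + math.exp(-(V - 19.9) / 12.7))
    tau_out[8] = 0.5 / (a_xs + b_xs)

    # --- L-type calcium ---
    i_cal = g_cal * d * f * fca * (V - 65.0)
    dv = V + 10.0
    inf_out[9] = 1.0 / (1.0 + math.exp(-dv / 8.0))
    if abs(dv) < 1e-10:
        tau_out[9] = 1.0 / (0.035 * 6.24 * 2.0)  # dv -> 0 limit
    else:
        e1 = math.exp(-dv / 6.24)
        tau_out[9] = (1.0 - e1) / (0.035 * dv * (1.0 + e1))
    inf_out[10] = 1.0 / (1.0 + math.exp((V + 28.0) / 6.9))
    tau_out[10] = 9.0 / (0.0197 * math.exp(-0.0337 * 0.0337 * dv * dv) + 0.02)
    inf_out[11] = 1.0 / (1.0 + cai / 0.00035)
    tau_out[11] = 2.0

    # --- pumps and exchangers ---
    sigma = (math.exp(_NAO / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * V / rtf)
                   + 0.0365 * sigma * math.exp(-V / rtf))
    i_nak = (0.59933874 * f_nak * _KO / (_KO + 1.5)
             / (1.0 + (10.0 / nai) ** 1.5))
    expg = math.exp(0.35 * V / rtf)
    expg1 = math.exp((0.35 - 1.0) * V / rtf)
    i_naca = (1600.0 * (expg * nai ** 3 * _CAO - expg1 * _NAO ** 3 * cai)
              / ((87.5 ** 3 + _NAO ** 3) * (1.38 + _CAO)
                 * (1.0 + 0.1 * expg1)))
    i_bna = 0.0006744375 * (V - e_na)
    i_bca = 0.001131 * (V - e_ca)
    i_pca = 0.275 * cai / (0.0005 + cai)

    # --- SR calcium handling ---
    i_rel = 30.0 * uu * uu * vv * ww * (carel - cai)
    i_up = 0.005 / (1.0 + 0.00092 / cai)
    i_upleak = 0.005 * caup / 15.0
    i_tr = (caup - carel) / 180.0

    fn = (1e-12 * _V_REL * i_rel
          - (5e-13 / _F) * (0.5 * i_cal - 0.2 * i_naca) * _CM)
    inf_out[12] = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 1.367e-15))
    tau_out[12] = 8.0
    inf_out[13] = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 1.367e-15))
    tau_out[13] = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 1.367e-15))
    inf_out[14] = 1.0 - 1.0 / (1.0 + math.exp(-(V - 40.0) / 17.0))
    dv = V - 7.9
    if abs(dv) < 1e-10:
        tau_out[14] = 6.0 * 0.2 / 1.3
    else:
        e1 = math.exp(-dv / 5.0)
        tau_out[14] = 6.0 * (1.0 - e1) / ((1.0 + 0.3 * e1) * dv)

    i_ion = (i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal + i_pca
             + i_nak + i_naca + i_bna + i_bca)
    d_out[0] = -i_ion + istim

    d_out[16] = (-3.0 * i_nak - 3.0 * i_naca - i_bna - i_na) * _CM / (_F * _V_I)
    d_out[17] = (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks) * _CM / (_F * _V_I)
    b1 = ((2.0 * i_naca - i_pca - i_cal - i_bca) * _CM / (2.0 * _F * _V_I)
          + (_V_UP * (i_upleak - i_up) + i_rel * _V_REL) / _V_I)
    b2 = (1.0 + 0.07 * 0.0005 / ((cai + 0.0005) ** 2)
          + 0.05 * 0.00238 / ((cai + 0.00238) ** 2))
    d_out[18] = b1 / b2
    d_out[19] = i_up - i_upleak - i_tr * _V_REL / _V_UP
    d_out[20] = (i_tr - i_rel) / (1.0 + 10.0 * 0.8 / ((carel + 0.8) ** 2))


@njit(cache=True)
def _crn_rhs_kernel(states, stim, p, out):
    d_out = np.empty(21)
    inf = np.empty(15)
    tau = np.empty(15)
    for i in range(states.shape[0]):
        _crn_core(states[i], p, stim[i], d_out, inf, tau)
        out[i, 0] = d_out[0]
        for g in range(15):
            out[i, 1 + g] = (inf[g] - states[i, 1 + g]) / tau[g]
        for c in range(5):
            out[i, 16 + c] = d_out[16 + c]


@njit(cache=True)
def _crn_step_node(s, dt, stim_i, p, d_out, inf, tau):
    _crn_core(s, p, stim_i, d_out, inf, tau)
    s[0] += dt * d_out[0]
    for g in range(15):
        gv = inf[g] + (s[1 + g] - inf[g]) * math.exp(-dt / tau[g])
        if gv < 0.0:
            gv = 0.0
        elif gv > 1.0:
            gv = 1.0
        s[1 + g] = gv
    for c in range(5):
        s[16 + c] += dt * d_out[16 + c]


@njit(cache=True)
def _crn_step_kernel(states, dt, stim, p):
    d_out = np.empty(21)
    inf = np.empty(15)
    tau = np.empty(15)
    for i in range(states.shape[0]):
        _crn_step_node(states[i], dt, stim[i], p, d_out, inf, tau)


@njit(cache=True)
def _sim_loop(states, indptr, indices, data, dt, n_steps, save_every,
              stim_on, stim_off, stim_amp, stim_indptr, stim_nodes,
              pvec, pvec_fib, is_fib, backend_id, V_out, t_out):
    """Fused monodomain time loop (diffusion matvec + reaction per step).

    Returns the number of saved frames, negated if |V| exceeded 100 mV
    (instability) at the last attempted save.
    """
    n = states.shape[0]
    stim = np.zeros(n)
    dv = np.empty(n)
    d_out = np.empty(21)
    inf = np.empty(15)
    tau = np.empty(15)
    decays = _fk_gate_decays(pvec, dt)
    decays_fib = _fk_gate_decays(pvec_fib, dt)
    k_save = 1
    for k in range(n_steps):
        t = k * dt
        for i in range(n):
            acc = 0.0
            for jj in range(indptr[i], indptr[i + 1]):
                acc += data[jj] * states[indices[jj], 0]
            dv[i] = acc
        for i in range(n):
            states[i, 0] += dt * dv[i]
        any_stim = False
        for s in range(stim_on.size):
            if stim_on[s] <= t < stim_off[s]:
                any_stim = True
        if any_stim:
            for i in range(n):
                stim[i] = 0.0
            for s in range(stim_on.size):
                if stim_on[s] <= t < stim_off[s]:
                    a = stim_amp[s]
                    for jj in range(stim_indptr[s], stim_indptr[s + 1]):
                        stim[stim_nodes[jj]] = a
        elif k > 0:
            for i in range(n):
                stim[i] = 0.0
        if backend_id == 0:
            for i in range(n):
                if is_fib[i]:
                    _fk_step_node_fast(states[i], dt, stim[i], pvec_fib,
                                       decays_fib)
                else:
                    _fk_step_node_fast(states[i], dt, stim[i], pvec, decays)
        else:
            for i in range(n):
                pp = pvec_fib if is_fib[i] else pvec
                _crn_step_node(states[i], dt, stim[i], pp, d_out, inf, tau)
        if (k + 1) % save_every == 0:
            bad = False
            for i in range(n):
                v = states[i, 0]
                V_out[k_save, i] = v
                if v > 100.0 or v < -100.0:
                    bad = True
            t_out[k_save] = (k + 1) * dt
            k_save += 1
            if bad:
                return -k_save
    return k_save


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def rest_vector(params: IonicParams) -> np.ndarray:
    """Nominal resting state vector (pre-equilibration) for the backend."""
    if params.backend == "surrogate":
        p = params.param_vector()
        return np.array([p[13], 1.0, 1.0])  # V_rest, gates fully recovered
    if params.caf_scalings == CAF_SCALINGS and not params.remodeled:
        return _CRN_REST_CAF.copy()
    return _CRN_REST.copy()


def step_kernel(backend: str):
    """In-place array step kernel: ``kernel(states, dt, stim, pvec)``."""
    return _fk_step_kernel if backend == "surrogate" else _crn_step_kernel


def rhs_kernel(backend: str):
    return _fk_rhs_kernel if backend == "surrogate" else _crn_rhs_kernel


def membrane_derivatives(state: IonicState, params: IonicParams,
                         i_stim: float = 0.0) -> np.ndarray:
    """Right-hand side d(state)/dt for one cell.

    ``i_stim`` is a depolarizing current density (pA/pF on the full backend,
    mV/ms-equivalent on the surrogate).
    """
    vec = state.as_vector()
    if not np.all(np.isfinite(vec)):
        names = _state_names(params.backend)
        bad = names[int(np.argmax(~np.isfinite(vec)))]
        raise ValueError(f"non-finite state variable: {bad}")
    states = vec[None, :].copy()
    out = np.empty_like(states)
    rhs_kernel(params.backend)(states, np.array([float(i_stim)]),
                               params.param_vector(), out)
    return out[0]


def step_cell(state: IonicState, params: IonicParams, dt: float,
              i_stim: float = 0.0) -> IonicState:
    """Advance one cell by dt (Rush–Larsen gates, explicit otherwise)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > params.dt_max:
        raise ValueError(f"dt {dt} exceeds dt_max {params.dt_max} "
                         f"for backend {params.backend}")
    states = state.as_vector()[None, :].copy()
    step_kernel(params.backend)(states, dt, np.array([float(i_stim)]),
                                params.param_vector())
    return IonicState.from_vector(states[0], params.backend)


def _state_names(backend: str) -> list[str]:
    if backend == "surrogate":
        return ["V", "v", "w"]
    return ["V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d",
            "f", "fca", "u", "v", "w", "Na_i", "K_i", "Ca_i", "Ca_up",
            "Ca_rel"]


def simulate_cell(params: IonicParams, t_end: float, dt: float | None = None,
                  stim_times: tuple = (), stim_duration: float = 2.0,
                  stim_amplitude: float = 20.0, dt_save: float = 0.5,
                  initial: np.ndarray | None = None):
    """Integrate a single cell; returns (t, V, final_state_vector)."""
    dt = params.dt_max if dt is None else dt
    if dt <= 0 or dt > params.dt_max:
        raise ValueError("invalid dt")
    pvec = params.param_vector()
    kern = step_kernel(params.backend)
    states = (rest_vector(params) if initial is None
              else np.asarray(initial, dtype=float)).copy()[None, :]
    n_steps = int(round(t_end / dt))
    save_every = max(1, int(round(dt_save / dt)))
    stim_times = np.asarray(stim_times, dtype=float)
    t_out, v_out = [0.0], [states[0, 0]]
    stim_arr = np.zeros(1)
    for k in range(n_steps):
        t = k * dt
        on = np.any((stim_times <= t) & (t < stim_times + stim_duration))
        stim_arr[0] = stim_amplitude if on else 0.0
        kern(states, dt, stim_arr, pvec)
        if (k + 1) % save_every == 0:
            t_out.append((k + 1) * dt)
            v_out.append(states[0, 0])
    return np.array(t_out), np.array(v_out), states[0].copy()


def equilibrate(params: IonicParams, t_end: float = 10000.0,
                dt: float | None = None) -> np.ndarray:
    """Quiescent equilibration to (near) the resting fixed point."""
    _, _, final = simulate_cell(params, t_end, dt=dt, dt_save=t_end)
    return final


def measure_apd90(v_trace: np.ndarray, t: np.ndarray, t_stim: float) -> float:
    """Action-potential duration at 90% repolarization.

    Measured from the point of maximum upstroke velocity after ``t_stim``
    to the first return to 90% of the way from peak back to the
    pre-stimulus baseline.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v_trace, dtype=float)
    pre = v[t <= t_stim]
    baseline = pre[-1] if pre.size else v[0]
    after = t >= t_stim
    idx0 = int(np.argmax(after))
    if v[idx0:].max() < -40.0:
        raise ValueError("no AP")
    dvdt = np.diff(v[idx0:]) / np.diff(t[idx0:])
    i_up = idx0 + int(np.argmax(dvdt))
    t_up = t[i_up]
    peak = v[i_up:].max()
    v90 = baseline + 0.1 * (peak - baseline)
    below = np.nonzero(v[i_up + 1:] <= v90)[0]
    if below.size == 0:
        raise ValueError("no repolarization to 90% within trace")
    i_down = i_up + 1 + below[0]
    # linear interpolation across the crossing sample
    v0, v1 = v[i_down - 1], v[i_down]
    t0, t1 = t[i_down - 1], t[i_down]
    frac = 0.0 if v1 == v0 else (v0 - v90) / (v0 - v1)
    return float(t0 + frac * (t1 - t0) - t_up)


def diastolic_threshold(params: IonicParams, dt: float | None = None,
                        stim_duration: float = 2.0,
                        bracket: tuple[float, float] = (0.1, 200.0),
                        tol: float = 0.05,
                        initial: np.ndarray | None = None) -> float:
    """Minimum 2-ms stimulus amplitude that elicits an action potential.

    Found by bisection on the stimulus amplitude; an AP is a depolarization
    above -40 mV (surrogate/full-voltage convention) within 50 ms.
    """
    init = equilibrate(params, 2000.0, dt=dt) if initial is None else initial

    def fires(amp: float) -> bool:
        _, v, _ = simulate_cell(params, 50.0, dt=dt, stim_times=(1.0,),
                                stim_duration=stim_duration,
                                stim_amplitude=amp, dt_save=0.5,
                                initial=init)
        return v.max() > -40.0

    lo, hi = bracket
    if fires(lo):
        return lo
    if not fires(hi):
        raise ValueError("no AP even at maximum bracket amplitude")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi
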