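"""ten Tusscher–Panfilov 2006 (TP06) human ventricular cell model.

Implements the published TP06 formulation: 12 transmembrane currents
(I_Na, I_K1, I_to, I_Kr, I_Ks, I_CaL, I_NaCa, I_NaK, I_pCa, I_pK,
I_bCa, I_bNa), calcium subsystem with subspace (Ca_ss) and SR (Ca_SR)
compartments, rapid-buffering approximation, and the R-bar ryanodine
release adaptation variable.  Transmural heterogeneity enters through
the layer-specific conductances (G_Ks, G_to) and the s-gate kinetics;
a separate "VF" parameter mode applies the steep-restitution overrides
(G_Kr, G_Ks, G_pCa, G_pK and a doubled f-gate time constant) used for
fibrillation studies.

Gates are advanced with the exponential Rush–Larsen rule
``x <- x_inf + (x - x_inf) * exp(-dt / tau_x)``; the membrane potential
and the five ionic concentrations use forward Euler.

Units: mV, ms, mM; currents are densities normalised by membrane
capacitance (pA/pF == mV/ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import NamedTuple, Sequence

import numpy as np
from numba import njit

__all__ = [
    "CellParameters",
    "CellState",
    "StimulusSpec",
    "CELL_TYPES",
    "MODES",
    "STATE_NAMES",
    "GATE_NAMES",
    "make_cell_params",
    "default_initial_state",
    "ionic_rhs",
    "step_rush_larsen",
    "simulate_single_cell",
]

CELL_TYPES = ("endocardial", "mid-myocardial", "epicardial")
MODES = ("restitution", "VF")

# State-vector layout (one row per cell/node).
STATE_NAMES = (
    "V", "Xr1", "Xr2", "Xs", "m", "h", "j", "d", "f", "f2", "fCass",
    "s", "r", "Ca_i", "Ca_SR", "Ca_ss", "Na_i", "K_i", "R_bar",
)
N_STATE = len(STATE_NAMES)
# Rush–Larsen variables: the 12 Hodgkin–Huxley gates plus R_bar (linear
# in itself, so the exponential update is exact for frozen Ca_ss).
GATE_NAMES = ("Xr1", "Xr2", "Xs", "m", "h", "j", "d", "f", "f2", "fCass", "s", "r", "R_bar")
_GATE_IDX = np.array([STATE_NAMES.index(g) for g in GATE_NAMES], dtype=np.int64)
_CONC_NAMES = ("Ca_i", "Ca_SR", "Ca_ss", "Na_i", "K_i")
_CONC_IDX = np.array([STATE_NAMES.index(c) for c in _CONC_NAMES], dtype=np.int64)

# ---------------------------------------------------------------------------
# Fixed model constants (published values; mV, ms, mM, pA/pF).
# ---------------------------------------------------------------------------
R_GAS = 8314.472      # mJ/(mol K)
TEMP = 310.0          # K
FARADAY = 96485.3415  # C/mol
CAPACITANCE = 0.185   # membrane capacitance scaling in the flux terms

K_O = 5.4
NA_O = 140.0
CA_O = 2.0

V_C = 0.016404
V_SR = 0.001094
V_SS = 0.00005468

BUF_C = 0.2
K_BUF_C = 0.001
BUF_SR = 10.0
K_BUF_SR = 0.3
BUF_SS = 0.4
K_BUF_SS = 0.00025

V_MAXUP = 0.006375
K_UP = 0.00025
V_REL = 0.102
V_LEAK = 0.00036
V_XFER = 0.0038
K1_PRIME = 0.15
K2_PRIME = 0.045
K3 = 0.060
K4 = 0.005
MAX_SR = 2.5
MIN_SR = 1.0
EC_50 = 1.5

P_KNA = 0.03
G_K1 = 5.405
G_NA = 14.838
G_CAL = 3.980e-5
G_BNA = 0.00029
G_BCA = 0.000592
K_PCA = 0.0005
P_NAK = 2.724
K_MK = 1.0
K_MNA = 40.0
K_NACA = 1000.0
KM_NAI = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA_NACA = 0.35
ALPHA_NACA = 2.5

# Layer-specific published ("restitution" mode) conductances.
_G_KS_DEFAULT = {"endocardial": 0.392, "mid-myocardial": 0.098, "epicardial": 0.392}
_G_TO_DEFAULT = {"endocardial": 0.073, "mid-myocardial": 0.294, "epicardial": 0.294}
_G_KR_DEFAULT = 0.153
_G_PCA_DEFAULT = 0.1238
_G_PK_DEFAULT = 0.0146

# VF-mode overrides (steep-restitution parameter set).
_G_KR_VF = 0.172
_G_KS_VF = {"endocardial": 0.2205, "mid-myocardial": 0.0515, "epicardial": 0.2205}
_G_PCA_VF = 1.8545
_G_PK_VF = 0.00073
_TAU_F_SCALE_VF = 2.0


class UnknownCellTypeError(ValueError):
    pass


class UnknownModeError(ValueError):
    pass


@dataclass(frozen=True)
class CellParameters:
    """Layer- and mode-dependent TP06 parameters.

    All remaining constants are module-level and shared by every cell.
    """

    cell_type: str
    mode: str
    G_Kr: float
    G_Ks: float
    G_to: float
    G_pCa: float
    G_pK: float
    tau_f_scale: float = 1.0

    def __post_init__(self):
        if self.cell_type not in CELL_TYPES:
            raise UnknownCellTypeError(f"unknown cell_type {self.cell_type!r}")
        if self.mode not in MODES:
            raise UnknownModeError(f"unknown mode {self.mode!r}")
        for name in ("G_Kr", "G_Ks", "G_to", "G_pCa", "G_pK"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tau_f_scale <= 0:
            raise ValueError("tau_f_scale must be positive")

    @property
    def endo_s_gate(self) -> bool:
        """Endocardial cells use distinct s-gate kinetics."""
        return self.cell_type == "endocardial"

    def to_config(self) -> dict:
        return asdict(self)


def make_cell_params(cell_type: str, mode: str = "restitution") -> CellParameters:
    """Return the complete TP06 parameter set for a layer and mode.

    ``restitution`` mode uses the published layer-specific conductances;
    ``VF`` mode applies the steep-restitution overrides (identical for
    the three layers except G_Ks, plus a doubled f-gate time constant).
    """
    if cell_type not in CELL_TYPES:
        raise UnknownCellTypeError(
            f"unknown cell_type {cell_type!r}; expected one of {CELL_TYPES}")
    if mode not in MODES:
        raise UnknownModeError(f"unknown mode {mode!r}; expected one of {MODES}")
    if mode == "VF":
        return CellParameters(
            cell_type=cell_type, mode=mode,
            G_Kr=_G_KR_VF, G_Ks=_G_KS_VF[cell_type],
            G_to=_G_TO_DEFAULT[cell_type],
            G_pCa=_G_PCA_VF, G_pK=_G_PK_VF,
            tau_f_scale=_TAU_F_SCALE_VF,
        )
    return CellParameters(
        cell_type=cell_type, mode=mode,
        G_Kr=_G_KR_DEFAULT, G_Ks=_G_KS_DEFAULT[cell_type],
        G_to=_G_TO_DEFAULT[cell_type],
        G_pCa=_G_PCA_DEFAULT, G_pK=_G_PK_DEFAULT,
        tau_f_scale=1.0,
    )


@dataclass
class CellState:
    """TP06 state vector for a single cell (mV, mM, dimensionless gates)."""

    V: float = -85.23
    Xr1: float = 0.00621
    Xr2: float = 0.4712
    Xs: float = 0.0095
    m: float = 0.00172
    h: float = 0.7444
    j: float = 0.7045
    # The published table value for the resting d gate is 3.373e-5; a gate
    # variable is confined to [0,1] by construction, so any larger printed
    # magnitude is a typographical loss of the negative exponent.
    d: float = 3.373e-5
    f: float = 0.7888
    f2: float = 0.9755
    fCass: float = 0.9953
    s: float = 0.999998
    r: float = 2.42e-8
    Ca_i: float = 0.000126
    Ca_SR: float = 3.64
    Ca_ss: float = 0.00036
    Na_i: float = 8.604
    K_i: float = 136.89
    R_bar: float = 0.9073

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=np.float64)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CellState":
        y = np.asarray(y, dtype=np.float64)
        if y.shape != (N_STATE,):
            raise ValueError(f"state array must have shape ({N_STATE},)")
        return cls(**{n: float(y[i]) for i, n in enumerate(STATE_NAMES)})

    def validate(self) -> None:
        y = self.as_array()
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite cell state")
        gates = y[_GATE_IDX]
        if np.any(gates < -1e-12) or np.any(gates > 1 + 1e-12):
            raise ValueError("gate variable outside [0, 1]")
        if np.any(y[_CONC_IDX] <= 0):
            raise ValueError("non-positive ionic concentration")


@dataclass(frozen=True)
class StimulusSpec:
    """Square stimulus pulse: current density / C_m, added to dV/dt."""

    amplitude: float   # mV/ms
    duration: float    # ms
    onset: float = 0.0  # ms

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.amplitude < 0:
            raise ValueError("stimulus amplitude must be non-negative")

    def value_at(self, t: float) -> float:
        return self.amplitude if self.onset <= t < self.onset + self.duration else 0.0


# ---------------------------------------------------------------------------
# Numba kernels.  ``_eval_node`` fills a 32-slot scratch row:
#   out[0]      dV/dt (ionic + stimulus)
#   out[1:14]   x_inf for the 13 Rush–Larsen variables (GATE_NAMES order)
#   out[14:27]  tau_x for the same variables (ms)
#   out[27:32]  d/dt of (Ca_i, Ca_SR, Ca_ss, Na_i, K_i)
# ---------------------------------------------------------------------------
N_SCRATCH = 32


@njit(cache=True, fastmath=False)
def _eval_node(y, g_kr, g_ks, g_to, g_pca, g_pk, tauf_scale, endo_s, stim, out):
    V = y[0]
    Xr1 = y[1]; Xr2 = y[2]; Xs = y[3]
    m = y[4]; h = y[5]; j = y[6]
    d = y[7]; f = y[8]; f2 = y[9]; fCass = y[10]
    s = y[11]; r = y[12]
    Cai = y[13]; CaSR = y[14]; Cass = y[15]
    Nai = y[16]; Ki = y[17]; Rbar = y[18]

    rtof = R_GAS * TEMP / FARADAY
    EK = rtof * np.log(K_O / Ki)
    ENa = rtof * np.log(NA_O / Nai)
    EKs = rtof * np.log((K_O + P_KNA * NA_O) / (Ki + P_KNA * Nai))
    ECa = 0.5 * rtof * np.log(CA_O / Cai)

    # --- fast Na+ current
    INa = G_NA * m * m * m * h * j * (V - ENa)
    m_inf = 1.0 / ((1.0 + np.exp((-56.86 - V) / 9.03)) ** 2)
    a_m = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    b_m = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    tau_m = a_m * b_m
    h_inf = 1.0 / ((1.0 + np.exp((V + 71.55) / 7.43)) ** 2)
    if V >= -40.0:
        a_h = 0.0
        b_h = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    else:
        a_h = 0.057 * np.exp(-(V + 80.0) / 6.8)
        b_h = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
    tau_h = 1.0 / (a_h + b_h)
    j_inf = h_inf
    if V >= -40.0:
        a_j = 0.0
        b_j = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    else:
        a_j = ((-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
               * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))))
        b_j = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    tau_j = 1.0 / (a_j + b_j)

    # --- L-type Ca2+ current (GHK-like driving term; series limit at V=15)
    vv = V - 15.0
    a_cal = 2.0 * vv / rtof
    if abs(a_cal) < 1e-7:
        drive = 2.0 * FARADAY * (0.25 * Cass - CA_O)
    else:
        ea = np.exp(a_cal)
        drive = 2.0 * FARADAY * a_cal * (0.25 * Cass * ea - CA_O) / (ea - 1.0)
    ICaL = G_CAL * d * f * f2 * fCass * drive
    d_inf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    a_d = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    b_d = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    g_d = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    tau_d = a_d * b_d + g_d
    f_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau_f = (1102.5 * np.exp(-((V + 27.0) ** 2) / 225.0)
             + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
             + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0) * tauf_scale
    f2_inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    tau_f2 = (600.0 * np.exp(-((V + 25.0) ** 2) / 170.0)
              + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
              + 16.0 / (1.0 + np.exp((V + 30.0) / 10.0)))
    fcass_inf = 0.6 / (1.0 + (Cass / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (Cass / 0.05) ** 2) + 2.0

    # --- transient outward
    Ito = g_to * r * s * (V - EK)
    r_inf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau_r = 9.5 * np.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
    if endo_s:
        s_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
        tau_s = 1000.0 * np.exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
    else:
        s_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        tau_s = (85.0 * np.exp(-((V + 45.0) ** 2) / 320.0)
                 + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0)

    # --- delayed rectifiers
    IKr = g_kr * np.sqrt(K_O / 5.4) * Xr1 * Xr2 * (V - EK)
    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    a_xr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    b_xr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    tau_xr1 = a_xr1 * b_xr1
    xr2_inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    a_xr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    b_xr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    tau_xr2 = a_xr2 * b_xr2
    IKs = g_ks * Xs * Xs * (V - EKs)
    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    a_xs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
    b_xs = 1.0 / (1.0 + np.exp((V - 35.0) / 15.0))
    tau_xs = a_xs * b_xs + 80.0

    # --- inward rectifier
    a_k1 = 0.1 / (1.0 + np.exp(0.06 * (V - EK - 200.0)))
    b_k1 = ((3.0 * np.exp(0.0002 * (V - EK + 100.0)) + np.exp(0.1 * (V - EK - 10.0)))
            / (1.0 + np.exp(-0.5 * (V - EK))))
    IK1 = G_K1 * np.sqrt(K_O / 5.4) * (a_k1 / (a_k1 + b_k1)) * (V - EK)

    # --- exchangers, pumps, backgrounds
    e_g = np.exp(GAMMA_NACA * V / rtof)
    e_g1 = np.exp((GAMMA_NACA - 1.0) * V / rtof)
    INaCa = (K_NACA * (e_g * Nai ** 3 * CA_O - e_g1 * NA_O ** 3 * Cai * ALPHA_NACA)
             / ((KM_NAI ** 3 + NA_O ** 3) * (KM_CA + CA_O)
                * (1.0 + K_SAT * e_g1)))
    INaK = (P_NAK * K_O * Nai
            / ((K_O + K_MK) * (Nai + K_MNA)
               * (1.0 + 0.1245 * np.exp(-0.1 * V / rtof) + 0.0353 * np.exp(-V / rtof))))
    IpCa = g_pca * Cai / (Cai + K_PCA)
    IpK = g_pk * (V - EK) / (1.0 + np.exp((25.0 - V) / 5.98))
    IbNa = G_BNA * (V - ENa)
    IbCa = G_BCA * (V - ECa)

    I_total = (INa + IK1 + Ito + IKr + IKs + ICaL + INaCa + INaK
               + IpCa + IpK + IbCa + IbNa)

    # --- calcium subsystem
    k_casr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_50 / CaSR) ** 2)
    k1 = K1_PRIME / k_casr
    k2 = K2_PRIME * k_casr
    O_rel = k1 * Cass * Cass * Rbar / (K3 + k1 * Cass * Cass)
    Irel = V_REL * O_rel * (CaSR - Cass)
    Ileak = V_LEAK * (CaSR - Cai)
    Iup = V_MAXUP / (1.0 + (K_UP / Cai) ** 2)
    Ixfer = V_XFER * (Cass - Cai)
    # R_bar relaxes as dR/dt = -k2*Cass*R + k4*(1-R): exact exponential form
    rbar_rate = k2 * Cass + K4
    rbar_inf = K4 / rbar_rate

    buf_c = 1.0 / (1.0 + BUF_C * K_BUF_C / ((Cai + K_BUF_C) ** 2))
    buf_sr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / ((CaSR + K_BUF_SR) ** 2))
    buf_ss = 1.0 / (1.0 + BUF_SS * K_BUF_SS / ((Cass + K_BUF_SS) ** 2))

    d_cai = buf_c * ((Ileak - Iup) * V_SR / V_C + Ixfer
                     - (IbCa + IpCa - 2.0 * INaCa) * CAPACITANCE / (2.0 * V_C * FARADAY))
    d_casr = buf_sr * (Iup - Irel - Ileak)
    d_cass = buf_ss * (-ICaL * CAPACITANCE / (2.0 * V_SS * FARADAY)
                       + Irel * V_SR / V_SS - Ixfer * V_C / V_SS)
    d_nai = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * CAPACITANCE / (V_C * FARADAY)
    d_ki = -(IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK - stim) * CAPACITANCE / (V_C * FARADAY)

    out[0] = -I_total + stim
    out[1] = xr1_inf; out[14] = tau_xr1
    out[2] = xr2_inf; out[15] = tau_xr2
    out[3] = xs_inf;  out[16] = tau_xs
    out[4] = m_inf;   out[17] = tau_m
    out[5] = h_inf;   out[18] = tau_h
    out[6] = j_inf;   out[19] = tau_j
    out[7] = d_inf;   out[20] = tau_d
    out[8] = f_inf;   out[21] = tau_f
    out[9] = f2_inf;  out[22] = tau_f2
    out[10] = fcass_inf; out[23] = tau_fcass
    out[11] = s_inf;  out[24] = tau_s
    out[12] = r_inf;  out[25] = tau_r
    out[13] = rbar_inf; out[26] = 1.0 / rbar_rate
    out[27] = d_cai
    out[28] = d_casr
    out[29] = d_cass
    out[30] = d_nai
    out[31] = d_ki


@njit(cache=True)
def _rl_step_kernel(Y, dt, stim, g_kr, g_ks, g_to, g_pca, g_pk,
                    tauf_scale, endo_s, active):
    """In-place Rush–Larsen / forward-Euler step for all nodes.

    Y: (n, 19) state array; per-node parameter arrays; ``active`` masks
    nodes carrying reaction dynamics (gel / excluded nodes are skipped).
    """
    n = Y.shape[0]
    scratch = np.empty(N_SCRATCH)
    for i in range(n):
        if not active[i]:
            continue
        y = Y[i]
        _eval_node(y, g_kr[i], g_ks[i], g_to[i], g_pca[i], g_pk[i],
                   tauf_scale[i], endo_s[i], stim[i], scratch)
        # gates: exact exponential relaxation toward x_inf
        for k in range(13):
            idx = 1 + k if k < 12 else 18
            x_inf = scratch[1 + k]
            tau = scratch[14 + k]
            # tau can underflow to 0 for wildly divergent voltages; the
            # clamp keeps the update defined so the caller's instability
            # guard can report the divergence instead of crashing
            if not tau > 1e-12:
                tau = 1e-12
            y[idx] = x_inf + (y[idx] - x_inf) * np.exp(-dt / tau)
        # V and concentrations: forward Euler
        y[0] += dt * scratch[0]
        y[13] += dt * scratch[27]
        y[14] += dt * scratch[28]
        y[15] += dt * scratch[29]
        y[16] += dt * scratch[30]
        y[17] += dt * scratch[31]


# Map the 13 RL scratch slots back onto state indices (gates 1..12, R_bar 18).
_RL_STATE_IDX = np.array(list(range(1, 13)) + [18], dtype=np.int64)


def _param_arrays(params: CellParameters, n: int = 1):
    full = np.full
    return (full(n, params.G_Kr), full(n, params.G_Ks), full(n, params.G_to),
            full(n, params.G_pCa), full(n, params.G_pK),
            full(n, params.tau_f_scale),
            np.full(n, params.endo_s_gate, dtype=np.bool_))


class IonicRates(NamedTuple):
    dVdt: float
    gate_inf: np.ndarray   # ordered as GATE_NAMES
    gate_tau: np.ndarray   # ordered as GATE_NAMES (ms)
    conc_rates: np.ndarray  # d/dt of (Ca_i, Ca_SR, Ca_ss, Na_i, K_i)


def ionic_rhs(state: CellState, params: CellParameters, stim: float = 0.0) -> IonicRates:
    """Evaluate the TP06 right-hand side at one state.

    Returns the total dV/dt (ionic sum plus stimulus), the gate kinetics
    in (x_inf, tau_x) form as used by Rush–Larsen, and the concentration
    rates.
    """
    state.validate()
    y = state.as_array()
    out = np.empty(N_SCRATCH)
    _eval_node(y, params.G_Kr, params.G_Ks, params.G_to, params.G_pCa,
               params.G_pK, params.tau_f_scale, params.endo_s_gate,
               float(stim), out)
    return IonicRates(float(out[0]), out[1:14].copy(), out[14:27].copy(),
                      out[27:32].copy())


def step_rush_larsen(state: CellState, params: CellParameters, dt: float,
                     stim: float = 0.0) -> CellState:
    """Advance one cell by one hybrid Rush–Larsen / forward-Euler step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.validate()
    Y = state.as_array()[None, :].copy()
    g = _param_arrays(params)
    stim_arr = np.array([float(stim)])
    active = np.ones(1, dtype=np.bool_)
    _rl_step_kernel(Y, float(dt), stim_arr, *g[:6], g[6], active)
    return CellState.from_array(Y[0])


def simulate_single_cell(params: CellParameters,
                         pacing: Sequence[StimulusSpec] = (),
                         dt: float = 0.1,
                         T: float = 1000.0,
                         record_every: float | None = None,
                         initial_state: CellState | None = None):
    """Integrate a single TP06 cell and return (t, V) arrays.

    ``pacing`` is a sequence of square stimuli; overlapping stimuli are
    summed (with a warning).  ``record_every`` decimates the stored
    trace (defaults to every step).  The full final state is available
    on the returned trace object.
    """
    import warnings

    if dt <= 0:
        raise ValueError("dt must be positive")
    if T <= 0:
        raise ValueError("T must be positive")
    for st in pacing:
        if st.onset < 0 or st.onset > T:
            raise ValueError("stimulus onset outside [0, T]")
    # overlap check
    iv = sorted((st.onset, st.onset + st.duration) for st in pacing)
    for (a0, a1), (b0, b1) in zip(iv, iv[1:]):
        if b0 < a1:
            warnings.warn("overlapping stimuli are summed", stacklevel=2)
            break

    n_steps = int(round(T / dt))
    stride = 1 if record_every is None else max(1, int(round(record_every / dt)))

    state0 = initial_state if initial_state is not None else default_initial_state()
    Y = state0.as_array()[None, :].copy()
    g = _param_arrays(params)
    active = np.ones(1, dtype=np.bool_)
    stim_arr = np.zeros(1)

    # precompute stimulus waveform on the step grid
    t_grid = np.arange(n_steps) * dt
    stim_wave = np.zeros(n_steps)
    for st in pacing:
        mask = (t_grid >= st.onset) & (t_grid < st.onset + st.duration)
        stim_wave[mask] += st.amplitude

    n_rec = n_steps // stride + 1
    t_out = np.empty(n_rec)
    v_out = np.empty(n_rec)
    t_out[0] = 0.0
    v_out[0] = Y[0, 0]
    k = 1
    for i in range(n_steps):
        stim_arr[0] = stim_wave[i]
        _rl_step_kernel(Y, dt, stim_arr, *g[:6], g[6], active)
        if (i + 1) % stride == 0 and k < n_rec:
            t_out[k] = (i + 1) * dt
            v_out[k] = Y[0, 0]
            k += 1
    trace = VoltageTrace(t=t_out[:k], V=v_out[:k],
                         final_state=CellState.from_array(Y[0]),
                         dt=dt, params=params)
    return trace


@dataclass
class VoltageTrace:
    """Single-cell (t, V) trace with provenance metadata."""

    t: np.ndarray
    V: np.ndarray
    final_state: CellState
    dt: float
    params: CellParameters

    def to_text(self, path) -> None:
        header = (f"# TP06 trace  cell_type={self.params.cell_type} "
                  f"mode={self.params.mode} dt={self.dt}\n# t_ms\tV_mV")
        np.savetxt(path, np.column_stack([self.t, self.V]),
                   delimiter="\t", header=header, comments="")


def default_initial_state() -> CellState:
    """The published TP06 initial (resting) state."""
    return CellState()
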