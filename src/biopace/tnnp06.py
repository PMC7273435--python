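"""ten Tusscher–Panfilov 2006 (TNNP06) human ventricular myocyte model.

The model describes the membrane potential of a single myocyte as

    dV/dt = -(I_ion + I_stim) / C_m,

where I_ion is the sum of twelve transmembrane currents
(I_Na, I_K1, I_to, I_Kr, I_Ks, I_CaL, I_NaK, I_NaCa, I_pK, I_pCa,
I_bCa, I_bNa), each controlled by a maximal conductance (or, for
I_CaL, a permeability-like scale).  Currents are expressed in pA/pF,
so the membrane capacitance cancels out of the voltage equation; the
whole-cell capacitance only enters the intracellular-concentration
bookkeeping.

Three transmural variants (endocardial, midmyocardial, epicardial)
differ in the transient-outward conductance g_to, the slow
delayed-rectifier conductance g_Ks and the I_to inactivation-gate
kinetics.

Numerics: Hodgkin–Huxley gates are advanced with the Rush–Larsen
exponential scheme (exact for a frozen voltage), the membrane
potential and the ionic concentrations with forward Euler.  The
production time step is 0.02 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from numba import njit

__all__ = [
    "CellParameters",
    "CellState",
    "CurrentSet",
    "CURRENT_NAMES",
    "STATE_NAMES",
    "CELL_TYPES",
    "RESTING_STATE",
    "compute_currents",
    "step",
    "BlowUpError",
]

# ---------------------------------------------------------------------------
# physical constants and fixed model parameters
# ---------------------------------------------------------------------------

R_GAS = 8314.472      # J / (kmol K)
TEMP = 310.0          # K
FARADAY = 96485.3415  # C / mol
RTONF = R_GAS * TEMP / FARADAY  # ~26.714 mV

K_O = 5.4     # mM extracellular K+
NA_O = 140.0  # mM extracellular Na+
CA_O = 2.0    # mM extracellular Ca2+

V_C = 0.016404      # cytoplasmic volume (units of the reference code)
V_SR = 0.001094     # sarcoplasmic-reticulum volume
V_SS = 0.00005468   # dyadic subspace volume

BUF_C, K_BUF_C = 0.2, 0.001     # cytoplasmic Ca buffer (mM)
BUF_SR, K_BUF_SR = 10.0, 0.3    # SR Ca buffer
BUF_SS, K_BUF_SS = 0.4, 0.00025  # subspace Ca buffer

V_MAX_UP, K_UP = 0.006375, 0.00025  # SERCA uptake
V_REL = 0.102     # mM/ms max RyR release
K1_PRIME = 0.15
K2_PRIME = 0.045
K3 = 0.060
K4 = 0.005
EC_SR = 1.5
MAX_SR, MIN_SR = 2.5, 1.0
V_LEAK = 0.00036
V_XFER = 0.0038

P_K_NA = 0.03  # Na+ permeability fraction of IKs

KM_NAI, KM_CA, K_SAT, GAMMA_NACA, ALPHA_NACA = 87.5, 1.38, 0.1, 0.35, 2.5
KM_K, KM_NA = 1.0, 40.0
K_P_CA = 0.0005

CELL_TYPES = ("endocardial", "midmyocardial", "epicardial")

# type-dependent defaults: (g_to, g_Ks)
_TYPE_DEFAULTS = {
    "endocardial": (0.073, 0.392),
    "midmyocardial": (0.294, 0.098),
    "epicardial": (0.294, 0.392),
}

# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------

# layout of the flat parameter vector consumed by the jitted kernels
_P_GNA, _P_GK1, _P_GCAL, _P_GTO, _P_GKR, _P_GKS, _P_GPK, _P_GPCA, \
    _P_GBNA, _P_GBCA, _P_KNACA, _P_PNAK, _P_ENDO, _P_CM = range(14)
N_PARAMS = 14


@dataclass(frozen=True)
class CellParameters:
    """Maximal conductances and scales of the TNNP06 model.

    Conductances are in nS/pF except ``g_CaL``, which is the
    permeability-like L-type scale of the TNNP06 formulation (kept in
    its native units), and the pump/exchanger scales ``p_NaK`` (pA/pF)
    and ``k_NaCa`` (pA/pF).  ``C_m`` is the whole-cell capacitance of
    the reference formulation, used only in concentration updates.
    """

    g_Na: float = 14.838
    g_K1: float = 5.405
    g_CaL: float = 3.98e-5
    g_to: float = 0.073
    g_Kr: float = 0.153
    g_Ks: float = 0.392
    g_pK: float = 0.0146
    g_pCa: float = 0.1238
    g_bNa: float = 0.00029
    g_bCa: float = 5.92e-4
    k_NaCa: float = 1000.0
    p_NaK: float = 2.724
    C_m: float = 0.185
    cell_type: str = "endocardial"

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(
                f"unknown cell_type {self.cell_type!r}; expected one of {CELL_TYPES}"
            )
        for f in fields(self):
            if f.name == "cell_type":
                continue
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v}")

    @classmethod
    def for_cell_type(cls, cell_type: str, **overrides) -> "CellParameters":
        """Defaults for a transmural cell type (g_to, g_Ks differ)."""
        if cell_type not in _TYPE_DEFAULTS:
            raise ValueError(
                f"unknown cell_type {cell_type!r}; expected one of {CELL_TYPES}"
            )
        g_to, g_Ks = _TYPE_DEFAULTS[cell_type]
        base = dict(g_to=g_to, g_Ks=g_Ks, cell_type=cell_type)
        base.update(overrides)
        return cls(**base)

    def replace(self, **overrides) -> "CellParameters":
        return replace(self, **overrides)

    def to_array(self) -> np.ndarray:
        p = np.empty(N_PARAMS)
        p[_P_GNA] = self.g_Na
        p[_P_GK1] = self.g_K1
        p[_P_GCAL] = self.g_CaL
        p[_P_GTO] = self.g_to
        p[_P_GKR] = self.g_Kr
        p[_P_GKS] = self.g_Ks
        p[_P_GPK] = self.g_pK
        p[_P_GPCA] = self.g_pCa
        p[_P_GBNA] = self.g_bNa
        p[_P_GBCA] = self.g_bCa
        p[_P_KNACA] = self.k_NaCa
        p[_P_PNAK] = self.p_NaK
        p[_P_ENDO] = 1.0 if self.cell_type == "endocardial" else 0.0
        p[_P_CM] = self.C_m
        return p


# ---------------------------------------------------------------------------
# state container
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "V", "m", "h", "j", "xr1", "xr2", "xs", "r", "s",
    "d", "f", "f2", "fcass", "R_prime",
    "Na_i", "K_i", "Ca_i", "Ca_ss", "Ca_sr",
)
N_STATE = len(STATE_NAMES)
_GATE_SLICE = slice(1, 14)  # m..R_prime are dimensionless in [0, 1]


@dataclass(frozen=True)
class CellState:
    """Full dynamical state of one myocyte.

    ``V`` in mV, gates dimensionless in [0, 1], concentrations in mM.
    ``R_prime`` is the closed-state occupancy of the SR release channel.
    """

    V: float = -86.2
    m: float = 0.0
    h: float = 0.75
    j: float = 0.75
    xr1: float = 0.0
    xr2: float = 1.0
    xs: float = 0.0
    r: float = 0.0
    s: float = 1.0
    d: float = 0.0
    f: float = 1.0
    f2: float = 1.0
    fcass: float = 1.0
    R_prime: float = 1.0
    Na_i: float = 7.67
    K_i: float = 138.3
    Ca_i: float = 7.0e-5
    Ca_ss: float = 7.0e-5
    Ca_sr: float = 1.3

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "CellState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_STATE,):
            raise ValueError(f"expected state vector of length {N_STATE}, got {arr.shape}")
        return cls(**dict(zip(STATE_NAMES, arr.tolist())))

    def validate(self) -> None:
        """Raise ValueError naming the first offending field, if any."""
        for name in STATE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite state variable {name} = {v}")
        for name in STATE_NAMES[_GATE_SLICE]:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"gate {name} = {v} outside [0, 1]")
        for name in ("Na_i", "K_i", "Ca_i", "Ca_ss", "Ca_sr"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"concentration {name} = {v} must be > 0")
        if not -120.0 <= self.V <= 80.0:
            raise ValueError(f"membrane potential V = {self.V} mV outside [-120, 80]")


#: published TNNP06 resting initial conditions
RESTING_STATE = CellState()

CURRENT_NAMES = (
    "I_Na", "I_K1", "I_to", "I_Kr", "I_Ks", "I_CaL",
    "I_NaK", "I_NaCa", "I_pK", "I_pCa", "I_bCa", "I_bNa",
)
N_CURRENTS = len(CURRENT_NAMES)


@dataclass(frozen=True)
class CurrentSet:
    """The twelve membrane currents (pA/pF) and their sum I_ion."""

    I_Na: float
    I_K1: float
    I_to: float
    I_Kr: float
    I_Ks: float
    I_CaL: float
    I_NaK: float
    I_NaCa: float
    I_pK: float
    I_pCa: float
    I_bCa: float
    I_bNa: float

    @property
    def I_ion(self) -> float:
        return (self.I_Na + self.I_K1 + self.I_to + self.I_Kr + self.I_Ks
                + self.I_CaL + self.I_NaK + self.I_NaCa + self.I_pK
                + self.I_pCa + self.I_bCa + self.I_bNa)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in CURRENT_NAMES])


# ---------------------------------------------------------------------------
# jitted kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _currents(s, p, out):
    """Evaluate the twelve membrane currents (pA/pF) at state ``s``.

    ``out`` receives the currents in the order of CURRENT_NAMES.
    """
    V = s[0]
    m, h, j = s[1], s[2], s[3]
    xr1, xr2, xs = s[4], s[5], s[6]
    r, sg = s[7], s[8]
    d, f, f2, fcass = s[9], s[10], s[11], s[12]
    Nai, Ki, Cai, Cass = s[14], s[15], s[16], s[17]

    Ek = RTONF * math.log(K_O / Ki)
    Ena = RTONF * math.log(NA_O / Nai)
    Eks = RTONF * math.log((K_O + P_K_NA * NA_O) / (Ki + P_K_NA * Nai))
    Eca = 0.5 * RTONF * math.log(CA_O / Cai)

    # fast Na+
    INa = p[_P_GNA] * m * m * m * h * j * (V - Ena)

    # L-type Ca2+ (GHK-like driving term; de-singularised at V = 15 mV)
    z = 2.0 * (V - 15.0) / RTONF
    if abs(V - 15.0) < 1e-6:
        ICaL = p[_P_GCAL] * d * f * f2 * fcass * 2.0 * FARADAY * (
            0.25 * Cass - CA_O)
    else:
        ez = math.exp(z)
        ICaL = (p[_P_GCAL] * d * f * f2 * fcass * 4.0 * (V - 15.0)
                * (FARADAY / RTONF) * (0.25 * Cass * ez - CA_O) / (ez - 1.0))

    # transient outward
    Ito = p[_P_GTO] * r * sg * (V - Ek)

    # rapid delayed rectifier
    IKr = p[_P_GKR] * math.sqrt(K_O / 5.4) * xr1 * xr2 * (V - Ek)

    # slow delayed rectifier
    IKs = p[_P_GKS] * xs * xs * (V - Eks)

    # inward rectifier with its voltage-dependent rectification factor
    ak1 = 0.1 / (1.0 + math.exp(0.06 * (V - Ek - 200.0)))
    bk1 = (3.0 * math.exp(0.0002 * (V - Ek + 100.0))
           + math.exp(0.1 * (V - Ek - 10.0))) / (1.0 + math.exp(-0.5 * (V - Ek)))
    IK1 = p[_P_GK1] * math.sqrt(K_O / 5.4) * ak1 / (ak1 + bk1) * (V - Ek)

    # Na+/Ca2+ exchanger
    evf = math.exp(GAMMA_NACA * V / RTONF)
    evf1 = math.exp((GAMMA_NACA - 1.0) * V / RTONF)
    INaCa = (p[_P_KNACA]
             * (evf * Nai ** 3 * CA_O - evf1 * NA_O ** 3 * Cai * ALPHA_NACA)
             / ((KM_NAI ** 3 + NA_O ** 3) * (KM_CA + CA_O)
                * (1.0 + K_SAT * evf1)))

    # Na+/K+ pump
    INaK = (p[_P_PNAK] * (K_O / (K_O + KM_K)) * (Nai / (Nai + KM_NA))
            / (1.0 + 0.1245 * math.exp(-0.1 * V / RTONF)
               + 0.0353 * math.exp(-V / RTONF)))

    # plateau and background currents
    IpCa = p[_P_GPCA] * Cai / (K_P_CA + Cai)
    IpK = p[_P_GPK] * (V - Ek) / (1.0 + math.exp((25.0 - V) / 5.98))
    IbNa = p[_P_GBNA] * (V - Ena)
    IbCa = p[_P_GBCA] * (V - Eca)

    out[0] = INa
    out[1] = IK1
    out[2] = Ito
    out[3] = IKr
    out[4] = IKs
    out[5] = ICaL
    out[6] = INaK
    out[7] = INaCa
    out[8] = IpK
    out[9] = IpCa
    out[10] = IbCa
    out[11] = IbNa


@njit(cache=True, fastmath=True)
def _step_cell(s, p, dt, istim, diff, cur):
    """Advance one cell by dt (ms), in place.

    ``diff`` is an external dV/dt contribution in mV/ms (the diffusion
    term of the monodomain equation; 0 for an isolated cell).  ``cur``
    is a scratch array of length 12 receiving the currents used.
    """
    V = s[0]
    _currents(s, p, cur)
    INa, IK1, Ito, IKr = cur[0], cur[1], cur[2], cur[3]
    IKs, ICaL, INaK, INaCa = cur[4], cur[5], cur[6], cur[7]
    IpK, IpCa, IbCa, IbNa = cur[8], cur[9], cur[10], cur[11]
    Iion = (INa + IK1 + Ito + IKr + IKs + ICaL + INaK + INaCa
            + IpK + IpCa + IbCa + IbNa)

    Cm = p[_P_CM]
    Nai, Ki, Cai, Cass, Casr = s[14], s[15], s[16], s[17], s[18]

    # --- SR calcium fluxes ----------------------------------------------
    kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / Casr) ** 2)
    k1 = K1_PRIME / kcasr
    k2 = K2_PRIME * kcasr
    Rp = s[13]
    # release-channel closed state: linear ODE, exact exponential update
    rp_rate = k2 * Cass + K4
    rp_inf = K4 / rp_rate
    s[13] = rp_inf + (Rp - rp_inf) * math.exp(-dt * rp_rate)
    OO = k1 * Cass * Cass * Rp / (K3 + k1 * Cass * Cass)
    Irel = V_REL * OO * (Casr - Cass)
    Ileak = V_LEAK * (Casr - Cai)
    Iup = V_MAX_UP / (1.0 + (K_UP / Cai) ** 2)
    Ixfer = V_XFER * (Cass - Cai)

    # --- concentrations (forward Euler, rapid-buffering factors) --------
    bufc = 1.0 / (1.0 + BUF_C * K_BUF_C / ((Cai + K_BUF_C) ** 2))
    bufsr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / ((Casr + K_BUF_SR) ** 2))
    bufss = 1.0 / (1.0 + BUF_SS * K_BUF_SS / ((Cass + K_BUF_SS) ** 2))

    dCai = bufc * ((Ileak - Iup) * V_SR / V_C + Ixfer
                   - (IbCa + IpCa - 2.0 * INaCa) * Cm / (2.0 * V_C * FARADAY))
    dCasr = bufsr * (Iup - Irel - Ileak)
    dCass = bufss * (-Ixfer * V_C / V_SS + Irel * V_SR / V_SS
                     - ICaL * Cm / (2.0 * V_SS * FARADAY))
    dNai = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * Cm / (V_C * FARADAY)
    dKi = -(IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK + istim) * Cm / (V_C * FARADAY)

    s[16] = Cai + dt * dCai
    s[18] = Casr + dt * dCasr
    s[17] = Cass + dt * dCass
    s[14] = Nai + dt * dNai
    s[15] = Ki + dt * dKi

    # --- Hodgkin-Huxley gates (Rush-Larsen) -----------------------------
    # INa gates
    m_inf = 1.0 / (1.0 + math.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + math.exp((V + 35.0) / 5.0)) \
        + 0.1 / (1.0 + math.exp((V - 50.0) / 200.0))
    tau_m = am * bm

    h_inf = 1.0 / (1.0 + math.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
    tau_h = 1.0 / (ah + bh)

    j_inf = h_inf
    if V >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        aj = ((-2.5428e4 * math.exp(0.2444 * V)
               - 6.948e-6 * math.exp(-0.04391 * V)) * (V + 37.78)
              / (1.0 + math.exp(0.311 * (V + 79.23))))
        bj = 0.02424 * math.exp(-0.01052 * V) \
            / (1.0 + math.exp(-0.1378 * (V + 40.14)))
    tau_j = 1.0 / (aj + bj)

    # IKr gates
    xr1_inf = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
    tau_xr1 = axr1 * bxr1

    xr2_inf = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
    tau_xr2 = axr2 * bxr2

    # IKs gate
    xs_inf = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((V - 35.0) / 15.0))
    tau_xs = axs * bxs + 80.0

    # Ito gates; the s-gate kinetics distinguish endocardial cells
    r_inf = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
    tau_r = 9.5 * math.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8
    if p[_P_ENDO] > 0.5:
        s_inf = 1.0 / (1.0 + math.exp((V + 28.0) / 5.0))
        tau_s = 1000.0 * math.exp(-(V + 67.0) ** 2 / 1000.0) + 8.0
    else:
        s_inf = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
        tau_s = (85.0 * math.exp(-(V + 45.0) ** 2 / 320.0)
                 + 5.0 / (1.0 + math.exp((V - 20.0) / 5.0)) + 3.0)

    # ICaL gates
    d_inf = 1.0 / (1.0 + math.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
    tau_d = ad * bd + gd

    f_inf = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
    af = 1102.5 * math.exp(-((V + 27.0) ** 2) / 225.0)
    bf = 200.0 / (1.0 + math.exp((13.0 - V) / 10.0))
    cf = 180.0 / (1.0 + math.exp((V + 30.0) / 10.0)) + 20.0
    tau_f = af + bf + cf

    f2_inf = 0.67 / (1.0 + math.exp((V + 35.0) / 7.0)) + 0.33
    af2 = 562.0 * math.exp(-((V + 27.0) ** 2) / 240.0)
    bf2 = 31.0 / (1.0 + math.exp((25.0 - V) / 10.0))
    cf2 = 80.0 / (1.0 + math.exp((V + 30.0) / 10.0))
    tau_f2 = af2 + bf2 + cf2

    fcass_inf = 0.6 / (1.0 + (Cass / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (Cass / 0.05) ** 2) + 2.0

    s[1] = m_inf + (s[1] - m_inf) * math.exp(-dt / tau_m)
    s[2] = h_inf + (s[2] - h_inf) * math.exp(-dt / tau_h)
    s[3] = j_inf + (s[3] - j_inf) * math.exp(-dt / tau_j)
    s[4] = xr1_inf + (s[4] - xr1_inf) * math.exp(-dt / tau_xr1)
    s[5] = xr2_inf + (s[5] - xr2_inf) * math.exp(-dt / tau_xr2)
    s[6] = xs_inf + (s[6] - xs_inf) * math.exp(-dt / tau_xs)
    s[7] = r_inf + (s[7] - r_inf) * math.exp(-dt / tau_r)
    s[8] = s_inf + (s[8] - s_inf) * math.exp(-dt / tau_s)
    s[9] = d_inf + (s[9] - d_inf) * math.exp(-dt / tau_d)
    s[10] = f_inf + (s[10] - f_inf) * math.exp(-dt / tau_f)
    s[11] = f2_inf + (s[11] - f2_inf) * math.exp(-dt / tau_f2)
    s[12] = fcass_inf + (s[12] - fcass_inf) * math.exp(-dt / tau_fcass)

    # --- membrane potential ---------------------------------------------
    s[0] = V + dt * (-(Iion + istim) + diff)


@njit(cache=True)
def _state_ok(s):
    """Cheap sanity check used inside long runs."""
    if not (-120.0 <= s[0] <= 80.0):
        return False
    if s[14] <= 0.0 or s[15] <= 0.0 or s[16] <= 0.0 or s[17] <= 0.0 or s[18] <= 0.0:
        return False
    return math.isfinite(s[0])


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


class BlowUpError(RuntimeError):
    """Raised when the integration leaves the physiological state space."""

    def __init__(self, t_ms: float, detail: str = ""):
        self.t_ms = t_ms
        msg = f"integration blew up at t = {t_ms:.2f} ms"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


def compute_currents(state: CellState, params: CellParameters) -> CurrentSet:
    """All twelve membrane currents (pA/pF) at the given state.

    Each current scales linearly with its maximal conductance at fixed
    state.  Raises ValueError (naming the field) for non-finite state
    values.
    """
    for name in STATE_NAMES:
        if not np.isfinite(getattr(state, name)):
            raise ValueError(
                f"non-finite state variable {name} = {getattr(state, name)}")
    out = np.empty(N_CURRENTS)
    _currents(state.to_array(), params.to_array(), out)
    return CurrentSet(**dict(zip(CURRENT_NAMES, out.tolist())))


def step(state: CellState, params: CellParameters, dt: float,
         I_stim: float = 0.0) -> CellState:
    """Advance the cell by one time step of ``dt`` ms.

    Forward-Euler update of V and concentrations, Rush–Larsen update
    of the gates.  ``I_stim`` in pA/pF (0 throughout the pacemaker
    experiments).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    s = state.to_array()
    cur = np.empty(N_CURRENTS)
    _step_cell(s, params.to_array(), dt, I_stim, 0.0, cur)
    if not _state_ok(s):
        raise BlowUpError(dt, f"V = {s[0]:.3g} mV")
    return CellState.from_array(s)
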