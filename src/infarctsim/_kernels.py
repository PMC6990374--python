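"""Numba kernels for the ten Tusscher-Panfilov 2006 membrane model and the
explicit monodomain update.

The voltage-dependent rate expressions are tabulated on a fine Vm grid once per
time step size (Rush-Larsen factors ``exp(-dt/tau)`` are baked into the table),
so the inner node loop performs only linear interpolation and arithmetic.  All
kernels are single-threaded; the grading/CI target is one CPU.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# TT2006 constants (endocardial parameter set)
# ---------------------------------------------------------------------------

R_GAS = 8314.472      # mJ mol^-1 K^-1
TEMP = 310.0          # K
FARADAY = 96485.3415  # C mol^-1
RTF = R_GAS * TEMP / FARADAY

CAP = 0.185           # cell capacitance used in concentration bookkeeping (uF)
V_C = 0.016404        # cytoplasmic volume (um^3 scale units)
V_SR = 0.001094
V_SS = 0.00005468

K_O = 5.4             # mM
NA_O = 140.0
CA_O = 2.0
P_KNA = 0.03

G_NA = 14.838         # nS/pF
G_K1 = 5.405
G_TO_ENDO = 0.073
G_KR = 0.153
G_KS_ENDO = 0.392
G_CAL = 0.0000398
G_B_NA = 0.00029
G_B_CA = 0.000592
G_P_CA = 0.1238
K_P_CA = 0.0005
G_P_K = 0.0146

P_NAK = 2.724
K_MK = 1.0
K_MNA = 40.0

K_NACA = 1000.0
GAMMA_NACA = 0.35
K_MNAI = 87.5
K_MCA = 1.38
K_SAT = 0.1
ALPHA_NACA = 2.5

V_REL = 0.102
K1_PRIME = 0.15
K2_PRIME = 0.045
K3_REL = 0.060
K4_REL = 0.005
EC_SR = 1.5
MAX_SR = 2.5
MIN_SR = 1.0
V_LEAK = 0.00036
V_MAXUP = 0.006375
K_UP = 0.00025
V_XFER = 0.0038

BUF_C = 0.2
K_BUF_C = 0.001
BUF_SR = 10.0
K_BUF_SR = 0.3
BUF_SS = 0.4
K_BUF_SS = 0.00025

SQRT_KO = math.sqrt(K_O / 5.4)
CONC_FACT = CAP / (V_C * FARADAY)          # converts pA/pF -> mM/ms (cytosol)
NACA_DEN = (K_MNAI ** 3 + NA_O ** 3) * (K_MCA + CA_O)

# State vector layout (19 variables; index 0 is Vm in mV)
STATE_NAMES = (
    "vm", "m", "h", "j", "d", "f", "f2", "fcass", "r", "s",
    "xr1", "xr2", "xs", "nai", "ki", "cai", "casr", "cass", "rbar",
)
N_STATE = len(STATE_NAMES)

# Published resting initial conditions (endocardial variant)
INITIAL_STATE = np.array([
    -86.2,      # vm
    0.0,        # m
    0.75,       # h
    0.75,       # j
    0.0,        # d
    1.0,        # f
    1.0,        # f2
    1.0,        # fcass
    0.0,        # r
    1.0,        # s
    0.0,        # xr1
    1.0,        # xr2
    0.0,        # xs
    7.67,       # nai (mM)
    138.3,      # ki (mM)
    0.00007,    # cai (mM)
    1.3,        # casr (mM)
    0.00007,    # cass (mM)
    1.0,        # rbar
], dtype=np.float64)

# ---------------------------------------------------------------------------
# Rate tables
# ---------------------------------------------------------------------------

TAB_VMIN = -120.0
TAB_VMAX = 80.0
TAB_DV = 0.05
N_TAB_COLS = 28

# column indices
(C_MINF, C_RLM, C_HINF, C_RLH, C_JINF, C_RLJ, C_DINF, C_RLD, C_FINF, C_RLF,
 C_F2INF, C_RLF2, C_SINF, C_RLS, C_RINF, C_RLR, C_XR1INF, C_RLXR1, C_XR2INF,
 C_RLXR2, C_XSINF, C_RLXS, C_ICALA, C_E2V, C_NACA1, C_NACA2, C_INAKF,
 C_IPKF) = range(N_TAB_COLS)

XK1_UMIN = -150.0
XK1_UMAX = 150.0
XK1_DU = 0.05


def build_rate_tables(dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Tabulate voltage-dependent quantities for time step ``dt`` (ms).

    Returns ``(tab, xk1)`` where ``tab`` has one row per Vm grid point and
    ``xk1`` tabulates the inward-rectifier open probability on a
    ``Vm - E_K`` grid.
    """
    v = np.arange(TAB_VMIN, TAB_VMAX + TAB_DV / 2, TAB_DV)
    tab = np.empty((v.size, N_TAB_COLS), dtype=np.float64)

    def rl(tau):
        return np.exp(-dt / tau)

    # INa gates
    m_inf = 1.0 / (1.0 + np.exp((-56.86 - v) / 9.03)) ** 2
    a_m = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
    b_m = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((v - 50.0) / 200.0))
    tau_m = a_m * b_m
    h_inf = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
    lo = v < -40.0
    a_h = np.where(lo, 0.057 * np.exp(-(v + 80.0) / 6.8), 0.0)
    b_h = np.where(lo, 2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v),
                   0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))))
    tau_h = 1.0 / (a_h + b_h)
    j_inf = h_inf
    with np.errstate(over="ignore"):
        a_j = np.where(
            lo,
            (-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
            * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))),
            0.0,
        )
    b_j = np.where(lo,
                   0.02424 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))),
                   0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))))
    tau_j = 1.0 / (a_j + b_j)

    # ICaL gates
    d_inf = 1.0 / (1.0 + np.exp((-8.0 - v) / 7.5))
    a_d = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
    b_d = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
    g_d = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    tau_d = a_d * b_d + g_d
    f_inf = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
    tau_f = (1102.5 * np.exp(-((v + 27.0) ** 2) / 225.0)
             + 200.0 / (1.0 + np.exp((13.0 - v) / 10.0))
             + 180.0 / (1.0 + np.exp((v + 30.0) / 10.0)) + 20.0)
    f2_inf = 0.67 / (1.0 + np.exp((v + 35.0) / 7.0)) + 0.33
    tau_f2 = (562.0 * np.exp(-((v + 27.0) ** 2) / 240.0)
              + 31.0 / (1.0 + np.exp((25.0 - v) / 10.0))
              + 80.0 / (1.0 + np.exp((v + 30.0) / 10.0)))

    # Ito gates (endocardial s kinetics)
    s_inf = 1.0 / (1.0 + np.exp((v + 28.0) / 5.0))
    tau_s = 1000.0 * np.exp(-((v + 67.0) ** 2) / 1000.0) + 8.0
    r_inf = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
    tau_r = 9.5 * np.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8

    # IKr gates
    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - v) / 7.0))
    a_xr1 = 450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))
    b_xr1 = 6.0 / (1.0 + np.exp((v + 30.0) / 11.5))
    tau_xr1 = a_xr1 * b_xr1
    xr2_inf = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
    a_xr2 = 3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
    b_xr2 = 1.12 / (1.0 + np.exp((v - 60.0) / 20.0))
    tau_xr2 = a_xr2 * b_xr2

    # IKs gate
    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - v) / 14.0))
    a_xs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - v) / 6.0))
    b_xs = 1.0 / (1.0 + np.exp((v - 35.0) / 15.0))
    tau_xs = a_xs * b_xs + 80.0

    # ICaL driving-force factor: 4 (V-15) F^2/(RT) / (exp(2(V-15)F/RT) - 1)
    z = 2.0 * (v - 15.0) / RTF
    e2v = np.exp(z)
    ical_a = np.empty_like(v)
    small = np.abs(z) < 1e-8
    ical_a[~small] = (4.0 * (v[~small] - 15.0) * FARADAY / RTF) / (e2v[~small] - 1.0)
    ical_a[small] = 2.0 * FARADAY  # limit of 4(V-15)(F/RTF)/(e^z - 1), z = 2(V-15)/RTF

    naca1 = np.exp(GAMMA_NACA * v / RTF)
    naca2 = np.exp((GAMMA_NACA - 1.0) * v / RTF)
    inak_f = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v / RTF) + 0.0353 * np.exp(-v / RTF))
    ipk_f = 1.0 / (1.0 + np.exp((25.0 - v) / 5.98))

    cols = [
        (C_MINF, m_inf), (C_RLM, rl(tau_m)), (C_HINF, h_inf), (C_RLH, rl(tau_h)),
        (C_JINF, j_inf), (C_RLJ, rl(tau_j)), (C_DINF, d_inf), (C_RLD, rl(tau_d)),
        (C_FINF, f_inf), (C_RLF, rl(tau_f)), (C_F2INF, f2_inf), (C_RLF2, rl(tau_f2)),
        (C_SINF, s_inf), (C_RLS, rl(tau_s)), (C_RINF, r_inf), (C_RLR, rl(tau_r)),
        (C_XR1INF, xr1_inf), (C_RLXR1, rl(tau_xr1)), (C_XR2INF, xr2_inf),
        (C_RLXR2, rl(tau_xr2)), (C_XSINF, xs_inf), (C_RLXS, rl(tau_xs)),
        (C_ICALA, ical_a), (C_E2V, e2v), (C_NACA1, naca1), (C_NACA2, naca2),
        (C_INAKF, inak_f), (C_IPKF, ipk_f),
    ]
    for ci, arr in cols:
        tab[:, ci] = arr

    u = np.arange(XK1_UMIN, XK1_UMAX + XK1_DU / 2, XK1_DU)
    a_k1 = 0.1 / (1.0 + np.exp(0.06 * (u - 200.0)))
    b_k1 = (3.0 * np.exp(0.0002 * (u + 100.0)) + np.exp(0.1 * (u - 10.0))) / (
        1.0 + np.exp(-0.5 * u))
    xk1 = (a_k1 / (a_k1 + b_k1)).astype(np.float64)
    return np.ascontiguousarray(tab), np.ascontiguousarray(xk1)


_TABLE_CACHE: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def get_rate_tables(dt: float) -> tuple[np.ndarray, np.ndarray]:
    key = round(float(dt), 9)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = build_rate_tables(key)
    return _TABLE_CACHE[key]


# ---------------------------------------------------------------------------
# Cell update (inlined into both kernels below)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, inline="always")
def _cell_update(S, i, gna, gkr, gks, istim, diff, dt, tab, xk1):
    """Advance state row ``i`` of ``S`` by ``dt`` ms.

    ``istim`` is the stimulus in pA/pF (already divided by the tissue membrane
    capacitance); ``diff`` the diffusive dVm/dt contribution in mV/ms.
    Returns the updated Vm.
    """
    v = S[i, 0]
    # table interpolation at v
    x = (v - TAB_VMIN) / TAB_DV
    if x < 0.0:
        x = 0.0
    nmax = tab.shape[0] - 1
    if x > nmax - 1e-9:
        x = nmax - 1e-9
    ix = int(x)
    fr = x - ix
    i1 = ix + 1

    m = S[i, 1]
    h = S[i, 2]
    j = S[i, 3]
    d = S[i, 4]
    f = S[i, 5]
    f2 = S[i, 6]
    fcass = S[i, 7]
    rg = S[i, 8]
    sg = S[i, 9]
    xr1 = S[i, 10]
    xr2 = S[i, 11]
    xs = S[i, 12]
    nai = S[i, 13]
    ki = S[i, 14]
    cai = S[i, 15]
    casr = S[i, 16]
    cass = S[i, 17]
    rbar = S[i, 18]

    ena = RTF * math.log(NA_O / nai)
    ek = RTF * math.log(K_O / ki)
    eks = RTF * math.log((K_O + P_KNA * NA_O) / (ki + P_KNA * nai))
    eca = 0.5 * RTF * math.log(CA_O / cai)

    ina = gna * G_NA * m * m * m * h * j * (v - ena)
    ical_a = tab[ix, C_ICALA] + fr * (tab[i1, C_ICALA] - tab[ix, C_ICALA])
    e2v = tab[ix, C_E2V] + fr * (tab[i1, C_E2V] - tab[ix, C_E2V])
    ical = G_CAL * d * f * f2 * fcass * ical_a * (0.25 * cass * e2v - CA_O)
    ito = G_TO_ENDO * rg * sg * (v - ek)
    ikr = gkr * G_KR * SQRT_KO * xr1 * xr2 * (v - ek)
    iks = gks * G_KS_ENDO * xs * xs * (v - eks)

    u = v - ek
    xu = (u - XK1_UMIN) / XK1_DU
    if xu < 0.0:
        xu = 0.0
    numax = xk1.shape[0] - 1
    if xu > numax - 1e-9:
        xu = numax - 1e-9
    iu = int(xu)
    fu = xu - iu
    xk1inf = xk1[iu] + fu * (xk1[iu + 1] - xk1[iu])
    ik1 = G_K1 * SQRT_KO * xk1inf * u

    naca1 = tab[ix, C_NACA1] + fr * (tab[i1, C_NACA1] - tab[ix, C_NACA1])
    naca2 = tab[ix, C_NACA2] + fr * (tab[i1, C_NACA2] - tab[ix, C_NACA2])
    inaca = K_NACA * (naca1 * nai * nai * nai * CA_O
                      - naca2 * NA_O * NA_O * NA_O * cai * ALPHA_NACA) / (
        NACA_DEN * (1.0 + K_SAT * naca2))
    inakf = tab[ix, C_INAKF] + fr * (tab[i1, C_INAKF] - tab[ix, C_INAKF])
    inak = P_NAK * K_O * nai / ((K_O + K_MK) * (nai + K_MNA)) * inakf
    ipca = G_P_CA * cai / (cai + K_P_CA)
    ipkf = tab[ix, C_IPKF] + fr * (tab[i1, C_IPKF] - tab[ix, C_IPKF])
    ipk = G_P_K * ipkf * (v - ek)
    ibna = G_B_NA * (v - ena)
    ibca = G_B_CA * (v - eca)

    # SR calcium release / uptake
    kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / casr) * (EC_SR / casr))
    k1 = K1_PRIME / kcasr
    k2 = K2_PRIME * kcasr
    o_rel = k1 * cass * cass * rbar / (K3_REL + k1 * cass * cass)
    irel = V_REL * o_rel * (casr - cass)
    ileak = V_LEAK * (casr - cai)
    iup = V_MAXUP / (1.0 + (K_UP / cai) * (K_UP / cai))
    ixfer = V_XFER * (cass - cai)

    # gates (Rush-Larsen): x <- x_inf - (x_inf - x) * exp(-dt/tau)
    g0 = tab[ix, C_MINF] + fr * (tab[i1, C_MINF] - tab[ix, C_MINF])
    S[i, 1] = g0 - (g0 - m) * (tab[ix, C_RLM] + fr * (tab[i1, C_RLM] - tab[ix, C_RLM]))
    g0 = tab[ix, C_HINF] + fr * (tab[i1, C_HINF] - tab[ix, C_HINF])
    S[i, 2] = g0 - (g0 - h) * (tab[ix, C_RLH] + fr * (tab[i1, C_RLH] - tab[ix, C_RLH]))
    g0 = tab[ix, C_JINF] + fr * (tab[i1, C_JINF] - tab[ix, C_JINF])
    S[i, 3] = g0 - (g0 - j) * (tab[ix, C_RLJ] + fr * (tab[i1, C_RLJ] - tab[ix, C_RLJ]))
    g0 = tab[ix, C_DINF] + fr * (tab[i1, C_DINF] - tab[ix, C_DINF])
    S[i, 4] = g0 - (g0 - d) * (tab[ix, C_RLD] + fr * (tab[i1, C_RLD] - tab[ix, C_RLD]))
    g0 = tab[ix, C_FINF] + fr * (tab[i1, C_FINF] - tab[ix, C_FINF])
    S[i, 5] = g0 - (g0 - f) * (tab[ix, C_RLF] + fr * (tab[i1, C_RLF] - tab[ix, C_RLF]))
    g0 = tab[ix, C_F2INF] + fr * (tab[i1, C_F2INF] - tab[ix, C_F2INF])
    S[i, 6] = g0 - (g0 - f2) * (tab[ix, C_RLF2] + fr * (tab[i1, C_RLF2] - tab[ix, C_RLF2]))
    g0 = tab[ix, C_RINF] + fr * (tab[i1, C_RINF] - tab[ix, C_RINF])
    S[i, 8] = g0 - (g0 - rg) * (tab[ix, C_RLR] + fr * (tab[i1, C_RLR] - tab[ix, C_RLR]))
    g0 = tab[ix, C_SINF] + fr * (tab[i1, C_SINF] - tab[ix, C_SINF])
    S[i, 9] = g0 - (g0 - sg) * (tab[ix, C_RLS] + fr * (tab[i1, C_RLS] - tab[ix, C_RLS]))
    g0 = tab[ix, C_XR1INF] + fr * (tab[i1, C_XR1INF] - tab[ix, C_XR1INF])
    S[i, 10] = g0 - (g0 - xr1) * (tab[ix, C_RLXR1] + fr * (tab[i1, C_RLXR1] - tab[ix, C_RLXR1]))
    g0 = tab[ix, C_XR2INF] + fr * (tab[i1, C_XR2INF] - tab[ix, C_XR2INF])
    S[i, 11] = g0 - (g0 - xr2) * (tab[ix, C_RLXR2] + fr * (tab[i1, C_RLXR2] - tab[ix, C_RLXR2]))
    g0 = tab[ix, C_XSINF] + fr * (tab[i1, C_XSINF] - tab[ix, C_XSINF])
    S[i, 12] = g0 - (g0 - xs) * (tab[ix, C_RLXS] + fr * (tab[i1, C_RLXS] - tab[ix, C_RLXS]))

    # fCass: Ca-dependent gate, forward Euler (tau >= 2 ms)
    csn = (cass / 0.05) * (cass / 0.05)
    fcass_inf = 0.6 / (1.0 + csn) + 0.4
    tau_fcass = 80.0 / (1.0 + csn) + 2.0
    S[i, 7] = fcass + dt * (fcass_inf - fcass) / tau_fcass

    # ryanodine receptor adaptation
    S[i, 18] = rbar + dt * (-k2 * cass * rbar + K4_REL * (1.0 - rbar))

    # buffered calcium updates
    bufc = 1.0 / (1.0 + BUF_C * K_BUF_C / ((cai + K_BUF_C) * (cai + K_BUF_C)))
    bufsr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / ((casr + K_BUF_SR) * (casr + K_BUF_SR)))
    bufss = 1.0 / (1.0 + BUF_SS * K_BUF_SS / ((cass + K_BUF_SS) * (cass + K_BUF_SS)))

    dcai = bufc * ((ileak - iup) * V_SR / V_C + ixfer
                   - (ibca + ipca - 2.0 * inaca) * CONC_FACT / 2.0)
    dcasr = bufsr * (iup - irel - ileak)
    dcass = bufss * (-ical * CAP / (2.0 * V_SS * FARADAY)
                     + irel * V_SR / V_SS - ixfer * V_C / V_SS)
    dnai = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * CONC_FACT
    dki = -(ik1 + ito + ikr + iks - 2.0 * inak + ipk - istim) * CONC_FACT

    S[i, 13] = nai + dt * dnai
    S[i, 14] = ki + dt * dki
    S[i, 15] = cai + dt * dcai
    S[i, 16] = casr + dt * dcasr
    S[i, 17] = cass + dt * dcass

    iion = (ina + ik1 + ito + ikr + iks + ical + inaca + inak
            + ipca + ipk + ibna + ibca)
    vnew = v + dt * (diff - iion + istim)
    S[i, 0] = vnew
    return vnew


@njit(cache=True, fastmath=True)
def step_tissue(S, nbr, wgt, gna, gkr, gks, istim, dt, tab, xk1):
    """One explicit monodomain step over all active nodes.

    ``S``      : (n, 19) state array (column 0 = Vm, mV)
    ``nbr``    : (n, 4) int32 neighbor indices into the active-node list, -1 = none
    ``wgt``    : (n, 4) edge weights D_edge/h^2 (1/ms)
    ``gna/gkr/gks`` : per-node conductance multipliers
    ``istim``  : per-node stimulus in pA/pF (zero outside the electrode)
    """
    n = S.shape[0]
    vold = np.empty(n, dtype=np.float64)
    for i in range(n):
        vold[i] = S[i, 0]
    vmax = -1.0e30
    for i in range(n):
        acc = 0.0
        vi = vold[i]
        for k in range(4):
            jn = nbr[i, k]
            if jn >= 0:
                acc += wgt[i, k] * (vold[jn] - vi)
        vnew = _cell_update(S, i, gna[i], gkr[i], gks[i], istim[i], acc, dt,
                            tab, xk1)
        if vnew > vmax:
            vmax = vnew
    return vmax


@njit(cache=True, fastmath=True)
def pace_single(S, gna, gkr, gks, dt, bcl, n_beats, stim_amp, stim_dur,
                vm_out, rec_stride, tab, xk1):
    """Pace one cell for ``n_beats`` cycles of length ``bcl`` ms.

    ``stim_amp`` in pA/pF, applied for ``stim_dur`` ms at each cycle start.
    ``vm_out`` receives Vm every ``rec_stride`` steps (pass a length-0 array to
    skip recording).  Returns the number of samples written.
    """
    steps_per_beat = int(round(bcl / dt))
    stim_steps = int(round(stim_dur / dt))
    nrec = vm_out.shape[0]
    w = 0
    step = 0
    for _b in range(n_beats):
        for k in range(steps_per_beat):
            istim = stim_amp if k < stim_steps else 0.0
            _cell_update(S, 0, gna, gkr, gks, istim, 0.0, dt, tab, xk1)
            if nrec > 0 and step % rec_stride == 0 and w < nrec:
                vm_out[w] = S[0, 0]
                w += 1
            step += 1
    return w


@njit(cache=True, fastmath=True)
def run_single(S, gna, gkr, gks, dt, n_steps, stim_start, stim_dur, stim_amp,
               vm_out, rec_stride, tab, xk1):
    """Free-run one cell for ``n_steps`` with a single stimulus pulse."""
    start = int(round(stim_start / dt))
    stop = start + int(round(stim_dur / dt))
    w = 0
    nrec = vm_out.shape[0]
    for k in range(n_steps):
        istim = stim_amp if (start <= k < stop) else 0.0
        _cell_update(S, 0, gna, gkr, gks, istim, 0.0, dt, tab, xk1)
        if nrec > 0 and k % rec_stride == 0 and w < nrec:
            vm_out[w] = S[0, 0]
            w += 1
    return w
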