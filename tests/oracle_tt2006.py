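"""Independent reference integration of the ten Tusscher-Panfilov 2006
endocardial ventricular myocyte model.

This is a direct, unoptimized transcription of the published equations as a
plain-Python right-hand side integrated with a stiff ODE solver
(scipy.integrate.solve_ivp, LSODA).  It shares no code with the table-based
Rush-Larsen production path in ``infarctsim._kernels`` and serves as the
oracle for trajectory-equivalence tests.

State order matches ``infarctsim.cellmodel.STATE_NAMES``.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

R = 8314.472
T = 310.0
F = 96485.3415
RTF = R * T / F

Cm = 0.185
V_c = 0.016404
V_sr = 0.001094
V_ss = 0.00005468

Ko = 5.4
Nao = 140.0
Cao = 2.0
pKNa = 0.03

GNa = 14.838
GK1 = 5.405
Gto = 0.073           # endocardial
GKr = 0.153
GKs = 0.392           # endocardial
GCaL = 0.0000398
GbNa = 0.00029
GbCa = 0.000592
GpCa = 0.1238
KpCa = 0.0005
GpK = 0.0146

PNaK = 2.724
KmK = 1.0
KmNa = 40.0

kNaCa = 1000.0
gamma = 0.35
KmNai = 87.5
KmCa = 1.38
ksat = 0.1
alpha = 2.5

Vrel = 0.102
k1p = 0.15
k2p = 0.045
k3 = 0.060
k4 = 0.005
EC = 1.5
maxsr = 2.5
minsr = 1.0
Vleak = 0.00036
Vmaxup = 0.006375
Kup = 0.00025
Vxfer = 0.0038

Bufc = 0.2
Kbufc = 0.001
Bufsr = 10.0
Kbufsr = 0.3
Bufss = 0.4
Kbufss = 0.00025


def rhs(t, y, gna_scale=1.0, gkr_scale=1.0, gks_scale=1.0, istim_fn=None):
    (V, m, h, j, d, f, f2, fcass, r, s, xr1, xr2, xs,
     Nai, Ki, Cai, Casr, Cass, Rbar) = y
    Istim = istim_fn(t) if istim_fn is not None else 0.0

    ENa = RTF * np.log(Nao / Nai)
    EK = RTF * np.log(Ko / Ki)
    EKs = RTF * np.log((Ko + pKNa * Nao) / (Ki + pKNa * Nai))
    ECa = 0.5 * RTF * np.log(Cao / Cai)

    INa = gna_scale * GNa * m ** 3 * h * j * (V - ENa)

    z = 2.0 * (V - 15.0) / RTF
    if abs(z) < 1e-8:
        drive = 2.0 * F * (0.25 * Cass - Cao)
    else:
        drive = (4.0 * (V - 15.0) * F / RTF) * \
            (0.25 * Cass * np.exp(z) - Cao) / (np.exp(z) - 1.0)
    ICaL = GCaL * d * f * f2 * fcass * drive

    Ito = Gto * r * s * (V - EK)
    IKr = gkr_scale * GKr * np.sqrt(Ko / 5.4) * xr1 * xr2 * (V - EK)
    IKs = gks_scale * GKs * xs ** 2 * (V - EKs)

    aK1 = 0.1 / (1.0 + np.exp(0.06 * (V - EK - 200.0)))
    bK1 = (3.0 * np.exp(0.0002 * (V - EK + 100.0))
           + np.exp(0.1 * (V - EK - 10.0))) / (1.0 + np.exp(-0.5 * (V - EK)))
    IK1 = GK1 * np.sqrt(Ko / 5.4) * aK1 / (aK1 + bK1) * (V - EK)

    INaCa = kNaCa * (np.exp(gamma * V / RTF) * Nai ** 3 * Cao
                     - np.exp((gamma - 1.0) * V / RTF) * Nao ** 3 * Cai * alpha) / (
        (KmNai ** 3 + Nao ** 3) * (KmCa + Cao)
        * (1.0 + ksat * np.exp((gamma - 1.0) * V / RTF)))
    INaK = PNaK * Ko * Nai / ((Ko + KmK) * (Nai + KmNa)) / (
        1.0 + 0.1245 * np.exp(-0.1 * V / RTF) + 0.0353 * np.exp(-V / RTF))
    IpCa = GpCa * Cai / (Cai + KpCa)
    IpK = GpK * (V - EK) / (1.0 + np.exp((25.0 - V) / 5.98))
    IbNa = GbNa * (V - ENa)
    IbCa = GbCa * (V - ECa)

    # gate kinetics
    m_inf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    tau_m = (1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))) * (
        0.1 / (1.0 + np.exp((V + 35.0) / 5.0))
        + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0)))
    h_inf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V < -40.0:
        a_h = 0.057 * np.exp(-(V + 80.0) / 6.8)
        b_h = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
    else:
        a_h = 0.0
        b_h = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    tau_h = 1.0 / (a_h + b_h)
    j_inf = h_inf
    if V < -40.0:
        a_j = ((-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
               * (V + 37.78)) / (1.0 + np.exp(0.311 * (V + 79.23)))
        b_j = 0.02424 * np.exp(-0.01052 * V) / (
            1.0 + np.exp(-0.1378 * (V + 40.14)))
    else:
        a_j = 0.0
        b_j = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    tau_j = 1.0 / (a_j + b_j)

    d_inf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    tau_d = (1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25) * (
        1.4 / (1.0 + np.exp((V + 5.0) / 5.0))) + 1.0 / (
        1.0 + np.exp((50.0 - V) / 20.0))
    f_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau_f = (1102.5 * np.exp(-((V + 27.0) ** 2) / 225.0)
             + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
             + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0)
    f2_inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    tau_f2 = (562.0 * np.exp(-((V + 27.0) ** 2) / 240.0)
              + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
              + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0)))
    fcass_inf = 0.6 / (1.0 + (Cass / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (Cass / 0.05) ** 2) + 2.0

    s_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))      # endocardial
    tau_s = 1000.0 * np.exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
    r_inf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau_r = 9.5 * np.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8

    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    tau_xr1 = (450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))) * (
        6.0 / (1.0 + np.exp((V + 30.0) / 11.5)))
    xr2_inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    tau_xr2 = (3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))) * (
        1.12 / (1.0 + np.exp((V - 60.0) / 20.0)))
    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    tau_xs = (1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))) * (
        1.0 / (1.0 + np.exp((V - 35.0) / 15.0))) + 80.0

    # calcium subsystem
    kcasr = maxsr - (maxsr - minsr) / (1.0 + (EC / Casr) ** 2)
    k1 = k1p / kcasr
    k2 = k2p * kcasr
    O = k1 * Cass ** 2 * Rbar / (k3 + k1 * Cass ** 2)
    Irel = Vrel * O * (Casr - Cass)
    Ileak = Vleak * (Casr - Cai)
    Iup = Vmaxup / (1.0 + (Kup / Cai) ** 2)
    Ixfer = Vxfer * (Cass - Cai)

    bufc = 1.0 / (1.0 + Bufc * Kbufc / (Cai + Kbufc) ** 2)
    bufsr = 1.0 / (1.0 + Bufsr * Kbufsr / (Casr + Kbufsr) ** 2)
    bufss = 1.0 / (1.0 + Bufss * Kbufss / (Cass + Kbufss) ** 2)

    dCai = bufc * ((Ileak - Iup) * V_sr / V_c + Ixfer
                   - (IbCa + IpCa - 2.0 * INaCa) * Cm / (2.0 * V_c * F))
    dCasr = bufsr * (Iup - Irel - Ileak)
    dCass = bufss * (-ICaL * Cm / (2.0 * V_ss * F)
                     + Irel * V_sr / V_ss - Ixfer * V_c / V_ss)
    dNai = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * Cm / (V_c * F)
    dKi = -(IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK - Istim) * Cm / (V_c * F)
    dRbar = -k2 * Cass * Rbar + k4 * (1.0 - Rbar)

    Iion = (INa + IK1 + Ito + IKr + IKs + ICaL + INaCa + INaK
            + IpCa + IpK + IbNa + IbCa)
    dV = -Iion + Istim

    return [
        dV,
        (m_inf - m) / tau_m,
        (h_inf - h) / tau_h,
        (j_inf - j) / tau_j,
        (d_inf - d) / tau_d,
        (f_inf - f) / tau_f,
        (f2_inf - f2) / tau_f2,
        (fcass_inf - fcass) / tau_fcass,
        (r_inf - r) / tau_r,
        (s_inf - s) / tau_s,
        (xr1_inf - xr1) / tau_xr1,
        (xr2_inf - xr2) / tau_xr2,
        (xs_inf - xs) / tau_xs,
        dNai, dKi, dCai, dCasr, dCass, dRbar,
    ]


def integrate(y0, t_end, stim_start, stim_dur, stim_amp,
              sample_interval=1.0, gna_scale=1.0, gkr_scale=1.0,
              gks_scale=1.0, rtol=1e-8, atol=1e-10):
    """Integrate the model with one square stimulus pulse (pA/pF).

    Integrates piecewise across the stimulus discontinuities.  Returns
    (times, Vm) sampled every ``sample_interval`` ms.
    """
    times = np.arange(0.0, t_end + 1e-9, sample_interval)
    segments = [(0.0, stim_start, 0.0),
                (stim_start, stim_start + stim_dur, stim_amp),
                (stim_start + stim_dur, t_end, 0.0)]
    y = np.asarray(y0, dtype=float)
    vm = np.empty_like(times)
    written = np.zeros(times.shape, dtype=bool)
    for (t0, t1, amp) in segments:
        if t1 <= t0:
            continue
        t_eval = times[(times >= t0 - 1e-12) & (times <= t1 + 1e-12)]
        sol = solve_ivp(
            rhs, (t0, t1), y, method="LSODA", t_eval=t_eval,
            args=(gna_scale, gkr_scale, gks_scale, lambda t: amp),
            rtol=rtol, atol=atol, max_step=1.0)
        if not sol.success:
            raise RuntimeError(f"oracle integration failed: {sol.message}")
        idx = np.searchsorted(times, sol.t)
        vm[idx] = sol.y[0]
        written[idx] = True
        y = sol.y[:, -1]
    if not written.all():
        raise RuntimeError("oracle sampling gap")
    return times, vm
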