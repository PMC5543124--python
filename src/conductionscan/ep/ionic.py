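"""Ionic cell models: membrane kinetics for the monodomain reaction term.

Three models, all vectorized over cells and integrated with Rush-Larsen
exponential updates for Hodgkin-Huxley gates and forward Euler for the
remaining states:

* :class:`MitchellSchaeffer` - a two-variable reduced model (fast tests,
  tissue-scale phantom runs).  Potential is rescaled to mV so thresholds are
  shared across models; its resting state is an exact fixed point.
* :class:`TenTusscher2004Epi` - human ventricular epicardial myocyte.
* :class:`Courtemanche1998` - human atrial myocyte.

Each model's kinetics live in a module-level function
``rates(V, state, I_stim) -> (dV/dt, dstate/dt, gate_inf, gate_tau)`` whose
leading ``n_gates`` state rows are Hodgkin-Huxley gates; the same function
serves the vectorized tissue solver, adaptive ODE integration, and (numba
JIT-compiled on first use, when numba is importable) the fast single-cell
integrator :func:`integrate_cell`.

Stimulus convention follows each published formulation: depolarizing
``I_stim`` is negative for the biophysical models (inward current, uA/uF)
and positive for Mitchell-Schaeffer (normalized inward flux).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IonicModel",
    "MitchellSchaeffer",
    "TenTusscher2004Epi",
    "Courtemanche1998",
    "get_model",
    "ionic_step",
    "integrate_cell",
]


# ---------------------------------------------------------------------------
# Mitchell-Schaeffer (2003) two-variable model, rescaled to mV
# ---------------------------------------------------------------------------

MS_TAU_IN, MS_TAU_OUT = 0.3, 6.0
MS_TAU_OPEN, MS_TAU_CLOSE = 120.0, 150.0
MS_U_GATE, MS_V_MIN, MS_V_MAX = 0.13, -85.0, 20.0


def ms_rates(V, state, I_stim):
    amp = MS_V_MAX - MS_V_MIN
    u = (V - MS_V_MIN) / amp
    h = state[0]
    du = h * u * u * (1.0 - u) / MS_TAU_IN - u / MS_TAU_OUT + I_stim
    ginf = np.zeros_like(state)
    gtau = np.ones_like(state)
    ginf[0] = np.where(u < MS_U_GATE, 1.0, 0.0)
    gtau[0] = np.where(u < MS_U_GATE, MS_TAU_OPEN, MS_TAU_CLOSE)
    dS = np.zeros_like(state)
    return amp * du, dS, ginf, gtau


# ---------------------------------------------------------------------------
# ten Tusscher et al. 2004, epicardial parameter set
# (units: mV, ms, mM; currents in uA/uF)
# ---------------------------------------------------------------------------

TT_RTF = 8314.472 * 310.0 / 96485.3415
TT_F, TT_CM = 96485.3415, 0.185
TT_VC, TT_VSR = 0.016404, 0.001094
TT_NAO, TT_KO, TT_CAO = 140.0, 5.4, 2.0
TT_GNA, TT_GK1, TT_GTO, TT_GKR, TT_GKS, TT_GCAL = \
    14.838, 5.405, 0.294, 0.096, 0.245, 1.75e-4
TT_GBNA, TT_GBCA, TT_GPCA, TT_GPK = 2.9e-4, 5.92e-4, 0.825, 0.0146
TT_PNAK, TT_KMK, TT_KMNA = 1.362, 1.0, 40.0
TT_KNACA, TT_KMNAI, TT_KMCA, TT_KSAT, TT_GAMMA, TT_ALPHA = \
    1000.0, 87.5, 1.38, 0.1, 0.35, 2.5
TT_KPCA, TT_PKNA = 5e-4, 0.03
TT_VMAXUP, TT_KUP, TT_VLEAK = 4.25e-4, 2.5e-4, 8e-5
TT_AREL, TT_BREL, TT_CREL = 0.016464, 0.25, 0.008232
TT_BUFC, TT_KBUFC, TT_BUFSR, TT_KBUFSR = 0.15, 1e-3, 10.0, 0.3


def tt2004_rates(V, state, I_stim):
    m, h, j, d, f = state[0], state[1], state[2], state[3], state[4]
    xr1, xr2, xs, r, s = state[5], state[6], state[7], state[8], state[9]
    fca, g = state[10], state[11]
    cai, casr, nai, ki = state[12], state[13], state[14], state[15]

    vf_rt = V / TT_RTF
    ena = TT_RTF * np.log(TT_NAO / nai)
    ek = TT_RTF * np.log(TT_KO / ki)
    eks = TT_RTF * np.log((TT_KO + TT_PKNA * TT_NAO) / (ki + TT_PKNA * nai))
    eca = 0.5 * TT_RTF * np.log(TT_CAO / cai)

    ina = TT_GNA * m ** 3 * h * j * (V - ena)
    e2 = np.exp(2.0 * vf_rt)
    num = 4.0 * V * TT_F / TT_RTF * (cai * e2 - 0.341 * TT_CAO)
    den = e2 - 1.0
    small = np.abs(V) < 1e-6
    drv = np.where(small, 2.0 * TT_F * (cai - 0.341 * TT_CAO),
                   num / np.where(small, 1.0, den))
    ical = TT_GCAL * d * f * fca * drv
    ito = TT_GTO * r * s * (V - ek)
    ikr = TT_GKR * np.sqrt(TT_KO / 5.4) * xr1 * xr2 * (V - ek)
    iks = TT_GKS * xs ** 2 * (V - eks)
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (V - ek - 200.0)))
    bk1 = (3.0 * np.exp(2e-4 * (V - ek + 100.0)) + np.exp(0.1 * (V - ek - 10.0))) \
        / (1.0 + np.exp(-0.5 * (V - ek)))
    ik1 = TT_GK1 * np.sqrt(TT_KO / 5.4) * ak1 / (ak1 + bk1) * (V - ek)
    inaca = TT_KNACA * (np.exp(TT_GAMMA * vf_rt) * nai ** 3 * TT_CAO
                        - np.exp((TT_GAMMA - 1.0) * vf_rt) * TT_NAO ** 3 * cai
                        * TT_ALPHA) \
        / ((TT_KMNAI ** 3 + TT_NAO ** 3) * (TT_KMCA + TT_CAO)
           * (1.0 + TT_KSAT * np.exp((TT_GAMMA - 1.0) * vf_rt)))
    inak = TT_PNAK * TT_KO * nai / ((TT_KO + TT_KMK) * (nai + TT_KMNA)
                                    * (1.0 + 0.1245 * np.exp(-0.1 * vf_rt)
                                       + 0.0353 * np.exp(-vf_rt)))
    ipca = TT_GPCA * cai / (TT_KPCA + cai)
    ipk = TT_GPK * (V - ek) / (1.0 + np.exp((25.0 - V) / 5.98))
    ibna = TT_GBNA * (V - ena)
    ibca = TT_GBCA * (V - eca)

    itot = ina + ik1 + ito + ikr + iks + ical + inaca + inak + ipca + ipk \
        + ibna + ibca
    dV = -(itot + I_stim)

    ginf = np.zeros_like(state)
    gtau = np.ones_like(state)
    ginf[0] = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) \
        + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    gtau[0] = am * bm
    ginf[1] = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    low = V < -40.0
    ah = np.where(low, 0.057 * np.exp(-(V + 80.0) / 6.8), 0.0)
    bh = np.where(low, 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V),
                  0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))))
    gtau[1] = 1.0 / (ah + bh)
    ginf[2] = ginf[1]
    aj = np.where(low, (-2.5428e4 * np.exp(0.2444 * V)
                        - 6.948e-6 * np.exp(-0.04391 * V)) * (V + 37.78)
                  / (1.0 + np.exp(0.311 * (V + 79.23))), 0.0)
    bj = np.where(low, 0.02424 * np.exp(-0.01052 * V)
                  / (1.0 + np.exp(-0.1378 * (V + 40.14))),
                  0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))))
    gtau[2] = 1.0 / (aj + bj)
    ginf[3] = 1.0 / (1.0 + np.exp((-5.0 - V) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    cd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    gtau[3] = ad * bd + cd
    ginf[4] = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    gtau[4] = 1125.0 * np.exp(-((V + 27.0) ** 2) / 240.0) + 80.0 \
        + 165.0 / (1.0 + np.exp((25.0 - V) / 10.0))
    ginf[5] = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    gtau[5] = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0)) \
        * 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    ginf[6] = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    gtau[6] = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0)) \
        * 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    ginf[7] = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    gtau[7] = 1100.0 / np.sqrt(1.0 + np.exp((-10.0 - V) / 6.0)) \
        * (1.0 / (1.0 + np.exp((V - 60.0) / 20.0)))
    ginf[8] = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    gtau[8] = 9.5 * np.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
    ginf[9] = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
    gtau[9] = 85.0 * np.exp(-((V + 45.0) ** 2) / 320.0) \
        + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0

    # Ca-dependent gates, conditionally frozen while depolarized
    afca = 1.0 / (1.0 + (cai / 3.25e-4) ** 8)
    bfca = 0.1 / (1.0 + np.exp((cai - 5e-4) / 1e-4))
    cfca = 0.2 / (1.0 + np.exp((cai - 7.5e-4) / 8e-4))
    fca_inf = (afca + bfca + cfca + 0.23) / 1.46
    dfca = np.where((fca_inf > fca) & (V > -60.0), 0.0, (fca_inf - fca) / 2.0)
    g_inf = np.where(cai < 3.5e-4, 1.0 / (1.0 + (cai / 3.5e-4) ** 6),
                     1.0 / (1.0 + (cai / 3.5e-4) ** 16))
    dg = np.where((g_inf > g) & (V > -60.0), 0.0, (g_inf - g) / 2.0)

    ileak = TT_VLEAK * (casr - cai)
    iup = TT_VMAXUP / (1.0 + (TT_KUP / cai) ** 2)
    irel = (TT_AREL * casr ** 2 / (TT_BREL ** 2 + casr ** 2) + TT_CREL) * d * g
    bufc = 1.0 / (1.0 + TT_BUFC * TT_KBUFC / (cai + TT_KBUFC) ** 2)
    bufsr = 1.0 / (1.0 + TT_BUFSR * TT_KBUFSR / (casr + TT_KBUFSR) ** 2)
    vcf = 1.0 / (TT_VC * TT_F)
    dS = np.zeros_like(state)
    dS[10] = dfca
    dS[11] = dg
    dS[12] = bufc * (ileak - iup + irel
                     - (ical + ibca + ipca - 2.0 * inaca) * 0.5 * vcf * TT_CM)
    dS[13] = bufsr * TT_VC / TT_VSR * (iup - irel - ileak)
    dS[14] = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * vcf * TT_CM
    dS[15] = -(ik1 + ito + ikr + iks - 2.0 * inak + ipk + I_stim) * vcf * TT_CM
    return dV, dS, ginf, gtau


# ---------------------------------------------------------------------------
# Courtemanche, Ramirez & Nattel 1998 human atrial model
# (units: mV, ms, mM; currents in pA/pF, cell capacitance 100 pF)
# ---------------------------------------------------------------------------

CRN_RTF = 8.3143 * 310.0 / 96.4867
CRN_F, CRN_CM = 96.4867, 100.0
CRN_VI, CRN_VUP, CRN_VREL = 13668.0, 1109.52, 96.48
CRN_NAO, CRN_KO, CRN_CAO = 140.0, 5.4, 1.8
CRN_GNA, CRN_GK1, CRN_GTO = 7.8, 0.09, 0.1652
CRN_GKR, CRN_GKS, CRN_GCAL = 0.029411765, 0.12941176, 0.12375
CRN_GBCA, CRN_GBNA = 0.001131, 0.0006744375
CRN_INAKMAX, CRN_KMNAI, CRN_KMKO = 0.59933874, 10.0, 1.5
CRN_IPCAMAX = 0.275
CRN_INACAMAX, CRN_KMNA, CRN_KMCA, CRN_KSAT, CRN_GAMMA = \
    1600.0, 87.5, 1.38, 0.1, 0.35
CRN_KREL, CRN_IUPMAX, CRN_KUP, CRN_CAUPMAX, CRN_TAUTR = \
    30.0, 0.005, 9.2e-4, 15.0, 180.0
CRN_CMDN, CRN_TRPN, CRN_CSQN = 0.05, 0.07, 10.0
CRN_KMCMDN, CRN_KMTRPN, CRN_KMCSQN = 0.00238, 5e-4, 0.8
CRN_KQ10 = 3.0


def crn1998_rates(V, state, I_stim):
    m, h, j = state[0], state[1], state[2]
    oa, oi, ua, ui = state[3], state[4], state[5], state[6]
    xr, xs, d, f, fca = state[7], state[8], state[9], state[10], state[11]
    w, u, v = state[12], state[13], state[14]
    cai, caup, carel = state[15], state[16], state[17]
    nai, ki = state[18], state[19]

    vf_rt = V / CRN_RTF
    ena = CRN_RTF * np.log(CRN_NAO / nai)
    ek = CRN_RTF * np.log(CRN_KO / ki)
    eca = 0.5 * CRN_RTF * np.log(CRN_CAO / cai)

    ina = CRN_GNA * m ** 3 * h * j * (V - ena)
    ik1 = CRN_GK1 * (V - ek) / (1.0 + np.exp(0.07 * (V + 80.0)))
    ito = CRN_GTO * oa ** 3 * oi * (V - ek)
    gkur = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
    ikur = gkur * ua ** 3 * ui * (V - ek)
    ikr = CRN_GKR * xr * (V - ek) / (1.0 + np.exp((V + 15.0) / 22.4))
    iks = CRN_GKS * xs ** 2 * (V - ek)
    ical = CRN_GCAL * d * f * fca * (V - 65.0)
    sigma = (np.exp(CRN_NAO / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * vf_rt)
                  + 0.0365 * sigma * np.exp(-vf_rt))
    inak = CRN_INAKMAX * fnak * CRN_KO \
        / ((1.0 + (CRN_KMNAI / nai) ** 1.5) * (CRN_KO + CRN_KMKO))
    inaca = CRN_INACAMAX * (np.exp(CRN_GAMMA * vf_rt) * nai ** 3 * CRN_CAO
                            - np.exp((CRN_GAMMA - 1.0) * vf_rt)
                            * CRN_NAO ** 3 * cai) \
        / ((CRN_KMNA ** 3 + CRN_NAO ** 3) * (CRN_KMCA + CRN_CAO)
           * (1.0 + CRN_KSAT * np.exp((CRN_GAMMA - 1.0) * vf_rt)))
    ipca = CRN_IPCAMAX * cai / (5e-4 + cai)
    ibna = CRN_GBNA * (V - ena)
    ibca = CRN_GBCA * (V - eca)

    itot = ina + ik1 + ito + ikur + ikr + iks + ical + ipca + inak \
        + inaca + ibna + ibca
    dV = -(itot + I_stim)

    ginf = np.zeros_like(state)
    gtau = np.ones_like(state)

    vm = V + 47.13
    am = np.where(np.abs(vm) < 1e-6, 3.2,
                  0.32 * vm / (1.0 - np.exp(-0.1 * np.where(np.abs(vm) < 1e-6,
                                                            1.0, vm))))
    bm = 0.08 * np.exp(-V / 11.0)
    ginf[0] = am / (am + bm)
    gtau[0] = 1.0 / (am + bm)
    low = V < -40.0
    ah = np.where(low, 0.135 * np.exp(-(V + 80.0) / 6.8), 0.0)
    bh = np.where(low, 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V),
                  1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))))
    ginf[1] = ah / (ah + bh)
    gtau[1] = 1.0 / (ah + bh)
    aj = np.where(low, (-1.2714e5 * np.exp(0.2444 * V)
                        - 3.474e-5 * np.exp(-0.04391 * V)) * (V + 37.78)
                  / (1.0 + np.exp(0.311 * (V + 79.23))), 0.0)
    bj = np.where(low, 0.1212 * np.exp(-0.01052 * V)
                  / (1.0 + np.exp(-0.1378 * (V + 40.14))),
                  0.3 * np.exp(-2.535e-7 * V)
                  / (1.0 + np.exp(-0.1 * (V + 32.0))))
    ginf[2] = aj / (aj + bj)
    gtau[2] = 1.0 / (aj + bj)

    ao = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    bo = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    gtau[3] = 1.0 / ((ao + bo) * CRN_KQ10)
    ginf[3] = 1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54))
    aoi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    boi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    gtau[4] = 1.0 / ((aoi + boi) * CRN_KQ10)
    ginf[4] = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))
    gtau[5] = gtau[3]
    ginf[5] = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
    aui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
    bui = np.exp((V - 158.0) / 16.0)
    gtau[6] = 1.0 / ((aui + bui) * CRN_KQ10)
    ginf[6] = 1.0 / (1.0 + np.exp((V - 99.45) / 27.48))

    vx = V + 14.1
    axr = np.where(np.abs(vx) < 1e-6, 0.0015,
                   3e-4 * vx / (1.0 - np.exp(-np.where(np.abs(vx) < 1e-6,
                                                       1.0, vx) / 5.0)))
    vb = V - 3.3328
    bxr = np.where(np.abs(vb) < 1e-6, 3.7836118e-4,
                   7.3898e-5 * vb / (np.exp(np.where(np.abs(vb) < 1e-6,
                                                     1.0, vb) / 5.1237) - 1.0))
    gtau[7] = 1.0 / (axr + bxr)
    ginf[7] = 1.0 / (1.0 + np.exp(-vx / 6.5))
    vs = V - 19.9
    axs = np.where(np.abs(vs) < 1e-6, 6.8e-4,
                   4e-5 * vs / (1.0 - np.exp(-np.where(np.abs(vs) < 1e-6,
                                                       1.0, vs) / 17.0)))
    bxs = np.where(np.abs(vs) < 1e-6, 3.15e-4,
                   3.5e-5 * vs / (np.exp(np.where(np.abs(vs) < 1e-6,
                                                  1.0, vs) / 9.0) - 1.0))
    gtau[8] = 0.5 / (axs + bxs)
    ginf[8] = 1.0 / np.sqrt(1.0 + np.exp(-vs / 12.7))

    vd = V + 10.0
    gtau[9] = np.where(np.abs(vd) < 1e-6, 2.289536,
                       (1.0 - np.exp(-vd / 6.24))
                       / (0.035 * np.where(np.abs(vd) < 1e-6, 1.0, vd)
                          * (1.0 + np.exp(-vd / 6.24))))
    ginf[9] = 1.0 / (1.0 + np.exp(-vd / 8.0))
    gtau[10] = 9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * vd ** 2) + 0.02)
    ginf[10] = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
    gtau[11] = 2.0
    ginf[11] = 1.0 / (1.0 + cai / 3.5e-4)
    vw = V - 7.9
    gtau[12] = np.where(np.abs(vw) < 1e-6, 0.9231,
                        6.0 * (1.0 - np.exp(-vw / 5.0))
                        / ((1.0 + 0.3 * np.exp(-vw / 5.0))
                           * np.where(np.abs(vw) < 1e-6, 1.0, vw)))
    ginf[12] = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))

    irel = CRN_KREL * u ** 2 * v * w * (carel - cai)
    fn = 1e-12 * CRN_VREL * irel \
        - 5e-13 / CRN_F * (0.5 * ical - 0.2 * inaca) * CRN_CM
    gtau[13] = 8.0
    ginf[13] = 1.0 / (1.0 + np.exp(-(fn - 3.4175e-13) / 1.367e-15))
    gtau[14] = 1.91 + 2.09 / (1.0 + np.exp(-(fn - 3.4175e-13) / 1.367e-15))
    ginf[14] = 1.0 - 1.0 / (1.0 + np.exp(-(fn - 6.835e-14) / 1.367e-15))

    iup = CRN_IUPMAX / (1.0 + CRN_KUP / cai)
    iupleak = CRN_IUPMAX * caup / CRN_CAUPMAX
    itr = (caup - carel) / CRN_TAUTR
    fvi = CRN_CM / (CRN_F * CRN_VI)
    b1 = (2.0 * inaca - ipca - ical - ibca) * 0.5 * fvi \
        + (CRN_VUP * (iupleak - iup) + irel * CRN_VREL) / CRN_VI
    b2 = 1.0 + CRN_TRPN * CRN_KMTRPN / (cai + CRN_KMTRPN) ** 2 \
        + CRN_CMDN * CRN_KMCMDN / (cai + CRN_KMCMDN) ** 2
    dS = np.zeros_like(state)
    dS[15] = b1 / b2
    dS[16] = iup - iupleak - itr * CRN_VREL / CRN_VUP
    dS[17] = (itr - irel) / (1.0 + CRN_CSQN * CRN_KMCSQN
                             / (carel + CRN_KMCSQN) ** 2)
    dS[18] = (-3.0 * inak - 3.0 * inaca - ibna - ina) * fvi
    dS[19] = (2.0 * inak - ik1 - ito - ikur - ikr - iks) * fvi
    return dV, dS, ginf, gtau


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

class IonicModel:
    """Base interface: subclasses define state layout and kinetics."""

    name: str = ""
    state_names: tuple[str, ...] = ()
    n_gates: int = 0           # leading state rows updated by Rush-Larsen
    #: largest stable Rush-Larsen/Euler step (ms), documented per model
    max_dt_ms: float = 0.02
    #: a stimulus amplitude reliably above threshold for a short pulse
    default_stim_amplitude: float = 0.0
    _rates = None              # module-level kinetics function

    def resting_state(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        return (np.full(n, self._V0, dtype=float),
                np.tile(np.asarray(self._S0, dtype=float)[:, None], (1, n)))

    def rates(self, V, state, I_stim=0.0):
        return type(self)._rates(np.asarray(V, dtype=float),
                                 np.asarray(state, dtype=float), I_stim)

    def packed_rhs(self, t, y, I_stim=0.0):
        """RHS over the packed vector [V, state...] for adaptive ODE solvers
        (gates as plain ODEs dy/dt = (inf - y)/tau)."""
        V = np.atleast_1d(y[0])
        S = y[1:][:, None]
        dV, dS, ginf, gtau = self.rates(V, S, I_stim)
        dS = dS.copy()
        g = slice(0, self.n_gates)
        dS[g] = (ginf[g] - S[g]) / gtau[g]
        return np.concatenate([np.atleast_1d(dV), dS[:, 0]])


class MitchellSchaeffer(IonicModel):
    """Reduced two-variable excitable model.

    The normalized potential u in [0, 1] maps to V = V_min + u (V_max-V_min)
    with V_min = -85, V_max = +20 mV.  State: the recovery gate h.
    (u=0, h=1) is an exact fixed point, so quiescent-tissue tests hold to
    machine precision.
    """

    name = "mitchell_schaeffer"
    state_names = ("h",)
    n_gates = 1
    max_dt_ms = 0.1
    default_stim_amplitude = 0.6  # normalized flux per ms
    _V0 = MS_V_MIN
    _S0 = (1.0,)
    _rates = staticmethod(ms_rates)


class TenTusscher2004Epi(IonicModel):
    """Human ventricular (epicardial) myocyte model.

    State (after V): gates m h j d f xr1 xr2 xs r s, the Ca-dependent gates
    fca and g (conditionally frozen, advanced by Euler), then Cai CaSR Nai
    Ki (mM).
    """

    name = "ten_tusscher_2004_epi"
    state_names = ("m", "h", "j", "d", "f", "xr1", "xr2", "xs", "r", "s",
                   "fca", "g", "cai", "casr", "nai", "ki")
    n_gates = 10
    max_dt_ms = 0.02
    default_stim_amplitude = -52.0  # uA/uF
    _V0 = -86.2
    _S0 = (0.0, 0.75, 0.75, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0,
           1.0, 1.0, 2e-4, 0.2, 11.6, 138.3)
    _rates = staticmethod(tt2004_rates)


class Courtemanche1998(IonicModel):
    """Human atrial myocyte model (cell capacitance 100 pF)."""

    name = "courtemanche_1998"
    state_names = ("m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d",
                   "f", "fca", "w", "u", "v", "cai", "caup", "carel",
                   "nai", "ki")
    n_gates = 15
    max_dt_ms = 0.02
    default_stim_amplitude = -28.0  # pA/pF
    _V0 = -81.18
    _S0 = (2.908e-3, 0.9649, 0.9775, 3.043e-2, 0.9992, 4.966e-3, 0.9986,
           3.296e-5, 1.869e-2, 1.367e-4, 0.9996, 0.7755, 0.9992, 0.0, 1.0,
           1.013e-4, 1.488, 1.488, 11.17, 139.0)
    _rates = staticmethod(crn1998_rates)


_MODELS = {m.name: m for m in (MitchellSchaeffer, TenTusscher2004Epi,
                               Courtemanche1998)}


def get_model(name: str, **kwargs) -> IonicModel:
    """Instantiate a model by id (``mitchell_schaeffer``,
    ``ten_tusscher_2004_epi``, ``courtemanche_1998``)."""
    try:
        return _MODELS[name](**kwargs)
    except KeyError:
        raise ValueError(f"unknown ionic model {name!r}; "
                         f"available: {sorted(_MODELS)}") from None


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def ionic_step(model: IonicModel, state: np.ndarray, V: np.ndarray,
               dt: float, I_stim=0.0) -> tuple[np.ndarray, np.ndarray]:
    """One reaction step: Rush-Larsen for gates, forward Euler otherwise.

    Returns ``(state_new, dV/dt)``; the caller advances V (adding any
    diffusion term).  Raises if the state goes non-finite, reporting the
    first offending cell.
    """
    if dt > model.max_dt_ms * (1 + 1e-9):
        raise ValueError(f"dt={dt} exceeds {model.name} stable step "
                         f"{model.max_dt_ms} ms")
    dV, dS, ginf, gtau = model.rates(V, state, I_stim)
    new = state + dt * dS
    g = slice(0, model.n_gates)
    new[g] = ginf[g] + (state[g] - ginf[g]) * np.exp(-dt / gtau[g])
    if not (np.all(np.isfinite(new)) and np.all(np.isfinite(dV))):
        bad = np.argwhere(~np.isfinite(new))
        raise FloatingPointError(
            f"{model.name}: non-finite state at entry "
            f"{tuple(bad[0]) if bad.size else '?'}")
    return new, dV


_compiled_cache: dict[str, object] = {}


def _compiled_rates(model: IonicModel):
    """JIT-compile the model's kinetics with numba, once; None if unavailable."""
    key = model.name
    if key not in _compiled_cache:
        try:
            import numba

            fn = numba.njit(cache=True)(_PLAIN[key])
            # trigger compilation so failures fall back cleanly
            V0, S0 = model.resting_state(1)
            fn(V0, S0, 0.0)
            _compiled_cache[key] = fn
        except Exception:
            _compiled_cache[key] = None
    return _compiled_cache[key]


_PLAIN = {"mitchell_schaeffer": ms_rates,
          "ten_tusscher_2004_epi": tt2004_rates,
          "courtemanche_1998": crn1998_rates}


def integrate_cell(model: IonicModel, duration_ms: float, dt_ms: float | None
                   = None, stim_amplitude: float | None = None,
                   stim_onset_ms: float = 0.0, stim_duration_ms: float = 0.0,
                   record_every: int = 10,
                   V0=None, S0=None):
    """Fixed-step single-cell integration (Rush-Larsen gates).

    Uses the numba-compiled kinetics when available (identical equations to
    :meth:`IonicModel.rates`).  Returns ``(t, V_trace, V_final, state_final)``
    with the trace sampled every ``record_every`` steps.
    """
    dt = float(dt_ms if dt_ms is not None else model.max_dt_ms)
    if dt > model.max_dt_ms * (1 + 1e-9):
        raise ValueError(f"dt={dt} exceeds {model.name} stable step")
    if V0 is None or S0 is None:
        V, S = model.resting_state(1)
    else:
        V, S = np.array(V0, ndmin=1, dtype=float), np.array(S0, dtype=float)
    rates = _compiled_rates(model) or _PLAIN[model.name]
    n_steps = int(np.ceil(duration_ms / dt))
    g = slice(0, model.n_gates)
    amp = (stim_amplitude if stim_amplitude is not None
           else model.default_stim_amplitude)
    ts, vs = [], []
    t = 0.0
    for step in range(n_steps):
        I = amp if stim_onset_ms <= t < stim_onset_ms + stim_duration_ms else 0.0
        dV, dS, ginf, gtau = rates(V, S, I)
        S = S + dt * dS
        S[g] = ginf[g] + (S[g] - dt * dS[g] - ginf[g]) * np.exp(-dt / gtau[g])
        V = V + dt * dV
        t += dt
        if step % record_every == 0:
            ts.append(t)
            vs.append(float(V[0]))
    return np.asarray(ts), np.asarray(vs), V, S
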