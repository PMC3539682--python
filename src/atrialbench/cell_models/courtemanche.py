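"""Courtemanche–Ramirez–Nattel human atrial myocyte model (1998).

Transcribed from Courtemanche M, Ramirez RJ, Nattel S, "Ionic mechanisms
underlying human atrial action potential properties: insights from a
mathematical model", Am J Physiol 275:H301-H321, 1998 (equations and the
published initial conditions).  21 states; voltage in mV, time in ms,
currents in pA, concentrations in mM.  Fifteen Hodgkin–Huxley gates are
integrated with Rush–Larsen; V_m, ion concentrations and the algebraically
buffered Ca compartments with forward Euler.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._base import CAF_FACTORS, IonicModel
from ._engine import FASTMATH, make_stepper

STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "u", "v", "w", "Nai", "Ki", "Cai", "Caup", "Carel",
)
STATE_UNITS = (
    "mV", "1", "1", "1", "1", "1", "1", "1", "1", "1",
    "1", "1", "1", "1", "1", "1", "mM", "mM", "mM", "mM", "mM",
)
GATES = np.arange(1, 16)
CAI = 18

PARAM_NAMES = (
    "gna", "gk1", "gto", "gkr", "gks", "gcal", "gbca", "gbna",
    "inakmax", "incxmax", "ipcamax", "gkur",
    "krel", "iupmax", "kup", "caupmax", "tautr",
    "cm", "nao", "ko", "cao",
)

#: cAF remodeling factors mapped onto this model's parameter names.
CAF_SCALING = {
    "gto": CAF_FACTORS["gto"],
    "gcal": CAF_FACTORS["gcal"],
    "gkur": CAF_FACTORS["gkur"],
    "gk1": CAF_FACTORS["gk1"],
}

CURRENT_NAMES = (
    "I_Na", "I_K1", "I_to", "I_Kur", "I_Kr", "I_Ks", "I_CaL",
    "I_NKA", "I_NCX", "I_bNa", "I_bCa", "I_PMCA",
)

# physical constants (model's conventions)
R = 8.3143  # J/(mol*K)
T = 310.0  # K
F = 96.4867  # C/mmol
VI = 13668.0  # intracellular volume, um^3
VUP = 1109.52
VREL = 96.48
CM = 100.0  # pF
KQ10 = 3.0
# Ca buffers
CMDN_MAX, TRPN_MAX, CSQN_MAX = 0.05, 0.07, 10.0
KM_CMDN, KM_TRPN, KM_CSQN = 0.00238, 0.0005, 0.8
# Na/Ca exchanger
KM_NA, KM_CA, K_SAT, GAMMA = 87.5, 1.38, 0.1, 0.35
# Na/K pump
KM_NAI, KM_KO = 10.0, 1.5


def params_control() -> np.ndarray:
    return np.array(
        [
            7.8,  # gna, nS/pF
            0.09,  # gk1
            0.1652,  # gto
            0.029411765,  # gkr
            0.12941176,  # gks
            0.12375,  # gcal
            0.001131,  # gbca
            0.0006744375,  # gbna
            0.59933874,  # inakmax, pA/pF
            1600.0,  # incxmax, pA/pF
            0.275,  # ipcamax, pA/pF
            1.0,  # gkur (scale on the voltage-dependent g_Kur expression)
            30.0,  # krel, 1/ms
            0.005,  # iupmax, mM/ms
            0.00092,  # kup, mM
            15.0,  # caupmax, mM
            180.0,  # tautr, ms
            CM,  # cm, pF
            140.0,  # nao, mM
            5.4,  # ko, mM
            1.8,  # cao, mM
        ]
    )


def initial_state() -> np.ndarray:
    """Published resting initial conditions."""
    return np.array(
        [
            -81.18,  # V
            2.908e-3,  # m
            9.649e-1,  # h
            9.775e-1,  # j
            3.043e-2,  # oa
            9.992e-1,  # oi
            4.966e-3,  # ua
            9.986e-1,  # ui
            3.296e-5,  # xr
            1.869e-2,  # xs
            1.367e-4,  # d
            9.996e-1,  # f
            7.755e-1,  # fca
            0.0,  # u
            1.0,  # v
            9.992e-1,  # w
            1.117e1,  # Nai
            1.39e2,  # Ki
            1.013e-4,  # Cai
            1.488,  # Caup
            1.488,  # Carel
        ]
    )


@njit(fastmath=FASTMATH)
def core(s, p, istim, d, yinf, tau):
    (gna, gk1, gto, gkr, gks, gcal, gbca, gbna, inakmax, incxmax, ipcamax,
     gkur_scale, krel, iupmax, kup, caupmax, tautr, cm, nao, ko, cao) = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9], p[10],
        p[11], p[12], p[13], p[14], p[15], p[16], p[17], p[18], p[19], p[20],
    )
    V = s[0]
    m, h, j = s[1], s[2], s[3]
    oa, oi, ua, ui = s[4], s[5], s[6], s[7]
    xr, xs = s[8], s[9]
    dg, fg, fca = s[10], s[11], s[12]
    u, vg, w = s[13], s[14], s[15]
    nai, ki, cai, caup, carel = s[16], s[17], s[18], s[19], s[20]

    rtf = R * T / F
    ena = rtf * np.log(nao / nai)
    ek = rtf * np.log(ko / ki)
    eca = 0.5 * rtf * np.log(cao / cai)

    # --- sarcolemmal currents (pA) ---
    ina = cm * gna * m * m * m * h * j * (V - ena)
    ik1 = cm * gk1 * (V - ek) / (1.0 + np.exp(0.07 * (V + 80.0)))
    ito = cm * gto * oa * oa * oa * oi * (V - ek)
    gkur = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
    ikur = cm * gkur_scale * gkur * ua * ua * ua * ui * (V - ek)
    ikr = cm * gkr * xr * (V - ek) / (1.0 + np.exp((V + 15.0) / 22.4))
    iks = cm * gks * xs * xs * (V - ek)
    ical = cm * gcal * dg * fg * fca * (V - 65.0)

    sigma = (np.exp(nao / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (
        1.0
        + 0.1245 * np.exp(-0.1 * V / rtf)
        + 0.0365 * sigma * np.exp(-V / rtf)
    )
    inak = (
        cm * inakmax * fnak * ko / (ko + KM_KO)
        / (1.0 + (KM_NAI / nai) ** 1.5)
    )
    expg = np.exp(GAMMA * V / rtf)
    expg1 = np.exp((GAMMA - 1.0) * V / rtf)
    inaca = (
        cm
        * incxmax
        * (expg * nai ** 3 * cao - expg1 * nao ** 3 * cai)
        / (
            (KM_NA ** 3 + nao ** 3)
            * (KM_CA + cao)
            * (1.0 + K_SAT * expg1)
        )
    )
    ibna = cm * gbna * (V - ena)
    ibca = cm * gbca * (V - eca)
    ipca = cm * ipcamax * cai / (0.0005 + cai)

    # --- SR fluxes (mM/ms) ---
    irel = krel * u * u * vg * w * (carel - cai)
    itr = (caup - carel) / tautr
    iup = iupmax / (1.0 + kup / cai)
    iupleak = iupmax * caup / caupmax

    # --- gate kinetics ---
    # fast Na+
    if np.abs(V + 47.13) < 1e-10:
        am = 3.2
    else:
        am = 0.32 * (V + 47.13) / (1.0 - np.exp(-0.1 * (V + 47.13)))
    bm = 0.08 * np.exp(-V / 11.0)
    yinf[1] = am / (am + bm)
    tau[1] = 1.0 / (am + bm)
    if V >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = (
            0.3
            * np.exp(-2.535e-7 * V)
            / (1.0 + np.exp(-0.1 * (V + 32.0)))
        )
    else:
        ah = 0.135 * np.exp(-(V + 80.0) / 6.8)
        bh = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
        aj = (
            (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
            * (V + 37.78)
            / (1.0 + np.exp(0.311 * (V + 79.23)))
        )
        bj = 0.1212 * np.exp(-0.01052 * V) / (
            1.0 + np.exp(-0.1378 * (V + 40.14))
        )
    yinf[2] = ah / (ah + bh)
    tau[2] = 1.0 / (ah + bh)
    yinf[3] = aj / (aj + bj)
    tau[3] = 1.0 / (aj + bj)
    # I_to gates
    aoa = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    boa = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    tau[4] = 1.0 / ((aoa + boa) * KQ10)
    yinf[4] = 1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54))
    aoi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    boi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    tau[5] = 1.0 / ((aoi + boi) * KQ10)
    yinf[5] = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))
    # I_Kur gates (same rate constants as oa for activation)
    tau[6] = tau[4]
    yinf[6] = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
    aui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
    bui = np.exp((V - 158.0) / 16.0)
    tau[7] = 1.0 / ((aui + bui) * KQ10)
    yinf[7] = 1.0 / (1.0 + np.exp((V - 99.45) / 27.48))
    # I_Kr activation
    if np.abs(V + 14.1) < 1e-10:
        axr = 0.0015
    else:
        axr = 0.0003 * (V + 14.1) / (1.0 - np.exp(-(V + 14.1) / 5.0))
    if np.abs(V - 3.3328) < 1e-10:
        bxr = 3.7836118e-4
    else:
        bxr = (
            7.3898e-5
            * (V - 3.3328)
            / (np.exp((V - 3.3328) / 5.1237) - 1.0)
        )
    tau[8] = 1.0 / (axr + bxr)
    yinf[8] = 1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5))
    # I_Ks activation
    if np.abs(V - 19.9) < 1e-10:
        axs = 0.00068
        bxs = 0.000315
    else:
        axs = 4e-5 * (V - 19.9) / (1.0 - np.exp(-(V - 19.9) / 17.0))
        bxs = 3.5e-5 * (V - 19.9) / (np.exp((V - 19.9) / 9.0) - 1.0)
    tau[9] = 0.5 / (axs + bxs)
    yinf[9] = 1.0 / np.sqrt(1.0 + np.exp(-(V - 19.9) / 12.7))
    # I_CaL gates
    if np.abs(V + 10.0) < 1e-10:
        tau[10] = 4.579 / (1.0 + np.exp(-(V + 10.0) / 6.24))
    else:
        tau[10] = (
            (1.0 - np.exp(-(V + 10.0) / 6.24))
            / (0.035 * (V + 10.0) * (1.0 + np.exp(-(V + 10.0) / 6.24)))
        )
    yinf[10] = 1.0 / (1.0 + np.exp(-(V + 10.0) / 8.0))
    tau[11] = 9.0 / (
        0.0197 * np.exp(-(0.0337 * 0.0337) * (V + 10.0) * (V + 10.0)) + 0.02
    )
    yinf[11] = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
    tau[12] = 2.0
    yinf[12] = 1.0 / (1.0 + cai / 0.00035)
    # SR release gates, driven by Fn (flux/current balance near the SR)
    fn = 1e-12 * VREL * irel - 5e-13 / F * (0.5 * ical - 0.2 * inaca)
    tau[13] = 8.0
    yinf[13] = 1.0 / (1.0 + np.exp(-(fn - 3.4175e-13) / 13.67e-16))
    tau[14] = 1.91 + 2.09 / (1.0 + np.exp(-(fn - 3.4175e-13) / 13.67e-16))
    yinf[14] = 1.0 - 1.0 / (1.0 + np.exp(-(fn - 6.835e-14) / 13.67e-16))
    if np.abs(V - 7.9) < 1e-10:
        tau[15] = 6.0 * 0.2 / 1.3
    else:
        tau[15] = (
            6.0
            * (1.0 - np.exp(-(V - 7.9) / 5.0))
            / ((1.0 + 0.3 * np.exp(-(V - 7.9) / 5.0)) * (V - 7.9))
        )
    yinf[15] = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))

    # gate rates (for callers using plain forward differences)
    for g in range(1, 16):
        d[g] = (yinf[g] - s[g]) / tau[g]

    # --- membrane and concentration ODEs ---
    iion = (
        ina + ik1 + ito + ikur + ikr + iks + ical + inak + inaca
        + ibna + ibca + ipca
    )
    d[0] = -iion / cm + istim

    d[16] = (-3.0 * inak - 3.0 * inaca - ibna - ina) / (F * VI)
    d[17] = (2.0 * inak - ik1 - ito - ikur - ikr - iks) / (F * VI)
    b1 = (2.0 * inaca - ipca - ical - ibca) / (2.0 * F * VI) + (
        VUP * (iupleak - iup) + irel * VREL
    ) / VI
    b2 = (
        1.0
        + TRPN_MAX * KM_TRPN / ((cai + KM_TRPN) * (cai + KM_TRPN))
        + CMDN_MAX * KM_CMDN / ((cai + KM_CMDN) * (cai + KM_CMDN))
    )
    d[18] = b1 / b2
    d[19] = iup - iupleak - itr * VREL / VUP
    d[20] = (itr - irel) / (
        1.0 + CSQN_MAX * KM_CSQN / ((carel + KM_CSQN) * (carel + KM_CSQN))
    )


@njit(fastmath=FASTMATH)
def currents(s, p, out):
    """Instantaneous sarcolemmal currents (pA), order per CURRENT_NAMES."""
    (gna, gk1, gto, gkr, gks, gcal, gbca, gbna, inakmax, incxmax, ipcamax,
     gkur_scale) = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9], p[10],
        p[11],
    )
    cm, nao, ko, cao = p[17], p[18], p[19], p[20]
    V = s[0]
    m, h, j = s[1], s[2], s[3]
    oa, oi, ua, ui = s[4], s[5], s[6], s[7]
    xr, xs = s[8], s[9]
    dg, fg, fca = s[10], s[11], s[12]
    nai, ki, cai = s[16], s[17], s[18]
    rtf = R * T / F
    ena = rtf * np.log(nao / nai)
    ek = rtf * np.log(ko / ki)
    eca = 0.5 * rtf * np.log(cao / cai)
    out[0] = cm * gna * m * m * m * h * j * (V - ena)
    out[1] = cm * gk1 * (V - ek) / (1.0 + np.exp(0.07 * (V + 80.0)))
    out[2] = cm * gto * oa * oa * oa * oi * (V - ek)
    gkur = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
    out[3] = cm * gkur_scale * gkur * ua * ua * ua * ui * (V - ek)
    out[4] = cm * gkr * xr * (V - ek) / (1.0 + np.exp((V + 15.0) / 22.4))
    out[5] = cm * gks * xs * xs * (V - ek)
    out[6] = cm * gcal * dg * fg * fca * (V - 65.0)
    sigma = (np.exp(nao / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (
        1.0
        + 0.1245 * np.exp(-0.1 * V / rtf)
        + 0.0365 * sigma * np.exp(-V / rtf)
    )
    out[7] = (
        cm * inakmax * fnak * ko / (ko + KM_KO)
        / (1.0 + (KM_NAI / nai) ** 1.5)
    )
    expg = np.exp(GAMMA * V / rtf)
    expg1 = np.exp((GAMMA - 1.0) * V / rtf)
    out[8] = (
        cm
        * incxmax
        * (expg * nai ** 3 * cao - expg1 * nao ** 3 * cai)
        / ((KM_NA ** 3 + nao ** 3) * (KM_CA + cao) * (1.0 + K_SAT * expg1))
    )
    out[9] = cm * gbna * (V - ena)
    out[10] = cm * gbca * (V - eca)
    out[11] = cm * ipcamax * cai / (0.0005 + cai)


step = make_stepper(core, len(STATE_NAMES), GATES)


def build() -> IonicModel:
    return IonicModel(
        name="courtemanche",
        variant="control",
        state_names=STATE_NAMES,
        state_units=STATE_UNITS,
        param_names=PARAM_NAMES,
        params=params_control(),
        initial_state=initial_state(),
        gating_index=GATES.copy(),
        stiff_index=np.empty(0, dtype=np.int64),
        current_names=CURRENT_NAMES,
        cai_index=CAI,
        cm=CM,
        caf_scaling=CAF_SCALING,
        core=core,
        step=step,
        currents_fn=currents,
    )
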