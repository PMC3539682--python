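"""Nygren 1998 and Maleckar 2009 human atrial myocyte models.

The Nygren et al. model (Circ Res 82:63-81, 1998) describes the human
atrial AP with a restricted extracellular cleft space, a diadic space
between the L-type channels and the SR release site, explicit cytosolic
Ca buffers and an electroneutral Na influx that stabilises long-term ion
concentrations.  Time is seconds and currents pA in the original; here
everything is converted to ms at the derivative level.

The Maleckar et al. model (Am J Physiol 297:H1398-H1410, 2009) is a
re-parameterisation of the Nygren framework: the transient outward and
ultrarapid (I_Kur) repolarising currents are reformulated from newer
voltage-clamp data, the electroneutral Na influx is removed, and an
acetylcholine-activated K current I_KACh is added (zero at the default
[ACh] = 0, i.e. no vagal tone).  Both models share one compiled core with
a compile-time variant switch.

29 states; 12 Hodgkin–Huxley gates (Rush–Larsen), everything else forward
Euler.  Reversal potentials use the cleft concentrations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._base import CAF_FACTORS, IonicModel
from ._engine import FASTMATH, make_stepper

STATE_NAMES = (
    "V", "m", "h1", "h2", "dL", "fL1", "fL2", "r", "s", "rsus", "ssus",
    "n", "pa",
    "Nac", "Kc", "Cac", "Nai", "Ki", "Cai", "Cad",
    "OC", "OTC", "OTMgC", "OTMgMg", "OCalse",
    "Caup", "Carel", "F1", "F2",
)
STATE_UNITS = (
    "mV", "1", "1", "1", "1", "1", "1", "1", "1", "1", "1", "1", "1",
    "mM", "mM", "mM", "mM", "mM", "mM", "mM",
    "1", "1", "1", "1", "1",
    "mM", "mM", "1", "1",
)
GATES = np.arange(1, 13)
CAI = 18

PARAM_NAMES = (
    "pna", "gcal", "gt", "gkur", "gks", "gkr", "gk1", "gbna", "gbca",
    "inakmax", "icapmax", "knaca", "phinaen", "iupmax",
    "cm", "nab", "kb", "cab", "ach",
)

CAF_SCALING = {
    "gt": CAF_FACTORS["gto"],
    "gcal": CAF_FACTORS["gcal"],
    "gkur": CAF_FACTORS["gkur"],  # I_sus in the Nygren nomenclature
    "gk1": CAF_FACTORS["gk1"],
}

CURRENT_NAMES = (
    "I_Na", "I_K1", "I_to", "I_Kur", "I_Kr", "I_Ks", "I_CaL",
    "I_NKA", "I_NCX", "I_bNa", "I_bCa", "I_PMCA",
)

# constants shared by both models (original units: s, pA, mM, nL)
R = 8314.0  # mJ/(mol*K)
T = 306.15  # K
F = 96487.0  # C/mol
VOL_I = 0.005884  # nL
VOL_C = 0.000800224
VOL_D = 0.00011768
VOL_UP = 0.0003969
VOL_REL = 0.0000441
TAU_NA, TAU_K, TAU_CA = 14.3, 10.0, 24.7  # cleft-bulk exchange, s
TAU_DI, TAU_TR = 0.01, 0.01  # s
MG_I = 2.5  # mM
E_CA_APP = 60.0  # mV
K_CA = 0.025  # mM
GAMMA_NCX, D_NCX = 0.45, 0.0003
K_NAK_K, K_NAK_NA = 1.0, 11.0
K_CAP = 0.0002
K_CYCA, K_SRCA, K_XCS = 0.0003, 0.5, 0.4
ALPHA_REL = 200000.0  # pA/mM
K_REL_I, K_REL_D = 0.0003, 0.003
R_RECOV = 0.815  # 1/s


def params_nygren() -> np.ndarray:
    return np.array(
        [
            0.0016,  # pna, nL/s
            6.75,  # gcal, nS
            7.5,  # gt, nS
            2.75,  # gkur (= g_sus), nS
            1.0,  # gks, nS
            0.5,  # gkr, nS
            3.0,  # gk1, nS
            0.060599,  # gbna, nS
            0.078681,  # gbca, nS
            70.8253,  # inakmax, pA
            4.0,  # icapmax, pA
            0.0374842,  # knaca, pA/mM^4
            -1.68,  # phinaen, pA (electroneutral Na influx)
            2800.0,  # iupmax, pA
            0.05,  # cm, nF
            130.0,  # nab, mM
            5.4,  # kb, mM
            1.8,  # cab, mM
            0.0,  # ach, mM (Nygren: unused)
        ]
    )


def params_maleckar() -> np.ndarray:
    p = params_nygren()
    p[0] = 0.0018  # pna
    p[2] = 8.25  # gt
    p[3] = 2.25  # gkur (dedicated I_Kur formulation)
    p[6] = 3.1  # gk1
    p[9] = 68.55  # inakmax
    p[12] = 0.0  # electroneutral Na influx removed
    return p


def initial_state() -> np.ndarray:
    """Published resting initial conditions of the parent (Nygren) model;
    the Maleckar variant relaxes from the same rest within the pre-pacing
    every protocol applies."""
    return np.array(
        [
            -74.2525,  # V
            3.2017e-3,  # m
            8.814e-1,  # h1
            8.742e-1,  # h2
            1.3005e-5,  # dL
            9.986e-1,  # fL1
            9.986e-1,  # fL2
            1.0678e-3,  # r
            9.49e-1,  # s
            1.5949e-4,  # rsus
            9.912e-1,  # ssus
            4.8357e-3,  # n
            1.0e-4,  # pa
            1.300115e2,  # Nac
            5.3581,  # Kc
            1.8147,  # Cac
            8.5547,  # Nai
            1.294349e2,  # Ki
            6.729e-5,  # Cai
            7.2495e-5,  # Cad
            2.75e-2,  # OC
            1.33e-2,  # OTC
            1.961e-1,  # OTMgC
            7.094e-1,  # OTMgMg
            4.369e-1,  # OCalse
            6.646e-1,  # Caup
            6.465e-1,  # Carel
            4.284e-1,  # F1
            2.8e-3,  # F2
        ]
    )


def _make_core(maleckar: bool):
    """Compile the rate function; ``maleckar`` switches the I_to/I_Kur
    kinetics, drops the electroneutral Na influx (via its parameter) and
    enables I_KACh."""

    @njit(fastmath=FASTMATH)
    def core(st, p, istim, d, yinf, tau):
        (pna, gcal, gt, gkur, gks, gkr, gk1, gbna, gbca, inakmax, icapmax,
         knaca, phinaen, iupmax, cm, nab, kb, cab, ach) = (
            p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9],
            p[10], p[11], p[12], p[13], p[14], p[15], p[16], p[17], p[18],
        )
        V = st[0]
        m, h1, h2 = st[1], st[2], st[3]
        dL, fL1, fL2 = st[4], st[5], st[6]
        rg, sg, rsus, ssus = st[7], st[8], st[9], st[10]
        n, pa = st[11], st[12]
        nac, kc, cac = st[13], st[14], st[15]
        nai, ki, cai, cad = st[16], st[17], st[18], st[19]
        oc, otc, otmgc, otmgmg, ocalse = st[20], st[21], st[22], st[23], st[24]
        caup, carel, f1, f2 = st[25], st[26], st[27], st[28]

        rtf = R * T / F
        ena = rtf * np.log(nac / nai)
        ek = rtf * np.log(kc / ki)
        eca = 0.5 * rtf * np.log(cac / cai)

        # --- membrane currents (pA) ---
        vff = V * F / (R * T)
        expv = np.exp(vff)
        # GHK flux; the V/(exp(VF/RT)-1) factor tends to RT/F at V = 0
        if np.abs(vff) < 1e-7:
            vfac = R * T / F
        else:
            vfac = V / (expv - 1.0)
        ina = (
            pna * m * m * m * (0.9 * h1 + 0.1 * h2) * nac * vfac * F * F / (R * T)
            * (np.exp((V - ena) * F / (R * T)) - 1.0)
        )
        fca = cad / (cad + K_CA)
        ical = gcal * dL * (fca * fL1 + (1.0 - fca) * fL2) * (V - E_CA_APP)
        it = gt * rg * sg * (V - ek)
        ikur = gkur * rsus * ssus * (V - ek)
        iks = gks * n * (V - ek)
        pi_kr = 1.0 / (1.0 + np.exp((V + 55.0) / 24.0))
        ikr = gkr * pa * pi_kr * (V - ek)
        ik1 = (
            gk1
            * np.power(kc, 0.4457)
            * (V - ek)
            / (1.0 + np.exp(1.5 * (V - ek + 3.6) * F / (R * T)))
        )
        ibna = gbna * (V - ena)
        ibca = gbca * (V - eca)
        inak = (
            inakmax
            * kc / (kc + K_NAK_K)
            * nai ** 1.5 / (nai ** 1.5 + K_NAK_NA ** 1.5)
            * (V + 150.0) / (V + 200.0)
        )
        icap = icapmax * cai / (cai + K_CAP)
        inaca = (
            knaca
            * (
                nai ** 3 * cac * np.exp(GAMMA_NCX * vff)
                - nac ** 3 * cai * np.exp((GAMMA_NCX - 1.0) * vff)
            )
            / (1.0 + D_NCX * (nac ** 3 * cai + nai ** 3 * cac))
        )
        ikach = 0.0
        if maleckar and ach > 0.0:
            ikach = (
                10.0 / (1.0 + 9.13652 / np.power(ach, 0.477811))
                * (0.0517 + 0.4516 / (1.0 + np.exp((V + 59.53) / 17.18)))
                * (V - ek)
                * cm
            )

        # --- SR and diadic fluxes (pA-equivalent) ---
        iup = (
            iupmax
            * (cai / K_CYCA - K_XCS * K_XCS * caup / K_SRCA)
            / ((cai + K_CYCA) / K_CYCA + K_XCS * (caup + K_SRCA) / K_SRCA)
        )
        itr = (caup - carel) * 2.0 * F * VOL_REL / TAU_TR
        f2frac = f2 / (f2 + 0.25)
        irel = ALPHA_REL * f2frac * f2frac * (carel - cai)
        idi = (cad - cai) * 2.0 * F * VOL_D / TAU_DI

        acti = (cai / (cai + K_REL_I)) ** 4
        actd = (cad / (cad + K_REL_D)) ** 4
        ract = 203.8 * (acti + actd)
        rinact = 33.96 + 339.6 * acti

        # --- gate kinetics (s; converted to ms below) ---
        yinf[1] = 1.0 / (1.0 + np.exp(-(V + 27.12) / 8.21))
        dv = (V + 25.57) / 28.8
        tau[1] = 4.2e-5 * np.exp(-dv * dv) + 2.4e-5
        hinf = 1.0 / (1.0 + np.exp((V + 63.6) / 5.3))
        yinf[2] = hinf
        yinf[3] = hinf
        hden = 1.0 + np.exp((V + 35.1) / 3.2)
        tau[2] = 0.03 / hden + 0.0003
        tau[3] = 0.12 / hden + 0.003
        yinf[4] = 1.0 / (1.0 + np.exp(-(V + 9.0) / 5.8))
        dv = (V + 35.0) / 30.0
        tau[4] = 0.0027 * np.exp(-dv * dv) + 0.002
        flinf = 1.0 / (1.0 + np.exp((V + 27.4) / 7.1))
        yinf[5] = flinf
        yinf[6] = flinf
        dv = (V + 40.0) / 14.4
        tau[5] = 0.161 * np.exp(-dv * dv) + 0.01
        dv = (V + 40.0) / 14.2
        tau[6] = 1.3323 * np.exp(-dv * dv) + 0.0626
        # transient outward gates
        yinf[7] = 1.0 / (1.0 + np.exp(-(V - 1.0) / 11.0))
        dv = V / 30.0
        tau[7] = 0.0035 * np.exp(-dv * dv) + 0.0015
        yinf[8] = 1.0 / (1.0 + np.exp((V + 40.5) / 11.5))
        if maleckar:
            dv = (V + 52.45) / 15.8827
            tau[8] = 0.025635 * np.exp(-dv * dv) + 0.01414
        else:
            dv = (V + 52.45) / 14.97
            tau[8] = 0.4812 * np.exp(-dv * dv) + 0.01414
        # sustained outward (Nygren I_sus) / ultrarapid (Maleckar I_Kur)
        if maleckar:
            yinf[9] = 1.0 / (1.0 + np.exp(-(V + 6.0) / 8.6))
            tau[9] = 0.009 / (1.0 + np.exp((V + 5.0) / 12.0)) + 0.0005
            yinf[10] = 1.0 / (1.0 + np.exp((V + 7.5) / 10.0))
            tau[10] = 0.59 / (1.0 + np.exp((V + 60.0) / 10.0)) + 3.05
        else:
            yinf[9] = 1.0 / (1.0 + np.exp(-(V + 4.3) / 8.0))
            tau[9] = 0.009 / (1.0 + np.exp((V + 5.0) / 12.0)) + 0.0005
            yinf[10] = 0.4 / (1.0 + np.exp((V + 20.0) / 10.0)) + 0.6
            tau[10] = 0.047 / (1.0 + np.exp((V + 60.0) / 10.0)) + 0.3
        yinf[11] = 1.0 / (1.0 + np.exp(-(V - 19.9) / 12.7))
        dv = (V - 20.0) / 20.0
        tau[11] = 0.7 + 0.4 * np.exp(-dv * dv)
        yinf[12] = 1.0 / (1.0 + np.exp(-(V + 15.0) / 6.0))
        dv = (V + 20.1376) / 22.1996
        tau[12] = 0.03118 + 0.21718 * np.exp(-dv * dv)
        for g in range(1, 13):
            tau[g] = tau[g] * 1000.0  # s -> ms
            d[g] = (yinf[g] - st[g]) / tau[g]

        # --- buffer ODEs (1/s) ---
        doc = 200000.0 * cai * (1.0 - oc) - 476.0 * oc
        dotc = 78400.0 * cai * (1.0 - otc) - 392.0 * otc
        dotmgc = 200000.0 * cai * (1.0 - otmgc - otmgmg) - 6.6 * otmgc
        dotmgmg = 2000.0 * MG_I * (1.0 - otmgc - otmgmg) - 666.0 * otmgmg
        docalse = 480.0 * carel * (1.0 - ocalse) - 400.0 * ocalse

        # --- balances (per second, converted to per ms at the end) ---
        itot = (
            ina + ical + it + ikur + ik1 + ikr + iks + ibna + ibca
            + inak + icap + inaca + ikach
        )
        dvdt = -itot / cm * 1e-3  # pA/nF = mV/s -> mV/ms
        d[0] = dvdt + istim

        inatot = ina + ibna + 3.0 * inak + 3.0 * inaca + phinaen
        iktot = it + ikur + ik1 + ikr + iks + ikach - 2.0 * inak
        # cytosolic Ca balance excludes I_CaL (L-type flux enters the diadic
        # space); the cleft sees the full sarcolemmal Ca flux including it
        icatot = ibca + icap - 2.0 * inaca
        icatot_cleft = ical + icatot

        d[13] = ((nab - nac) / TAU_NA + inatot / (VOL_C * F)) * 1e-3
        d[14] = ((kb - kc) / TAU_K + iktot / (VOL_C * F)) * 1e-3
        d[15] = ((cab - cac) / TAU_CA + icatot_cleft / (2.0 * VOL_C * F)) * 1e-3
        d[16] = -inatot / (VOL_I * F) * 1e-3
        d[17] = -iktot / (VOL_I * F) * 1e-3
        dodt_ca = 0.045 * doc + 0.08 * dotc + 0.16 * dotmgc
        d[18] = (
            -(icatot + iup - irel - idi) / (2.0 * VOL_I * F) - dodt_ca
        ) * 1e-3
        d[19] = -(ical + idi) / (2.0 * VOL_D * F) * 1e-3
        d[20] = doc * 1e-3
        d[21] = dotc * 1e-3
        d[22] = dotmgc * 1e-3
        d[23] = dotmgmg * 1e-3
        d[24] = docalse * 1e-3
        d[25] = (iup - itr) / (2.0 * VOL_UP * F) * 1e-3
        d[26] = ((itr - irel) / (2.0 * VOL_REL * F) - 31.0 * docalse) * 1e-3
        d[27] = (R_RECOV * (1.0 - f1 - f2) - ract * f1) * 1e-3
        d[28] = (ract * f1 - rinact * f2) * 1e-3

    return core


def _make_currents():
    @njit(fastmath=FASTMATH)
    def currents(st, p, out):
        """Sarcolemmal currents (pA), order per CURRENT_NAMES."""
        (pna, gcal, gt, gkur, gks, gkr, gk1, gbna, gbca, inakmax, icapmax,
         knaca) = (
            p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9],
            p[10], p[11],
        )
        V = st[0]
        m, h1, h2 = st[1], st[2], st[3]
        dL, fL1, fL2 = st[4], st[5], st[6]
        rg, sg, rsus, ssus = st[7], st[8], st[9], st[10]
        n, pa = st[11], st[12]
        nac, kc, cac = st[13], st[14], st[15]
        nai, ki, cai, cad = st[16], st[17], st[18], st[19]
        rtf = R * T / F
        ena = rtf * np.log(nac / nai)
        ek = rtf * np.log(kc / ki)
        eca = 0.5 * rtf * np.log(cac / cai)
        vff = V * F / (R * T)
        if np.abs(vff) < 1e-7:
            vfac = R * T / F
        else:
            vfac = V / (np.exp(vff) - 1.0)
        out[0] = (
            pna * m * m * m * (0.9 * h1 + 0.1 * h2) * nac * vfac * F * F / (R * T)
            * (np.exp((V - ena) * F / (R * T)) - 1.0)
        )
        out[1] = (
            gk1 * np.power(kc, 0.4457) * (V - ek)
            / (1.0 + np.exp(1.5 * (V - ek + 3.6) * F / (R * T)))
        )
        out[2] = gt * rg * sg * (V - ek)
        out[3] = gkur * rsus * ssus * (V - ek)
        out[4] = gkr * pa * (V - ek) / (1.0 + np.exp((V + 55.0) / 24.0))
        out[5] = gks * n * (V - ek)
        fca = cad / (cad + K_CA)
        out[6] = gcal * dL * (fca * fL1 + (1.0 - fca) * fL2) * (V - E_CA_APP)
        out[7] = (
            inakmax * kc / (kc + K_NAK_K)
            * nai ** 1.5 / (nai ** 1.5 + K_NAK_NA ** 1.5)
            * (V + 150.0) / (V + 200.0)
        )
        out[8] = (
            knaca
            * (
                nai ** 3 * cac * np.exp(GAMMA_NCX * vff)
                - nac ** 3 * cai * np.exp((GAMMA_NCX - 1.0) * vff)
            )
            / (1.0 + D_NCX * (nac ** 3 * cai + nai ** 3 * cac))
        )
        out[9] = gbna * (V - ena)
        out[10] = gbca * (V - eca)
        out[11] = icapmax * cai / (cai + K_CAP)

    return currents


_CORE_N = _make_core(False)
_CORE_M = _make_core(True)
_CURRENTS = _make_currents()
_STEP_N = make_stepper(_CORE_N, len(STATE_NAMES), GATES)
_STEP_M = make_stepper(_CORE_M, len(STATE_NAMES), GATES)


def _build(name: str, core, step, params) -> IonicModel:
    return IonicModel(
        name=name,
        variant="control",
        state_names=STATE_NAMES,
        state_units=STATE_UNITS,
        param_names=PARAM_NAMES,
        params=params,
        initial_state=initial_state(),
        gating_index=GATES.copy(),
        stiff_index=np.empty(0, dtype=np.int64),
        current_names=CURRENT_NAMES,
        cai_index=CAI,
        cm=50.0,
        caf_scaling=CAF_SCALING,
        core=core,
        step=step,
        currents_fn=_CURRENTS,
    )


def build_nygren() -> IonicModel:
    return _build("nygren", _CORE_N, _STEP_N, params_nygren())


def build_maleckar() -> IonicModel:
    return _build("maleckar", _CORE_M, _STEP_M, params_maleckar())
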