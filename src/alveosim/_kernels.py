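"""Numba inner loops for the breath-by-breath simulation.

``run_breaths`` advances the compartmental mechanics over a block of
identical pressure-controlled breaths (or constant-pressure CPAP chunks)
with per-step recruitment timers and per-breath end-expiratory
derecruitment.  ``solve_breath_gas`` computes the quasi-steady alveolar gas
and end-capillary blood of every compartment for one breath by a vectorised
bisection on the per-compartment O2 and CO2 mass balances.

These kernels mirror the reference implementations in
:mod:`alveosim.mechanics`; equivalence is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .blood import _co2_content_auto, _invert_pco2, _invert_po2, _kelman_sat, _o2_content, _ph_hh

#: conversion factor between gas tension balance and volume flux
#: (PACO2 = 863 * VCO2 / VA with VA in ml/min, VCO2 in ml/min STPD)
K_GAS = 863.0


@njit(cache=True)
def run_breaths(
    # parameters
    k, k2, k3, pext, top, pclose, raw, tauc,
    # state (modified in place)
    vol, is_open, timer, maxp,
    # waveform: square wave peep/(peep+dp), inspiratory time ti of ttot
    peep, dp, ti, ttot, n_breaths, dt,
    # outputs (n_breaths x n), preallocated
    out_inhaled, out_open, out_palv_mean, out_palv_peak,
    out_vt, out_ppk, out_peep_alv,
):
    n = k.shape[0]
    n_steps = max(int(round(ttot / dt)), 1)
    n_insp = int(round(ti / dt))
    for b in range(n_breaths):
        for i in range(n):
            out_inhaled[b, i] = 0.0
            out_palv_mean[b, i] = 0.0
        vt_acc = 0.0
        for s in range(n_steps):
            insp = s < n_insp
            paw = peep + dp if insp else peep
            for i in range(n):
                if is_open[i]:
                    palv = (pext[i] + k[i] * vol[i] + k2[i] * vol[i] ** 2
                            + k3[i] * vol[i] ** 3)
                    flow = (paw - palv) / raw[i]
                    v = vol[i] + flow * dt
                    if v < 0.0:
                        v = 0.0
                    if insp and v > vol[i]:
                        out_inhaled[b, i] += v - vol[i]
                    vol[i] = v
                    palv = (pext[i] + k[i] * vol[i] + k2[i] * vol[i] ** 2
                            + k3[i] * vol[i] ** 3)
                    if palv > maxp[i]:
                        maxp[i] = palv
                    out_palv_mean[b, i] += palv
                else:
                    # opening timer against TOP, reset below threshold
                    if paw > top[i]:
                        timer[i] += dt
                        if timer[i] >= tauc[i]:
                            is_open[i] = True
                            vol[i] = 0.0
                            timer[i] = 0.0
                    else:
                        timer[i] = 0.0
                    out_palv_mean[b, i] += pext[i]
        # end-expiration bookkeeping and cliff-edge derecruitment
        vt = 0.0
        for i in range(n):
            out_palv_mean[b, i] /= n_steps
            vt += out_inhaled[b, i]
            palv = (pext[i] + k[i] * vol[i] + k2[i] * vol[i] ** 2
                    + k3[i] * vol[i] ** 3)
            out_peep_alv[b, i] = palv if is_open[i] else pext[i]
            if is_open[i] and palv < pclose[i]:
                is_open[i] = False
                vol[i] = 0.0
                timer[i] = 0.0
            out_open[b, i] = is_open[i]
            out_palv_peak[b, i] = maxp[i]
        out_vt[b] = vt
        # running top-20% mean of per-compartment maxima
        m = (n + 4) // 5
        srt = np.sort(maxp)[::-1]
        acc = 0.0
        for j in range(m):
            acc += srt[j]
        out_ppk[b] = acc / m


@njit(cache=True)
def solve_breath_gas(
    va, q_flux, open_mask,
    fio2, pb, temp, hco3, hb,
    cvo2, cvco2, pvo2, pvco2,
    pao2_out, paco2_out, cco2_out, ccco2_out,
):
    """Quasi-steady alveolar gas per compartment.

    va : fresh alveolar ventilation per compartment, ml/min
    q_flux : blood flow through each compartment in dl/min
        (10 * cardiac output [l/min] * flow fraction), so that
        q_flux * (content difference in ml/dl) is a gas flux in ml/min
    Outputs per compartment: alveolar PO2/PCO2 and end-capillary O2/CO2
    contents.  Unventilated or collapsed compartments equilibrate to venous
    blood (pure shunt).
    """
    n = va.shape[0]
    pio2 = fio2 * (pb - 47.0)
    for i in range(n):
        if (not open_mask[i]) or va[i] < 1e-9:
            pao2_out[i] = pvo2
            paco2_out[i] = pvco2
            cco2_out[i] = cvo2
            ccco2_out[i] = cvco2
            continue
        if q_flux[i] < 1e-12:
            # ventilated but unperfused: alveolar dead space
            pao2_out[i] = pio2
            paco2_out[i] = 0.0
            cco2_out[i] = _o2_content(pio2, 1.0, _ph_hh(1.0, hco3), temp, hb)
            ccco2_out[i] = 0.0
            continue
        qi = q_flux[i]  # dl/min through this compartment
        paco2 = pvco2 * 0.8
        pao2 = pio2 * 0.5
        for _ in range(2):
            # O2 balance: va*(PIO2-PAO2)/863 = 10*q*CO*(Cc'O2 - CvO2)
            lo = 0.5
            hi = pio2
            ph = _ph_hh(paco2, hco3)
            for _ in range(45):
                mid = 0.5 * (lo + hi)
                uptake_gas = va[i] * (pio2 - mid) / K_GAS
                uptake_blood = qi * (_o2_content(mid, paco2, ph, temp, hb) - cvo2)
                if uptake_gas - uptake_blood > 0.0:
                    lo = mid
                else:
                    hi = mid
            pao2 = 0.5 * (lo + hi)
            # CO2 balance: va*PACO2/863 = 10*q*CO*(CvCO2 - Cc'CO2)
            so2 = _kelman_sat(pao2, paco2, ph, temp)
            lo = 0.05
            hi = pvco2 + 1.0
            for _ in range(45):
                mid = 0.5 * (lo + hi)
                elim_gas = va[i] * mid / K_GAS
                elim_blood = qi * (cvco2 - _co2_content_auto(mid, so2, hb, temp, hco3))
                if elim_gas - elim_blood < 0.0:
                    lo = mid
                else:
                    hi = mid
            paco2 = 0.5 * (lo + hi)
        ph = _ph_hh(paco2, hco3)
        so2 = _kelman_sat(pao2, paco2, ph, temp)
        pao2_out[i] = pao2
        paco2_out[i] = paco2
        cco2_out[i] = _o2_content(pao2, paco2, ph, temp, hb)
        ccco2_out[i] = _co2_content_auto(paco2, so2, hb, temp, hco3)


@njit(cache=True)
def mix_and_invert(q_frac, cco2, ccco2, hb, temp, hco3):
    """Perfusion-weighted arterial contents and recovered tensions."""
    n = q_frac.shape[0]
    cao2 = 0.0
    caco2 = 0.0
    for i in range(n):
        cao2 += q_frac[i] * cco2[i]
        caco2 += q_frac[i] * ccco2[i]
    so2 = 0.95
    paco2 = 40.0
    pao2 = 90.0
    for _ in range(3):
        paco2 = _invert_pco2(caco2, so2, hb, temp, hco3)
        pao2 = _invert_po2(cao2, paco2, hb, temp, hco3)
        so2 = _kelman_sat(pao2, paco2, _ph_hh(paco2, hco3), temp)
    return cao2, caco2, pao2, paco2, so2
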