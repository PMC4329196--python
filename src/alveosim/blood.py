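"""Blood oxygen and carbon dioxide chemistry.

Implements the standard adult correlations used throughout clinical gas
exchange modelling:

* oxyhaemoglobin saturation — Kelman's rational-polynomial fit to the adult
  dissociation curve, with the classic "virtual PO2" correction for the Bohr
  effect (pH, PCO2) and temperature;
* whole-blood CO2 content — the Douglas correlation (plasma CO2 content from
  Henderson-Hasselbalch, corrected to whole blood with a saturation-dependent
  Haldane term);
* pH — Henderson-Hasselbalch at a fixed metabolic state (constant plasma
  bicarbonate, i.e. zero base excess by default).

All tensions are in mmHg, contents in ml dl^-1, haemoglobin in g dl^-1,
temperature in degC.  The scalar cores are numba-compiled because they sit
inside the per-compartment alveolar gas solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "BloodSample",
    "o2_saturation",
    "o2_content",
    "co2_content",
    "ph_from_pco2",
    "make_blood_sample",
    "blood_from_contents",
    "HB_O2_CAPACITY",
    "O2_SOLUBILITY",
]

#: ml O2 bound per gram of fully saturated haemoglobin
HB_O2_CAPACITY = 1.34
#: ml O2 physically dissolved per dl blood per mmHg
O2_SOLUBILITY = 0.003
#: plasma bicarbonate (mmol l^-1) at PCO2 40, zero base excess
DEFAULT_HCO3 = 24.0
#: acute whole-blood buffer line: bicarbonate generated per mmHg PCO2 by
#: non-bicarbonate buffers (chiefly haemoglobin); gives the in vitro
#: whole-blood CO2 dissociation slope of ~0.4 ml dl^-1 mmHg^-1 near the
#: arterial point and a physiological a-v PCO2 difference of ~4 mmHg
BUFFER_SLOPE = 0.15
#: ml of CO2 gas (STPD) per mmol
_ML_PER_MMOL = 22.26


@njit(cache=True)
def _ph_hh(pco2: float, hco3: float) -> float:
    if pco2 < 1e-6:
        pco2 = 1e-6
    hco3_eff = hco3 + BUFFER_SLOPE * (pco2 - 40.0)
    if hco3_eff < 8.0:
        hco3_eff = 8.0
    return 6.1 + math.log10(hco3_eff / (0.0301 * pco2))


@njit(cache=True)
def _kelman_sat(po2: float, pco2: float, ph: float, temp: float) -> float:
    if po2 <= 0.0:
        return 0.0
    if pco2 < 1e-6:
        pco2 = 1e-6
    # virtual PO2: shifts the standard curve for temperature, pH and PCO2
    x = po2 * 10.0 ** (
        0.024 * (37.0 - temp)
        + 0.40 * (ph - 7.4)
        + 0.06 * (math.log10(40.0) - math.log10(pco2))
    )
    if x < 10.0:
        s = x * (0.003683 + 0.000584 * x)
    else:
        a1 = -8532.2289
        a2 = 2121.401
        a3 = -67.073989
        a4 = 935960.87
        a5 = -31346.258
        a6 = 2396.1674
        a7 = -67.104406
        num = x * (a1 + x * (a2 + x * (a3 + x)))
        den = a4 + x * (a5 + x * (a6 + x * (a7 + x)))
        s = num / den
    if s < 0.0:
        s = 0.0
    elif s > 1.0:
        s = 1.0
    return s


@njit(cache=True)
def _o2_content(po2: float, pco2: float, ph: float, temp: float, hb: float) -> float:
    return HB_O2_CAPACITY * hb * _kelman_sat(po2, pco2, ph, temp) + O2_SOLUBILITY * po2


@njit(cache=True)
def _co2_blood(pco2: float, so2: float, hb: float, ph: float, temp: float) -> float:
    if pco2 <= 0.0:
        return 0.0
    pk = 6.086 + 0.042 * (7.4 - ph) + (38.0 - temp) * (0.00472 + 0.00139 * (7.4 - ph))
    sol = 0.0307 + 0.00057 * (37.0 - temp) + 0.00002 * (37.0 - temp) ** 2
    cp = sol * pco2 * (1.0 + 10.0 ** (ph - pk))  # plasma, mmol/l
    # Haldane correction: deoxygenated haemoglobin carries more CO2
    hald = 1.0 - 0.0289 * hb / ((3.352 - 0.456 * so2) * (8.142 - ph))
    return cp * hald * _ML_PER_MMOL / 10.0  # ml/dl


@njit(cache=True)
def _co2_content_auto(pco2: float, so2: float, hb: float, temp: float, hco3: float) -> float:
    return _co2_blood(pco2, so2, hb, _ph_hh(pco2, hco3), temp)


@njit(cache=True)
def _invert_pco2(content: float, so2: float, hb: float, temp: float, hco3: float) -> float:
    """PCO2 such that whole-blood CO2 content matches, pH self-consistent."""
    if content <= 0.0:
        return 0.0
    lo, hi = 0.05, 250.0
    if _co2_content_auto(hi, so2, hb, temp, hco3) < content:
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _co2_content_auto(mid, so2, hb, temp, hco3) < content:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@njit(cache=True)
def _invert_po2(content: float, pco2: float, hb: float, temp: float, hco3: float) -> float:
    """PO2 such that O2 content matches at the given PCO2."""
    ph = _ph_hh(pco2, hco3)
    if content <= 0.0:
        return 0.0
    lo, hi = 0.0, 800.0
    if _o2_content(hi, pco2, ph, temp, hb) < content:
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _o2_content(mid, pco2, ph, temp, hb) < content:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class BloodSample:
    """Gas tensions, saturation and gas contents of a blood sample.

    Attributes
    ----------
    po2, pco2:
        Gas tensions (mmHg).
    so2:
        Fractional haemoglobin O2 saturation in [0, 1].
    o2_content, co2_content:
        Gas contents (ml dl^-1).
    """

    po2: float
    pco2: float
    so2: float
    o2_content: float
    co2_content: float


def o2_saturation(po2: float, pco2: float = 40.0, ph: float = 7.4, temp: float = 37.0) -> float:
    """Fractional oxyhaemoglobin saturation (Kelman correlation).

    Monotone increasing in PO2, bounded in [0, 1]; Bohr and temperature
    shifts applied through the virtual-PO2 transformation.
    """
    if po2 < 0:
        raise ValueError("PO2 must be non-negative")
    return float(_kelman_sat(float(po2), float(pco2), float(ph), float(temp)))


def o2_content(po2: float, hb: float, pco2: float = 40.0, ph: float = 7.4,
               temp: float = 37.0) -> float:
    """Whole-blood O2 content (ml dl^-1): bound plus dissolved."""
    return float(_o2_content(float(po2), float(pco2), float(ph), float(temp), float(hb)))


def co2_content(pco2: float, so2: float, hb: float, ph: float | None = None,
                temp: float = 37.0, hco3: float = DEFAULT_HCO3) -> float:
    """Whole-blood CO2 content (ml dl^-1), Douglas correlation.

    If ``ph`` is omitted it is computed from PCO2 by Henderson-Hasselbalch
    at the fixed bicarbonate ``hco3``.  Monotone increasing in PCO2 and,
    through the Haldane term, decreasing in SO2.
    """
    if pco2 < 0:
        raise ValueError("PCO2 must be non-negative")
    if ph is None:
        ph = _ph_hh(float(pco2), float(hco3))
    return float(_co2_blood(float(pco2), float(so2), float(hb), float(ph), float(temp)))


def ph_from_pco2(pco2: float, hco3: float = DEFAULT_HCO3) -> float:
    """Plasma pH from PCO2 at fixed bicarbonate (zero base excess)."""
    return float(_ph_hh(float(pco2), float(hco3)))


def make_blood_sample(po2: float, pco2: float, hb: float, temp: float = 37.0,
                      hco3: float = DEFAULT_HCO3) -> BloodSample:
    """Construct a fully populated :class:`BloodSample` from tensions."""
    ph = _ph_hh(float(pco2), float(hco3))
    s = _kelman_sat(float(po2), float(pco2), ph, float(temp))
    return BloodSample(
        po2=float(po2),
        pco2=float(pco2),
        so2=float(s),
        o2_content=float(_o2_content(float(po2), float(pco2), ph, float(temp), float(hb))),
        co2_content=float(_co2_blood(float(pco2), float(s), float(hb), ph, float(temp))),
    )


def blood_from_contents(o2c: float, co2c: float, hb: float, temp: float = 37.0,
                        hco3: float = DEFAULT_HCO3) -> BloodSample:
    """Recover tensions from O2 and CO2 contents.

    The inversion alternates between the two gases because CO2 content
    depends on saturation (Haldane) and saturation depends on PCO2 (Bohr);
    two sweeps converge to well below measurement precision.
    """
    so2 = 0.9
    pco2 = 40.0
    po2 = 90.0
    for _ in range(4):
        pco2 = _invert_pco2(float(co2c), so2, float(hb), float(temp), float(hco3))
        po2 = _invert_po2(float(o2c), pco2, float(hb), float(temp), float(hco3))
        so2 = _kelman_sat(po2, pco2, _ph_hh(pco2, float(hco3)), float(temp))
    return BloodSample(po2=float(po2), pco2=float(pco2), so2=float(so2),
                       o2_content=float(o2c), co2_content=float(co2c))
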