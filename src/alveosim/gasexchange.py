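"""Per-compartment gas exchange, perfusion distribution and Fick coupling.

Blood leaving every *open* compartment equilibrates with that compartment's
alveolar gas, which is itself the quasi-steady solution of the compartment's
ventilation/perfusion mass balance.  Collapsed compartments pass mixed
venous blood through unchanged (true shunt).  Arterial blood is the
perfusion-weighted mixture of *contents* (never tensions); arterial tensions
are recovered by inverting the content relations.  Mixed venous blood
follows from the Fick principle at fixed cardiac output, with a first-order
venous-pool mixing delay so that PaO2 transients over minutes are resolved.

Perfusion is distributed in proportion to per-compartment vascular
conductance, modulated by

* hypoxic pulmonary vasoconstriction (HPV): a sigmoid reduction of
  conductance at low alveolar PO2 (half-effect 40 mmHg), and
* a distension factor reducing conductance of highly pressurised
  compartments (West-zone-like capillary compression), which creates
  alveolar dead space at high airway pressures and reproduces the initial
  PaCO2 rise when ventilator pressure increases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import blood as _blood
from ._kernels import mix_and_invert, solve_breath_gas
from .blood import BloodSample, blood_from_contents, make_blood_sample
from .mechanics import LungParams, LungState

__all__ = [
    "MetabolicParams",
    "PerfusionState",
    "GasExchangeConfig",
    "o2_saturation",
    "co2_content",
    "distribute_perfusion",
    "compartment_alveolar_gas",
    "mix_arterial",
    "shunt_fraction",
    "venous_from_fick",
    "NonphysicalBloodState",
]

# re-exported chemistry primitives (part of this module's surface)
o2_saturation = _blood.o2_saturation
co2_content = _blood.co2_content


class NonphysicalBloodState(ValueError):
    """Raised when the Fick balance leaves no oxygen in venous blood."""


@dataclass(frozen=True)
class MetabolicParams:
    """Whole-body metabolic and circulatory constants.

    hb g/dl, co (cardiac output) l/min, vo2 ml/min, rq dimensionless,
    fio2 fraction, temp degC, pb (barometric pressure) mmHg.
    """

    hb: float
    co: float
    vo2: float
    rq: float
    fio2: float
    temp: float = 37.0
    pb: float = 760.0
    hco3: float = _blood.DEFAULT_HCO3

    def __post_init__(self) -> None:
        if min(self.hb, self.co, self.vo2, self.fio2, self.pb) <= 0:
            raise ValueError("metabolic parameters must be positive")
        if not 0 < self.fio2 <= 1:
            raise ValueError("FiO2 must be in (0, 1]")
        if not 0.5 <= self.rq <= 1.1:
            raise ValueError("RQ outside fitting bounds [0.5, 1.1]")


@dataclass
class PerfusionState:
    """Per-compartment blood-flow fractions (sum to one)."""

    q: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.q < 0):
            raise ValueError("flow fractions must be non-negative")
        s = self.q.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError("flow fractions must sum to 1")

    def shunt_flow(self, open_mask: np.ndarray) -> float:
        """Fraction of cardiac output through collapsed compartments."""
        return float(self.q[~np.asarray(open_mask, bool)].sum())


@dataclass(frozen=True)
class GasExchangeConfig:
    """Structural constants of the gas-exchange model."""

    hpv_enabled: bool = True
    hpv_half: float = 40.0      # mmHg alveolar PO2 at half effect
    hpv_exponent: float = 3.0
    hpv_max_reduction: float = 0.5
    distension_enabled: bool = True
    distension_p_half: float = 25.0  # cm H2O mean alveolar pressure
    distension_exponent: float = 3.0
    v_dead: float = 140.0       # ml series (anatomical + apparatus) dead space
    vd_paw_slope: float = 4.0   # ml per cm H2O: conducting-airway distension
    vd_paw_cap: float = 16.0    # cm H2O at which airway distension saturates
    venous_tau: float = 30.0    # s, venous-pool mixing time constant

    def v_dead_at(self, mean_paw: float) -> float:
        """Series dead space grows with mean airway pressure (airway
        distension, saturating once the conducting airways are fully
        dilated); one mechanism behind the PaCO2 rise at high PEEP."""
        return self.v_dead + self.vd_paw_slope * min(max(mean_paw, 0.0),
                                                     self.vd_paw_cap)


def _hpv_factor(pao2: np.ndarray, cfg: GasExchangeConfig) -> np.ndarray:
    if not cfg.hpv_enabled:
        return np.ones_like(pao2)
    p = np.maximum(pao2, 1e-6)
    sig = 1.0 / (1.0 + (p / cfg.hpv_half) ** cfg.hpv_exponent)
    return 1.0 - cfg.hpv_max_reduction * sig


def _distension_factor(p_alv: np.ndarray, cfg: GasExchangeConfig) -> np.ndarray:
    if not cfg.distension_enabled:
        return np.ones_like(p_alv)
    p = np.maximum(p_alv, 0.0)
    return 1.0 / (1.0 + (p / cfg.distension_p_half) ** cfg.distension_exponent)


def distribute_perfusion(state: LungState, params: LungParams,
                         alveolar_po2: np.ndarray,
                         cfg: GasExchangeConfig = GasExchangeConfig(),
                         p_alv_mean: np.ndarray | None = None) -> PerfusionState:
    """Distribute cardiac output over compartments.

    Flow is proportional to vascular conductance 1/r_vasc, scaled by the HPV
    factor (low alveolar PO2 diverts flow away) and the distension factor
    (high mean alveolar pressure compresses capillaries).  Collapsed
    compartments keep their conductance — that flow is true shunt.
    """
    if p_alv_mean is None:
        p_alv_mean = state.p_alv
    g = (1.0 / params.r_vasc) * _hpv_factor(np.asarray(alveolar_po2, float), cfg) \
        * _distension_factor(np.asarray(p_alv_mean, float), cfg)
    total = g.sum()
    if total <= 0:
        raise ValueError("all vascular conductances vanished")
    return PerfusionState(q=g / total)


def compartment_alveolar_gas(va: np.ndarray, q_lmin: np.ndarray,
                             open_mask: np.ndarray, venous: BloodSample,
                             metabolic: MetabolicParams) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-steady alveolar PO2/PCO2 per compartment from the V/Q balance.

    ``va`` is fresh alveolar ventilation (ml/min) and ``q_lmin`` blood flow
    (l/min) per compartment.  Compartments without ventilation take venous
    tensions; unperfused compartments approach inspired gas (dead space).
    """
    va = np.asarray(va, float)
    n = len(va)
    pao2 = np.empty(n)
    paco2 = np.empty(n)
    cco2 = np.empty(n)
    ccco2 = np.empty(n)
    solve_breath_gas(
        va, 10.0 * np.asarray(q_lmin, float), np.asarray(open_mask, bool),
        metabolic.fio2, metabolic.pb, metabolic.temp, metabolic.hco3, metabolic.hb,
        venous.o2_content, venous.co2_content, venous.po2, venous.pco2,
        pao2, paco2, cco2, ccco2,
    )
    return pao2, paco2


def mix_arterial(state: LungState, params: LungParams, perfusion: PerfusionState,
                 venous: BloodSample, metabolic: MetabolicParams,
                 va: np.ndarray) -> BloodSample:
    """Arterial blood from perfusion-weighted mixing of end-capillary contents.

    End-capillary blood of each open, ventilated compartment equilibrates to
    that compartment's alveolar gas; collapsed compartments contribute
    unchanged venous blood.  Tensions are recovered by inverting the content
    relations.
    """
    va = np.asarray(va, float)
    n = len(va)
    pao2 = np.empty(n)
    paco2 = np.empty(n)
    cco2 = np.empty(n)
    ccco2 = np.empty(n)
    solve_breath_gas(
        va, 10.0 * metabolic.co * perfusion.q, state.is_open,
        metabolic.fio2, metabolic.pb, metabolic.temp, metabolic.hco3, metabolic.hb,
        venous.o2_content, venous.co2_content, venous.po2, venous.pco2,
        pao2, paco2, cco2, ccco2,
    )
    cao2, caco2, pao2_a, paco2_a, so2 = mix_and_invert(
        perfusion.q, cco2, ccco2, metabolic.hb, metabolic.temp, metabolic.hco3)
    return BloodSample(po2=float(pao2_a), pco2=float(paco2_a), so2=float(so2),
                       o2_content=float(cao2), co2_content=float(caco2))


def shunt_fraction(cc_o2: float, ca_o2: float, cv_o2: float) -> float:
    """Venous admixture Qs/Qt = (Cc'O2 - CaO2) / (Cc'O2 - CvO2)."""
    den = cc_o2 - cv_o2
    if den <= 1e-9:
        raise ValueError("end-capillary content must exceed venous content")
    return (cc_o2 - ca_o2) / den


def venous_from_fick(arterial: BloodSample, metabolic: MetabolicParams) -> BloodSample:
    """Steady-state mixed venous blood from the Fick principle at fixed CO.

    CvO2 = CaO2 - VO2/(10 CO);  CvCO2 = CaCO2 + RQ*VO2/(10 CO)
    (contents ml/dl, CO l/min).  Raises :class:`NonphysicalBloodState` when
    the balance would leave negative venous oxygen content.
    """
    if metabolic.co <= 0:
        raise ValueError("cardiac output must be positive")
    dv = metabolic.vo2 / (10.0 * metabolic.co)
    cvo2 = arterial.o2_content - dv
    cvco2 = arterial.co2_content + metabolic.rq * dv
    if cvo2 < 0:
        raise NonphysicalBloodState(
            "venous O2 content negative: oxygen delivery cannot meet VO2")
    return blood_from_contents(cvo2, cvco2, metabolic.hb,
                               temp=metabolic.temp, hco3=metabolic.hco3)
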