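"""Patient records, parameter distributions and virtual-patient assembly.

Static records for five ARDS patients (labelled A-E) are embedded: measured
haemoglobin, cardiac output and FiO2, the mixed venous and arterial blood-gas
targets used for calibration, and the ventilation settings at which they
were recorded (inspiratory pressure 15 cm H2O, PEEP 5 cm H2O).

A :class:`VirtualPatient` is assembled by sampling per-compartment
mechanical parameters from population distributions described by
:class:`FitParameters`:

* a *healthy* sub-population with near-zero threshold opening pressures
  (normal alveoli do not collapse), and
* a *diseased* fraction — the calibrated "% of compartments collapsed" —
  whose TOPs follow a clipped Gaussian on [6, 60] cm H2O and whose closing
  pressures follow their own clipped Gaussian (typically 5-12 cm H2O),
  giving opening/closing hysteresis;
* log-normal opening time-constants tau_c for the diseased units.

Sampling separates the raw standard-normal draws (fixed per seed) from the
hyper-parameter transform, so calibration can move hyper-parameters smoothly
while the underlying population draw stays frozen.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .gasexchange import MetabolicParams
from .mechanics import LungParams
from .protocols import VentilatorSettings

__all__ = [
    "StaticPatientRecord",
    "FitParameters",
    "UnitDraws",
    "VirtualPatient",
    "load_patients_table1",
    "build_virtual_patient",
    "FIT_BOUNDS",
]


@dataclass(frozen=True)
class StaticPatientRecord:
    """Static blood-gas record of one ARDS patient.

    ``pv`` is the absolute inspiratory ventilator pressure and ``peep`` the
    end-expiratory pressure at which the targets were measured (cm H2O);
    the driving pressure is ``pv - peep``.
    """

    label: str
    hb: float            # g/dl
    co: float            # l/min
    fio2: float
    pvo2: float          # mmHg, mixed venous
    pvco2: float         # mmHg
    qs_qt: float         # %, venous admixture
    pao2: float          # mmHg, arterial
    pv: float = 15.0
    peep: float = 5.0
    # reported calibration outputs / initial guesses
    vr: float = 14.0     # breaths/min
    ie: float = 0.33
    rq: float = 0.7
    vo2: float = 250.0   # ml/min
    collapsed_pct: float = 20.0

    def __post_init__(self) -> None:
        if min(self.pvo2, self.pvco2, self.pao2) <= 0:
            raise ValueError("blood-gas targets must be positive")
        if not 0 < self.qs_qt < 100:
            raise ValueError("Qs/Qt must be in (0, 100) percent")

    @property
    def dp(self) -> float:
        return self.pv - self.peep

    @property
    def pf_ratio(self) -> float:
        """Baseline PaO2/FiO2 (mmHg), the ARDS severity index."""
        return self.pao2 / self.fio2

    def targets(self) -> np.ndarray:
        return np.array([self.pvo2, self.pvco2, self.qs_qt, self.pao2])


_TABLE1 = {
    "A": dict(hb=10.5, co=11.1, fio2=0.8, pvo2=47.3, pvco2=44.4, qs_qt=28.6,
              pao2=153.7, vr=12.25, ie=0.28, rq=0.6, vo2=294.3, collapsed_pct=26),
    "B": dict(hb=10.8, co=7.2, fio2=0.9, pvo2=38.3, pvco2=55.5, qs_qt=31.7,
              pao2=85.5, vr=12.14, ie=0.25, rq=0.6, vo2=300.0, collapsed_pct=29),
    "C": dict(hb=11.5, co=5.6, fio2=0.5, pvo2=48.0, pvco2=47.6, qs_qt=22.6,
              pao2=130.5, vr=16.04, ie=0.38, rq=0.9, vo2=200.0, collapsed_pct=12),
    "D": dict(hb=9.8, co=7.7, fio2=0.8, pvo2=42.83, pvco2=51.0, qs_qt=32.3,
              pao2=110.3, vr=17.68, ie=0.38, rq=0.7, vo2=257.2, collapsed_pct=20),
    "E": dict(hb=9.0, co=5.9, fio2=1.0, pvo2=34.5, pvco2=33.82, qs_qt=43.1,
              pao2=64.5, vr=17.0, ie=0.43, rq=0.61, vo2=246.8, collapsed_pct=21),
}


def load_patients_table1(label: str | None = None):
    """Embedded static records for the five calibration patients A-E.

    Returns the record for ``label``, or a dict of all five when ``label``
    is None.  Unknown labels raise ``KeyError``.
    """
    if label is not None:
        key = label.upper()
        if key not in _TABLE1:
            raise KeyError(f"unknown patient label {label!r} (use A-E)")
        return StaticPatientRecord(label=key, **_TABLE1[key])
    return {k: StaticPatientRecord(label=k, **v) for k, v in _TABLE1.items()}


@dataclass(frozen=True)
class FitParameters:
    """Hyper-parameters describing one virtual patient's population.

    Whole-patient parameters (vr, ie, rq, vo2) plus the distribution
    hyper-parameters from which the 100 per-compartment parameter sets are
    sampled.  Units: pressures cm H2O, stiffness cm H2O/ml, tau_c seconds
    (log-space hyper-parameters are natural logs).
    """

    vr: float = 14.0
    ie: float = 0.33
    rq: float = 0.7
    vo2: float = 250.0
    collapsed_frac: float = 0.20   # diseased fraction of compartments
    top_mean: float = 18.0
    top_sd: float = 9.0
    close_mean: float = 7.5
    close_sd: float = 1.5
    pext_mean: float = 1.5
    pext_sd: float = 0.5
    k_mean: float = 0.1
    k_sd_rel: float = 0.12
    k2_mean: float = 0.075
    k3_mean: float = 1.0e-4
    raw_mean: float = 0.5
    tauc_log_mean: float = 4.5     # ln seconds; exp(4.5) ~ 90 s
    tauc_log_sd: float = 0.8
    w_vasc_diseased: float = 1.1   # relative conductance of diseased units

    def replace(self, **kw) -> "FitParameters":
        return replace(self, **kw)


#: physiological bounds for the calibrated parameters (documented defaults)
FIT_BOUNDS = {
    "vr": (8.0, 25.0),
    "rq": (0.5, 1.1),
    "vo2": (150.0, 400.0),
    "collapsed_frac": (0.02, 0.60),
    "k_mean": (0.05, 0.6),
    "w_vasc_diseased": (0.85, 1.35),
    "tauc_log_mean": (np.log(5.0), np.log(600.0)),
    "tauc_log_sd": (0.3, 1.5),
    "close_mean": (5.0, 11.0),
}


@dataclass
class UnitDraws:
    """Frozen standard-normal draws and diseased-unit permutation."""

    z_top: np.ndarray
    z_close: np.ndarray
    z_k: np.ndarray
    z_k3: np.ndarray
    z_pext: np.ndarray
    z_raw: np.ndarray
    z_rvasc: np.ndarray
    z_tauc: np.ndarray
    perm: np.ndarray
    seed: int

    @classmethod
    def sample(cls, n: int, seed: int) -> "UnitDraws":
        rng = np.random.default_rng(seed)
        z = {f: rng.standard_normal(n) for f in
             ("z_top", "z_close", "z_k", "z_k3", "z_pext", "z_raw",
              "z_rvasc", "z_tauc")}
        return cls(perm=rng.permutation(n), seed=seed, **z)


def realize_lung(fp: FitParameters, draws: UnitDraws,
                 n: int | None = None) -> tuple[LungParams, np.ndarray]:
    """Transform hyper-parameters + frozen draws into per-compartment arrays.

    Returns the lung parameter arrays and the boolean mask of healthy
    (initially open) compartments.
    """
    n = len(draws.z_top) if n is None else n
    n_dis = int(round(fp.collapsed_frac * n))
    diseased = np.zeros(n, bool)
    diseased[draws.perm[:n_dis]] = True

    top = 0.3 + np.abs(0.8 * draws.z_top)          # healthy: ~0-3 cm H2O
    top_d = np.clip(fp.top_mean + fp.top_sd * draws.z_top, 6.0, 60.0)
    top = np.where(diseased, top_d, top)

    closing = 0.5 * top                             # healthy close far below PEEP
    close_d = np.clip(fp.close_mean + fp.close_sd * draws.z_close, 1.0,
                      top - 0.25)
    closing = np.where(diseased, close_d, closing)

    k = np.clip(fp.k_mean * (1.0 + fp.k_sd_rel * draws.z_k),
                0.4 * fp.k_mean, 2.0 * fp.k_mean)
    k2 = np.clip(fp.k2_mean * (1.0 + 0.2 * draws.z_k3), 1e-4, None)
    k3 = np.full(n, fp.k3_mean)
    pext = np.clip(fp.pext_mean + fp.pext_sd * draws.z_pext, 0.0, 8.0)
    raw = np.clip(fp.raw_mean * (1.0 + 0.15 * draws.z_raw), 0.3, None)
    rvasc = np.clip(1.0 + 0.2 * draws.z_rvasc, 0.4, 2.5)
    rvasc = np.where(diseased, rvasc / fp.w_vasc_diseased, rvasc)
    tauc = np.where(diseased,
                    np.clip(np.exp(fp.tauc_log_mean + fp.tauc_log_sd * draws.z_tauc),
                            0.1, 1800.0),
                    0.5)
    params = LungParams(k=k, k2=k2, k3=k3, p_ext=pext, top=top,
                        d_close=top - closing,
                        r_aw=raw, r_vasc=rvasc, tau_c=tauc, v0=np.zeros(n))
    return params, ~diseased


@dataclass
class VirtualPatient:
    """A fully specified simulated patient."""

    label: str
    lung: LungParams
    metabolic: MetabolicParams
    vent: VentilatorSettings
    initial_open: np.ndarray
    fit_params: FitParameters | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.lung.n

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "label": self.label,
            "lung": self.lung.to_dict(),
            "metabolic": asdict(self.metabolic),
            "vent": self.vent.__dict__,
            "initial_open": np.asarray(self.initial_open, bool).tolist(),
            "fit_params": asdict(self.fit_params) if self.fit_params else None,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VirtualPatient":
        return cls(
            label=d["label"],
            lung=LungParams.from_dict(d["lung"]),
            metabolic=MetabolicParams(**d["metabolic"]),
            vent=VentilatorSettings(**d["vent"]),
            initial_open=np.asarray(d["initial_open"], bool),
            fit_params=FitParameters(**d["fit_params"]) if d.get("fit_params") else None,
            provenance=d.get("provenance", {}),
        )

    def checksum(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def build_virtual_patient(record: StaticPatientRecord, fp: FitParameters,
                          seed: int, n: int = 100) -> VirtualPatient:
    """Assemble a virtual patient from a static record and hyper-parameters."""
    draws = UnitDraws.sample(n, seed)
    lung, healthy = realize_lung(fp, draws, n)
    metabolic = MetabolicParams(hb=record.hb, co=record.co, vo2=fp.vo2,
                                rq=fp.rq, fio2=record.fio2)
    vent = VentilatorSettings(peep=record.peep, dp=record.dp, vr=fp.vr,
                              ie=fp.ie, fio2=record.fio2)
    return VirtualPatient(label=record.label, lung=lung, metabolic=metabolic,
                          vent=vent, initial_open=healthy, fit_params=fp,
                          provenance={"seed": seed, "record": record.label})
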