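"""Breath-by-breath orchestration of a virtual patient under a protocol.

Mechanics are integrated at a fixed step (default 10 ms) inside each breath;
recruitment timers run continuously and cliff-edge derecruitment is applied
once per breath at end-expiration.  Gas exchange is computed quasi-steadily
once per breath: per-compartment alveolar gas from the V/Q balance, arterial
blood by content mixing, and a mixed-venous pool relaxing toward the Fick
steady state with a first-order time constant (default 30 s) so oxygenation
transients over minutes are resolved.

During apnoeic CPAP segments (sustained inflation) the alveolar gas store is
held frozen: at high FiO2 the alveolar oxygen reservoir far outlasts the
40 s hold, and a quasi-steady solve with zero ventilation would collapse
alveolar tensions to venous values nonphysically.

Evaluation metrics recorded every breath: PaO2/FiO2, PaCO2, dynamic
compliance, tidal volume, percent recruited, venous admixture, plus the
maneuver-level P_peak (mean of the per-compartment maximum pressures over
the most pressurised 20% of compartments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import mix_and_invert, run_breaths, solve_breath_gas
from .blood import BloodSample, blood_from_contents, make_blood_sample
from .gasexchange import (GasExchangeConfig, NonphysicalBloodState, PerfusionState,
                          _distension_factor, _hpv_factor, shunt_fraction)
from .mechanics import LungState, dynamic_compliance, p_peak_top20
from .patients import VirtualPatient
from .protocols import Protocol, ProtocolSegment, build_baseline, build_mrs, build_named

__all__ = [
    "EngineConfig",
    "SimulationResult",
    "run_protocol",
    "run_settled",
    "compare_rms",
    "sweep_peep_max",
    "sweep_peep_end",
]


@dataclass(frozen=True)
class EngineConfig:
    """Numerical settings of the breath-by-breath simulation."""

    dt: float = 0.01            # s, within-breath integration step
    cpap_chunk: float = 5.0     # s, bookkeeping interval during CPAP holds
    gas: GasExchangeConfig = field(default_factory=GasExchangeConfig)


@dataclass
class SimulationResult:
    """Breath-indexed time series plus maneuver-level metrics."""

    label: str
    data: pd.DataFrame
    p_peak: float
    provenance: dict = field(default_factory=dict)

    def baseline_pf(self, pre_rm_end: float, window: float = 60.0) -> float:
        """Mean PaO2/FiO2 over the last ``window`` s of the pre-RM stage."""
        d = self.data
        sel = (d.time_s > pre_rm_end - window) & (d.time_s <= pre_rm_end)
        if not sel.any():
            raise ValueError("no breaths in baseline window")
        return float(d.pf_ratio[sel].mean())

    def delta_po2(self, pre_rm_end: float) -> float:
        """Maximum PaO2/FiO2 minus the pre-RM baseline (mmHg)."""
        return float(self.data.pf_ratio.max()) - self.baseline_pf(pre_rm_end)

    @property
    def final_percent_recruited(self) -> float:
        return float(self.data.pct_recruited.iloc[-1])


class _GasState:
    """Mutable blood/alveolar gas state carried across breaths."""

    def __init__(self, patient: VirtualPatient, cfg: EngineConfig):
        m = patient.metabolic
        art = make_blood_sample(90.0, 40.0, m.hb)
        self.venous = blood_from_contents(
            max(art.o2_content - m.vo2 / (10 * m.co), 1.0),
            art.co2_content + m.rq * m.vo2 / (10 * m.co), m.hb)
        n = patient.n
        self.pao2_alv = np.full(n, self.venous.po2)
        self.paco2_alv = np.full(n, self.venous.pco2)
        self.cc_o2 = np.full(n, self.venous.o2_content)
        self.cc_co2 = np.full(n, self.venous.co2_content)
        self.arterial = art


def _perfusion(patient: VirtualPatient, gs: _GasState, open_mask: np.ndarray,
               p_alv_mean: np.ndarray, cfg: GasExchangeConfig) -> np.ndarray:
    pao2 = np.where(open_mask, gs.pao2_alv, gs.venous.po2)
    g = (1.0 / patient.lung.r_vasc) * _hpv_factor(pao2, cfg) \
        * _distension_factor(np.where(open_mask, p_alv_mean, 0.0), cfg)
    return g / g.sum()


def _gas_breath(patient: VirtualPatient, gs: _GasState, va: np.ndarray,
                open_mask: np.ndarray, p_alv_mean: np.ndarray,
                duration: float, cfg: GasExchangeConfig,
                frozen: bool = False) -> dict:
    """One quasi-steady gas-exchange update; returns breath metrics."""
    m = patient.metabolic
    q = _perfusion(patient, gs, open_mask, p_alv_mean, cfg)
    if frozen:
        # CPAP hold: alveolar tensions kept, only perfusion/mixing update
        pass
    else:
        solve_breath_gas(va, 10.0 * m.co * q, open_mask,
                         m.fio2, m.pb, m.temp, m.hco3, m.hb,
                         gs.venous.o2_content, gs.venous.co2_content,
                         gs.venous.po2, gs.venous.pco2,
                         gs.pao2_alv, gs.paco2_alv, gs.cc_o2, gs.cc_co2)
    cao2, caco2, pao2, paco2, sao2 = mix_and_invert(
        q, gs.cc_o2, gs.cc_co2, m.hb, m.temp, m.hco3)
    gs.arterial = BloodSample(pao2, paco2, sao2, cao2, caco2)
    # Fick steady-state target for the venous pool, first-order relaxation
    dv = m.vo2 / (10.0 * m.co)
    cv_o2_ss = cao2 - dv
    cv_co2_ss = caco2 + m.rq * dv
    if cv_o2_ss < 0.2:
        raise NonphysicalBloodState(
            f"patient {patient.label}: venous O2 content {cv_o2_ss:.2f} ml/dl; "
            "oxygen delivery cannot sustain VO2 at this shunt")
    alpha = 1.0 - np.exp(-duration / cfg.venous_tau)
    cv_o2 = gs.venous.o2_content + alpha * (cv_o2_ss - gs.venous.o2_content)
    cv_co2 = gs.venous.co2_content + alpha * (cv_co2_ss - gs.venous.co2_content)
    gs.venous = blood_from_contents(cv_o2, cv_co2, m.hb, temp=m.temp, hco3=m.hco3)
    # venous admixture via the Berggren equation against ideal capillary blood
    w_open = q[open_mask].sum()
    if w_open > 1e-9:
        cc_ideal = float((q * gs.cc_o2)[open_mask].sum() / w_open)
    else:
        cc_ideal = cao2
    try:
        qsqt = 100.0 * shunt_fraction(cc_ideal, cao2, gs.venous.o2_content)
    except ValueError:
        qsqt = np.nan
    return dict(pao2=pao2, paco2=paco2, sao2=sao2, pvo2=gs.venous.po2,
                pvco2=gs.venous.pco2, qs_qt=qsqt,
                pf_ratio=pao2 / m.fio2)


def _segment_arrays(n_breaths: int, n: int):
    return (np.zeros((n_breaths, n)), np.zeros((n_breaths, n), np.bool_),
            np.zeros((n_breaths, n)), np.zeros((n_breaths, n)),
            np.zeros(n_breaths), np.zeros(n_breaths), np.zeros((n_breaths, n)))


def run_protocol(patient: VirtualPatient, protocol: Protocol,
                 config: EngineConfig | None = None) -> SimulationResult:
    """Simulate a patient under a protocol and record per-breath metrics.

    Deterministic: the patient fixes all sampled parameters, and the engine
    itself draws no random numbers.
    """
    cfg = config or EngineConfig()
    lung = patient.lung
    n = lung.n
    closing = lung.closing
    state = LungState.initial(lung, patient.initial_open.copy(),
                              v_dead=cfg.gas.v_dead)
    gs = _GasState(patient, cfg)
    rows: list[dict] = []
    t = 0.0
    for seg_idx, seg in enumerate(protocol.segments):
        s = seg.settings
        if s.mode == "cpap":
            n_chunks = max(int(round(seg.duration / cfg.cpap_chunk)), 1)
            chunk = seg.duration / n_chunks
            outs = _segment_arrays(n_chunks, n)
            run_breaths(lung.k, lung.k2, lung.k3, lung.p_ext, lung.top, closing,
                        lung.r_aw, lung.tau_c,
                        state.volume, state.is_open, state.opening_timer,
                        state.max_pressure,
                        s.peep, 0.0, 0.0, chunk, n_chunks, cfg.dt, *outs)
            inh, open_b, palv_mean, _palv_pk, vt_b, ppk_b, _pee = outs
            for b in range(n_chunks):
                t += chunk
                met = _gas_breath(patient, gs, inh[b] * 0.0, open_b[b],
                                  palv_mean[b], chunk, cfg.gas, frozen=True)
                rows.append(dict(time_s=t, seg=seg_idx, peep=s.peep, dp=0.0,
                                 vt_ml=0.0, cdyn=np.nan,
                                 pct_recruited=100.0 * open_b[b].sum() / n,
                                 p_peak_run=ppk_b[b], **met))
        else:
            n_breaths = max(int(round(seg.duration / s.t_breath)), 1)
            outs = _segment_arrays(n_breaths, n)
            run_breaths(lung.k, lung.k2, lung.k3, lung.p_ext, lung.top, closing,
                        lung.r_aw, lung.tau_c,
                        state.volume, state.is_open, state.opening_timer,
                        state.max_pressure,
                        s.peep, s.dp, s.t_insp, s.t_breath, n_breaths, cfg.dt,
                        *outs)
            inh, open_b, palv_mean, _palv_pk, vt_b, ppk_b, _pee = outs
            vd_eff = cfg.gas.v_dead_at(s.peep + s.ie * s.dp)
            for b in range(n_breaths):
                t += s.t_breath
                vt = vt_b[b]
                # shared series dead space: only fresh gas beyond VD exchanges
                if vt > vd_eff:
                    va = inh[b] * (vt - vd_eff) / vt * s.vr
                else:
                    va = np.zeros(n)
                met = _gas_breath(patient, gs, va, open_b[b], palv_mean[b],
                                  s.t_breath, cfg.gas)
                rows.append(dict(time_s=t, seg=seg_idx, peep=s.peep, dp=s.dp,
                                 vt_ml=vt,
                                 cdyn=dynamic_compliance(vt, s.p_peak, s.peep),
                                 pct_recruited=100.0 * open_b[b].sum() / n,
                                 p_peak_run=ppk_b[b], **met))
    df = pd.DataFrame(rows)
    return SimulationResult(label=protocol.label, data=df,
                            p_peak=p_peak_top20(state),
                            provenance={"protocol": protocol.label,
                                        "patient": patient.label,
                                        "dt": cfg.dt})


def run_settled(patient: VirtualPatient, peep: float, dp: float,
                config: EngineConfig | None = None, settle_breaths: int = 12,
                max_iter: int = 80, tol: float = 5e-4) -> dict:
    """Steady-state outputs at fixed ventilator settings.

    Runs a short mechanical settling phase, then iterates the per-breath gas
    exchange and the Fick venous balance to a fixed point (no venous delay).
    Used by the calibration objective; orders of magnitude faster than
    time-marching the venous pool.
    """
    cfg = config or EngineConfig()
    lung = patient.lung
    n = lung.n
    s = patient.vent
    state = LungState.initial(lung, patient.initial_open.copy(),
                              v_dead=cfg.gas.v_dead)
    outs = _segment_arrays(settle_breaths, n)
    run_breaths(lung.k, lung.k2, lung.k3, lung.p_ext, lung.top, lung.closing,
                lung.r_aw, lung.tau_c,
                state.volume, state.is_open, state.opening_timer,
                state.max_pressure,
                peep, dp, s.t_insp, s.t_breath, settle_breaths, cfg.dt, *outs)
    inh, open_b, palv_mean, _pk, vt_b, ppk_b, _pee = outs
    b = settle_breaths - 1
    vt = vt_b[b]
    open_mask = open_b[b]
    vd_eff = cfg.gas.v_dead_at(peep + s.ie * dp)
    if vt > vd_eff:
        va = inh[b] * (vt - vd_eff) / vt * s.vr
    else:
        va = np.zeros(n)
    gs = _GasState(patient, cfg)
    m = patient.metabolic
    met: dict = {}
    prev = np.array([gs.venous.o2_content, gs.venous.co2_content])
    for it in range(max_iter):
        met = _gas_breath(patient, gs, va, open_mask, palv_mean[b],
                          duration=3.0 * cfg.gas.venous_tau, cfg=cfg.gas)
        cur = np.array([gs.venous.o2_content, gs.venous.co2_content])
        if np.max(np.abs(cur - prev)) < tol:
            break
        prev = cur
    met.update(vt_ml=float(vt), pct_recruited=100.0 * open_mask.sum() / n,
               cdyn=dynamic_compliance(float(vt), peep + dp, peep) if dp > 0 else np.nan,
               open_mask=open_mask.copy())
    return met


# ---------------------------------------------------------------------------
# maneuver comparisons and PEEP sweeps


def _protocol_for(patient: VirtualPatient, name: str) -> Protocol:
    return build_named(name, patient=patient.vent)


def compare_rms(patient: VirtualPatient,
                config: EngineConfig | None = None) -> pd.DataFrame:
    """Run MRS-10, SI-10 and PRM-10 and tabulate ΔPO2 and P_peak.

    ΔPO2 is the maximum PaO2/FiO2 during/after the maneuver minus the mean
    over the last minute of the pre-RM stage (mmHg); P_peak is the top-20%
    mean of per-compartment maximum pressures over the maneuver (cm H2O).
    """
    rows = []
    for name in ("MRS-10", "SI-10", "PRM-10"):
        proto = _protocol_for(patient, name)
        res = run_protocol(patient, proto, config)
        pre_end = proto.segments[0].duration
        rows.append(dict(rm=name, delta_po2=res.delta_po2(pre_end),
                         p_peak=res.p_peak))
    return pd.DataFrame(rows).set_index("rm")


def sweep_peep_max(patient: VirtualPatient, values,
                   config: EngineConfig | None = None) -> pd.Series:
    """Percent of compartments recruited at the end of the MRS recruitment
    phase, for each peak PEEP value (post-RM stages omitted)."""
    out = {}
    for pm in values:
        pm = float(pm)
        proto = build_mrs(peep_end=min(10.0, pm - 5.0), peep_max=pm,
                          patient=patient.vent, post_rm=0.0)
        # recruitment steps occupy segments 1..pm/5 (segment 0 is pre-RM)
        seg_peak = int(round(pm / 5.0))
        res = run_protocol(patient, proto, config)
        d = res.data
        out[float(pm)] = float(d.pct_recruited[d.seg == seg_peak].iloc[-1])
    return pd.Series(out, name="pct_recruited")


def sweep_peep_end(patient: VirtualPatient, values,
                   config: EngineConfig | None = None) -> pd.Series:
    """Percent of compartments still open at the end of a full MRS
    (PEEP_max 45) titrated to each end-maneuver PEEP, after the post-RM
    stage."""
    out = {}
    for pe in values:
        proto = build_mrs(peep_end=float(pe), peep_max=45.0, patient=patient.vent)
        res = run_protocol(patient, proto, config)
        out[float(pe)] = res.final_percent_recruited
    return pd.Series(out, name="pct_open")
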