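"""Pressure-controlled ventilation waveforms and recruitment maneuvers.

Three maneuvers are built in, each sandwiched between a pre-maneuver stage
(tidal ventilation at PEEP 10, driving pressure 15 cm H2O) and a
post-maneuver stage at the end-maneuver PEEP:

* **MRS** (maximal recruitment strategy): a PEEP staircase 5 → PEEP_max in
  5 cm H2O steps of 2 min at fixed driving pressure 15, followed by a
  downward PEEP titration from min(25, PEEP_max - 5) in 5 cm H2O steps of
  5 min to the end-maneuver PEEP.
* **SI** (sustained inflation): a single breath-free CPAP hold, by default
  40 cm H2O for 40 s.
* **PRM** (prolonged recruitment maneuver): driving pressure raised every
  2 min in 5 cm H2O steps from 15 to 25 above a fixed PEEP of 15.

Pressure waveforms are square (instant rise/fall): PEEP + dP during the
inspiratory fraction of each breath cycle, PEEP during expiration, constant
pressure for CPAP segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VentilatorSettings",
    "ProtocolSegment",
    "Protocol",
    "build_baseline",
    "build_mrs",
    "build_si",
    "build_prm",
    "build_named",
    "pressure_at",
    "PRE_RM_DURATION",
    "POST_RM_DURATION",
]

#: default stage durations (s); the source protocols do not state them
PRE_RM_DURATION = 300.0
POST_RM_DURATION = 1200.0


@dataclass(frozen=True)
class VentilatorSettings:
    """One set of pressure-controlled ventilator settings.

    ``ie`` stores the inspiratory time as a fraction of the breath cycle,
    I/(I+E).  ``mode`` is ``"tidal"`` or ``"cpap"`` (constant pressure; VR
    and IE are ignored during CPAP).
    """

    peep: float
    dp: float
    vr: float = 12.0
    ie: float = 0.33
    fio2: float = 0.21
    mode: str = "tidal"

    def __post_init__(self) -> None:
        if self.peep < 0 or self.dp < 0:
            raise ValueError("PEEP and driving pressure must be non-negative")
        if self.mode not in ("tidal", "cpap"):
            raise ValueError("mode must be 'tidal' or 'cpap'")
        if self.mode == "tidal":
            if self.vr <= 0:
                raise ValueError("ventilation rate must be positive")
            if not 0 < self.ie < 1:
                raise ValueError("IE fraction must be in (0, 1)")
        if not 0 < self.fio2 <= 1:
            raise ValueError("FiO2 must be in (0, 1]")

    @property
    def t_breath(self) -> float:
        return 60.0 / self.vr

    @property
    def t_insp(self) -> float:
        return self.ie * self.t_breath

    @property
    def p_peak(self) -> float:
        return self.peep + self.dp


@dataclass(frozen=True)
class ProtocolSegment:
    duration: float
    settings: VentilatorSettings

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")


@dataclass(frozen=True)
class Protocol:
    """Ordered, contiguous list of ventilator segments."""

    label: str
    segments: tuple[ProtocolSegment, ...]

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def segment_at(self, t: float) -> tuple[ProtocolSegment, float]:
        """Segment containing time ``t`` and the local time within it."""
        if t < 0 or t >= self.total_duration:
            raise ValueError(f"t={t} outside protocol [0, {self.total_duration})")
        acc = 0.0
        for seg in self.segments:
            if t < acc + seg.duration:
                return seg, t - acc
            acc += seg.duration
        raise AssertionError("unreachable")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "segments": [
                {"duration": s.duration, **s.settings.__dict__}
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        segs = []
        for s in d["segments"]:
            s = dict(s)
            dur = s.pop("duration")
            segs.append(ProtocolSegment(dur, VentilatorSettings(**s)))
        return cls(label=d["label"], segments=tuple(segs))


def pressure_at(protocol: Protocol, t: float) -> float:
    """Airway opening pressure (cm H2O) of the square waveform at time t."""
    seg, tl = protocol.segment_at(t)
    s = seg.settings
    if s.mode == "cpap":
        return s.peep
    phase = tl % s.t_breath
    return s.peep + s.dp if phase < s.t_insp else s.peep


def build_baseline(peep: float, duration: float, patient: VentilatorSettings,
                   dp: float = 15.0) -> ProtocolSegment:
    """Tidal baseline segment at the given PEEP with dP 15 above PEEP."""
    return ProtocolSegment(duration, replace(patient, peep=peep, dp=dp, mode="tidal"))


def _sandwich(label: str, core: list[ProtocolSegment], patient: VentilatorSettings,
              peep_end: float, pre_rm: float, post_rm: float) -> Protocol:
    segs = []
    if pre_rm > 0:
        segs.append(build_baseline(10.0, pre_rm, patient))
    segs.extend(core)
    if post_rm > 0:
        segs.append(build_baseline(peep_end, post_rm, patient))
    return Protocol(label=label, segments=tuple(segs))


def build_mrs(peep_end: float, peep_max: float = 45.0,
              patient: VentilatorSettings | None = None, dp: float = 15.0,
              recruit_step: float = 120.0, titrate_step: float = 300.0,
              pre_rm: float = PRE_RM_DURATION,
              post_rm: float = POST_RM_DURATION) -> Protocol:
    """Maximal recruitment strategy with downward PEEP titration.

    Recruitment: PEEP 5, 10, ... peep_max (2 min each, dP fixed).
    Titration: PEEP min(25, peep_max - 5) down in -5 steps (5 min each) to
    ``peep_end``; a peep_end off the 5-grid is appended as an exact final
    step.
    """
    if patient is None:
        patient = VentilatorSettings(peep=5, dp=dp)
    if not (10 <= peep_max <= 45) or peep_max % 5:
        raise ValueError("peep_max must be a multiple of 5 in [10, 45]")
    titr_start = min(25.0, peep_max - 5.0)
    if not 5 <= peep_end <= titr_start:
        raise ValueError("peep_end must lie in [5, titration start]")
    core = [build_baseline(p, recruit_step, patient, dp)
            for p in np.arange(5.0, peep_max + 1e-9, 5.0)]
    p = titr_start
    titr: list[float] = []
    while p > peep_end + 1e-9:
        titr.append(p)
        p -= 5.0
    titr.append(float(peep_end))
    core += [build_baseline(p, titrate_step, patient, dp) for p in titr]
    return _sandwich(f"MRS-{peep_end:g}", core, patient, peep_end, pre_rm, post_rm)


def build_si(peep_end: float, pressure: float = 40.0, hold: float = 40.0,
             patient: VentilatorSettings | None = None,
             pre_rm: float = PRE_RM_DURATION,
             post_rm: float = POST_RM_DURATION) -> Protocol:
    """Sustained inflation: one breath-free CPAP hold, then post-RM tidal."""
    if patient is None:
        patient = VentilatorSettings(peep=5, dp=15)
    if hold <= 0:
        raise ValueError("hold duration must be positive")
    core = [ProtocolSegment(hold, replace(patient, peep=pressure, dp=0.0, mode="cpap"))]
    return _sandwich(f"SI-{peep_end:g}", core, patient, peep_end, pre_rm, post_rm)


def build_prm(peep_end: float, peep: float = 15.0, dp_start: float = 15.0,
              dp_end: float = 25.0, dp_step: float = 5.0,
              step_duration: float = 120.0,
              patient: VentilatorSettings | None = None,
              pre_rm: float = PRE_RM_DURATION,
              post_rm: float = POST_RM_DURATION) -> Protocol:
    """Prolonged recruitment maneuver: rising dP above a fixed PEEP."""
    if patient is None:
        patient = VentilatorSettings(peep=5, dp=15)
    if dp_step <= 0:
        raise ValueError("dp_step must be positive")
    if dp_end < dp_start:
        raise ValueError("dp_end must be >= dp_start")
    core = [ProtocolSegment(step_duration, replace(patient, peep=peep, dp=dp, mode="tidal"))
            for dp in np.arange(dp_start, dp_end + 1e-9, dp_step)]
    return _sandwich(f"PRM-{peep_end:g}", core, patient, peep_end, pre_rm, post_rm)


_BUILDERS = {"MRS": build_mrs, "SI": build_si, "PRM": build_prm}


def build_named(name: str, patient: VentilatorSettings | None = None, **kw) -> Protocol:
    """Build a protocol from a name like ``MRS-10``, ``SI-5`` or ``PRM-10``."""
    try:
        kind, end = name.upper().split("-")
        builder = _BUILDERS[kind]
        peep_end = float(end)
    except (ValueError, KeyError) as e:
        raise ValueError(f"unknown protocol name {name!r}") from e
    return builder(peep_end=peep_end, patient=patient, **kw)
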