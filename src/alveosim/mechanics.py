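"""Per-compartment lung mechanics with recruitment/derecruitment hysteresis.

The lung is divided into N (default 100) parallel alveolar compartments
behind a shared series dead space.  Each compartment obeys a cubic
pressure-volume law

    P_alv = P_ext + k * V + k2 * V**2 + k3 * V**3

(``P_ext`` lumps superimposed gravitational pressure and surface-tension
effects, ``k`` is the linear stiffness, the quadratic term dominates the
progressive stiffening — giving elastance that grows roughly with the
square root of distending pressure, as clinical compliance trajectories
under PEEP staircases show — and the small cubic term guards the extreme
high-volume end) and fills through its airway resistance:

    dV/dt = (P_aw - P_alv) / R_aw.

A collapsed compartment holds zero volume and admits no flow.  It reopens
only after the airway pressure has exceeded its threshold opening pressure
(TOP) continuously for its opening time-constant ``tau_c``; the timer resets
whenever the pressure falls back to or below TOP.  An open compartment
re-collapses ("cliff-edge" derecruitment, evaluated once per breath at
end-expiration) when its end-expiratory alveolar pressure falls below its
closing pressure TOP - d_close, which is strictly below TOP — this is the
hysteresis between opening and closing.

The functions in this module are the plain-numpy reference implementation of
the mechanics; the breath-by-breath engine uses an equivalent numba kernel
(:mod:`alveosim._kernels`) that is tested against these functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CompartmentParams",
    "LungParams",
    "LungState",
    "MechanicsConfig",
    "alveolar_pressure",
    "step_mechanics",
    "update_recruitment",
    "update_derecruitment",
    "dynamic_compliance",
    "p_peak_top20",
    "percent_recruited",
]


@dataclass(frozen=True)
class CompartmentParams:
    """Mechanical parameters of a single alveolar compartment.

    Units: ``k`` cm H2O/ml, ``k3`` cm H2O/ml^3, pressures cm H2O,
    ``r_aw`` cm H2O s/ml, ``tau_c`` s, ``v0`` ml.  ``r_vasc`` is a
    dimensionless relative vascular resistance (1 = average conductance).
    """

    k: float
    k2: float = 0.0
    k3: float = 0.0
    p_ext: float = 0.0
    top: float = 0.0
    d_close: float = 0.0
    r_aw: float = 1.0
    r_vasc: float = 1.0
    tau_c: float = 0.0
    v0: float = 0.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("stiffness k must be positive")
        if self.r_aw <= 0:
            raise ValueError("airway resistance must be positive")
        if self.r_vasc <= 0:
            raise ValueError("vascular resistance must be positive")
        if self.tau_c < 0:
            raise ValueError("opening time-constant must be non-negative")
        if self.v0 < 0:
            raise ValueError("unstressed volume must be non-negative")
        if self.top > 0 and not (0 < self.d_close <= self.top):
            raise ValueError("need 0 < d_close <= TOP (closing pressure >= 0)")

    @property
    def closing_pressure(self) -> float:
        return self.top - self.d_close


@dataclass
class LungParams:
    """Parameter arrays for all compartments of one lung (struct of arrays)."""

    k: np.ndarray
    k2: np.ndarray
    k3: np.ndarray
    p_ext: np.ndarray
    top: np.ndarray
    d_close: np.ndarray
    r_aw: np.ndarray
    r_vasc: np.ndarray
    tau_c: np.ndarray
    v0: np.ndarray

    def __post_init__(self) -> None:
        arrs = [self.k, self.k2, self.k3, self.p_ext, self.top, self.d_close,
                self.r_aw, self.r_vasc, self.tau_c, self.v0]
        n = len(self.k)
        for a in arrs:
            if len(a) != n:
                raise ValueError("all parameter arrays must share length")
        if np.any(self.k <= 0) or np.any(self.r_aw <= 0) or np.any(self.r_vasc <= 0):
            raise ValueError("k, r_aw, r_vasc must be positive")
        if np.any(self.tau_c < 0) or np.any(self.v0 < 0):
            raise ValueError("tau_c and v0 must be non-negative")
        if np.any(self.closing < -1e-9):
            raise ValueError("closing pressures must be non-negative")
        if np.any(self.d_close[self.top > 0] <= 0):
            raise ValueError("d_close must be positive where TOP > 0")

    @property
    def n(self) -> int:
        return len(self.k)

    @property
    def closing(self) -> np.ndarray:
        """Per-compartment closing pressure TOP - d_close (cm H2O)."""
        return self.top - self.d_close

    @classmethod
    def from_compartments(cls, comps: list[CompartmentParams]) -> "LungParams":
        return cls(
            k=np.array([c.k for c in comps], float),
            k2=np.array([c.k2 for c in comps], float),
            k3=np.array([c.k3 for c in comps], float),
            p_ext=np.array([c.p_ext for c in comps], float),
            top=np.array([c.top for c in comps], float),
            d_close=np.array([c.d_close for c in comps], float),
            r_aw=np.array([c.r_aw for c in comps], float),
            r_vasc=np.array([c.r_vasc for c in comps], float),
            tau_c=np.array([c.tau_c for c in comps], float),
            v0=np.array([c.v0 for c in comps], float),
        )

    def compartment(self, i: int) -> CompartmentParams:
        return CompartmentParams(
            k=float(self.k[i]), k2=float(self.k2[i]), k3=float(self.k3[i]),
            p_ext=float(self.p_ext[i]),
            top=float(self.top[i]), d_close=float(self.d_close[i]),
            r_aw=float(self.r_aw[i]), r_vasc=float(self.r_vasc[i]),
            tau_c=float(self.tau_c[i]), v0=float(self.v0[i]),
        )

    def to_dict(self) -> dict:
        return {name: getattr(self, name).tolist()
                for name in ("k", "k2", "k3", "p_ext", "top", "d_close",
                             "r_aw", "r_vasc", "tau_c", "v0")}

    @classmethod
    def from_dict(cls, d: dict) -> "LungParams":
        return cls(**{name: np.asarray(d[name], float)
                      for name in ("k", "k2", "k3", "p_ext", "top", "d_close",
                                   "r_aw", "r_vasc", "tau_c", "v0")})


@dataclass
class LungState:
    """Dynamic state of the compartmental lung.

    ``volume`` is the volume above the unstressed volume (ml); collapsed
    compartments hold exactly zero.  ``opening_timer`` accumulates time spent
    above TOP while collapsed.  ``max_pressure`` is the running per-
    compartment maximum alveolar pressure over the maneuver.
    """

    is_open: np.ndarray
    volume: np.ndarray
    p_alv: np.ndarray
    opening_timer: np.ndarray
    max_pressure: np.ndarray
    v_dead: float = 150.0
    p_aw: float = 0.0

    @classmethod
    def initial(cls, params: LungParams, open_mask: np.ndarray | None = None,
                v_dead: float = 150.0) -> "LungState":
        n = params.n
        if open_mask is None:
            open_mask = np.zeros(n, bool)
        open_mask = np.asarray(open_mask, bool).copy()
        vol = np.zeros(n)
        p_alv = params.p_ext.copy()
        return cls(is_open=open_mask, volume=vol, p_alv=p_alv,
                   opening_timer=np.zeros(n), max_pressure=p_alv.copy(),
                   v_dead=float(v_dead))

    @property
    def n(self) -> int:
        return len(self.volume)

    @property
    def total_volume(self) -> float:
        return float(self.volume.sum())

    def copy(self) -> "LungState":
        return LungState(self.is_open.copy(), self.volume.copy(), self.p_alv.copy(),
                         self.opening_timer.copy(), self.max_pressure.copy(),
                         self.v_dead, self.p_aw)


@dataclass(frozen=True)
class MechanicsConfig:
    """Integration settings for the compartmental mechanics."""

    dt: float = 0.01
    n_compartments: int = 100
    default_d_close: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_compartments < 1:
            raise ValueError("need at least one compartment")


def alveolar_pressure(volume, params: CompartmentParams | LungParams):
    """Alveolar pressure from the cubic PV law, cm H2O.

    Strictly increasing in volume; raises for negative volume.
    """
    v = np.asarray(volume, float)
    if np.any(v < 0):
        raise ValueError("volume must be non-negative")
    p = params.p_ext + params.k * v + params.k2 * v ** 2 + params.k3 * v ** 3
    return float(p) if np.isscalar(volume) else p


def step_mechanics(state: LungState, params: LungParams, p_aw: float,
                   dt: float) -> LungState:
    """Advance open-compartment volumes by one explicit-Euler step.

    Collapsed compartments are untouched (no flow); volumes are floored at
    zero during expiration.  Updates alveolar pressures and the running
    pressure maxima in place and returns the state.
    """
    if not math.isfinite(p_aw):
        raise ValueError("airway pressure must be finite")
    op = state.is_open
    flow = np.where(op, (p_aw - state.p_alv) / params.r_aw, 0.0)
    state.volume[op] = np.maximum(state.volume[op] + flow[op] * dt, 0.0)
    state.p_alv[op] = (params.p_ext[op] + params.k[op] * state.volume[op]
                       + params.k2[op] * state.volume[op] ** 2
                       + params.k3[op] * state.volume[op] ** 3)
    np.maximum(state.max_pressure, state.p_alv, out=state.max_pressure)
    state.p_aw = p_aw
    return state


def update_recruitment(state: LungState, params: LungParams, p_aw: float,
                       dt: float) -> LungState:
    """Accumulate opening timers and open compartments whose timer matured.

    While collapsed: if ``p_aw`` exceeds TOP the timer grows by ``dt``,
    otherwise it resets to zero.  A compartment opens (volume 0, filling
    handled by subsequent mechanics steps) once its timer reaches tau_c.
    """
    closed = ~state.is_open
    above = closed & (p_aw > params.top)
    state.opening_timer[above] += dt
    state.opening_timer[closed & ~above] = 0.0
    opens = above & (state.opening_timer >= params.tau_c)
    if np.any(opens):
        state.is_open[opens] = True
        state.volume[opens] = 0.0
        state.opening_timer[opens] = 0.0
        state.p_alv[opens] = params.p_ext[opens]
    return state


def update_derecruitment(state: LungState, params: LungParams,
                         p_ee: np.ndarray | None = None) -> LungState:
    """End-expiratory cliff-edge collapse.

    Any open compartment whose end-expiratory alveolar pressure (by default
    the state's current alveolar pressure) is below its closing pressure
    TOP - d_close collapses instantly: volume and timer go to zero.
    """
    if p_ee is None:
        p_ee = state.p_alv
    closing = params.closing
    collapse = state.is_open & (p_ee < closing)
    if np.any(collapse):
        state.is_open[collapse] = False
        state.volume[collapse] = 0.0
        state.opening_timer[collapse] = 0.0
        state.p_alv[collapse] = params.p_ext[collapse]
    return state


def dynamic_compliance(tidal_volume: float, p_insp_peak: float, peep: float) -> float:
    """Dynamic compliance Vt / (P_peak_insp - PEEP), ml per mbar.

    1 mbar is treated as 1 cm H2O (≈2% convention error, documented).
    """
    dp = p_insp_peak - peep
    if dp <= 0:
        raise ValueError("driving pressure must be positive")
    return tidal_volume / dp


def p_peak_top20(state: LungState, fraction: float = 0.2) -> float:
    """Mean of the per-compartment maximum pressures over the most highly
    pressurised ``fraction`` (default 20%) of compartments, cm H2O."""
    n = state.n
    if n == 0:
        raise ValueError("empty lung")
    m = int(math.ceil(fraction * n))
    top = np.sort(state.max_pressure)[::-1][:m]
    return float(top.mean())


def percent_recruited(state: LungState) -> float:
    """Percentage of compartments currently open."""
    return 100.0 * float(state.is_open.sum()) / state.n
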