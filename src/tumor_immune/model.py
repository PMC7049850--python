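"""Right-hand sides of the tumor-immune system and treatment schedules.

State ordering is ``(T, N, L, Y, C, I)`` for the untreated six-state system
and ``(T, N, L, Y, C, I, M)`` with the chemotherapy drug concentration ``M``
appended for the treated system.  Dose channels are ordered
``(v_M, v_I, v_L, v_Y)``: chemotherapy, IL-2 cytokine, CD8+T and CD4+T
adoptive therapy, each a piecewise-constant rate in dose units per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Tuple, Union

import numpy as np
import yaml

from .parameters import ParameterSet

__all__ = [
    "STATE_VARS",
    "DOSE_CHANNELS",
    "StateVector",
    "Channel",
    "TreatmentSchedule",
    "lysis_fraction_D",
    "rhs_untreated",
    "rhs_treated",
    "rhs_untreated_terms",
    "dose_at",
    "event_times",
]

STATE_VARS = ("T", "N", "L", "Y", "C", "I", "M")
DOSE_CHANNELS = ("v_M", "v_I", "v_L", "v_Y")


@dataclass
class StateVector:
    """Populations and concentrations at one instant.

    ``T, N, L, Y, C`` are cell populations, ``I`` the IL-2 concentration and
    ``M`` the chemotherapy drug concentration (both in the model's implicit
    concentration units).  All components are nonnegative.
    """

    t: float = 0.0
    T: float = 0.0
    N: float = 0.0
    L: float = 0.0
    Y: float = 0.0
    C: float = 0.0
    I: float = 0.0
    M: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise ValueError("time must be finite")
        for name in STATE_VARS:
            if getattr(self, name) < 0:
                raise ValueError(f"state component {name} must be nonnegative")

    def to_array(self, n: int = 7) -> np.ndarray:
        vals = [self.T, self.N, self.L, self.Y, self.C, self.I, self.M]
        return np.asarray(vals[:n], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float], t: float = 0.0) -> "StateVector":
        y = list(map(float, y))
        if len(y) == 6:
            y = y + [0.0]
        return cls(t, *y)


# ---------------------------------------------------------------------------
# treatment schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Channel:
    """One dose channel: OFF, CONSTANT(intensity) or PULSED(...).

    A pulsed channel delivers ``intensity`` (dose units/day) on the half-open
    windows ``[start + i*period, start + i*period + duration)`` for
    ``i = 0 .. n_pulses-1``.  Pulses are constant-rate infusions; the default
    duration of one day follows the convention of the predecessor
    chemotherapy-modelling literature and is configurable because the printed
    regimens state only intensity, start, period and count.
    """

    mode: str = "off"               # "off" | "constant" | "pulsed"
    intensity: float = 0.0
    start: float = 0.0
    period: float = 1.0
    n_pulses: int = 1
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("off", "constant", "pulsed"):
            raise ValueError(f"unknown channel mode {self.mode!r}")
        if self.intensity < 0:
            raise ValueError("intensity must be nonnegative")
        if self.mode == "pulsed":
            if self.period <= 0:
                raise ValueError("period must be positive")
            if not 0 < self.duration <= self.period:
                raise ValueError("duration must lie in (0, period]")
            if self.n_pulses < 1:
                raise ValueError("n_pulses must be >= 1")

    def rate(self, t: float) -> float:
        if self.mode == "off":
            return 0.0
        if self.mode == "constant":
            return self.intensity
        rel = t - self.start
        if rel < 0:
            return 0.0
        i = math.floor(rel / self.period)
        if i >= self.n_pulses:
            return 0.0
        return self.intensity if rel - i * self.period < self.duration else 0.0

    def switch_times(self) -> list:
        if self.mode != "pulsed" or self.intensity == 0:
            return []
        out = []
        for i in range(self.n_pulses):
            t_on = self.start + i * self.period
            out += [t_on, t_on + self.duration]
        return out


def _channel_from_dict(data: Union[dict, None]) -> Channel:
    if not data:
        return Channel()
    return Channel(**data)


@dataclass(frozen=True)
class TreatmentSchedule:
    """Four dose channels: chemo ``v_M``, IL-2 ``v_I``, CD8+T ``v_L``, CD4+T ``v_Y``."""

    v_M: Channel = field(default_factory=Channel)
    v_I: Channel = field(default_factory=Channel)
    v_L: Channel = field(default_factory=Channel)
    v_Y: Channel = field(default_factory=Channel)

    @property
    def channels(self) -> Tuple[Channel, Channel, Channel, Channel]:
        return (self.v_M, self.v_I, self.v_L, self.v_Y)

    def is_off(self) -> bool:
        return all(ch.mode == "off" or ch.intensity == 0 for ch in self.channels)

    @classmethod
    def from_dict(cls, mapping: dict) -> "TreatmentSchedule":
        known = set(DOSE_CHANNELS)
        extra = set(mapping) - known
        if extra:
            raise KeyError(f"unknown channels: {sorted(extra)}")
        return cls(**{name: _channel_from_dict(mapping.get(name)) for name in known})

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "TreatmentSchedule":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def as_dict(self) -> dict:
        out = {}
        for name, ch in zip(DOSE_CHANNELS, self.channels):
            entry = {"mode": ch.mode}
            if ch.mode != "off":
                entry["intensity"] = ch.intensity
            if ch.mode == "pulsed":
                entry.update(start=ch.start, period=ch.period,
                             n_pulses=ch.n_pulses, duration=ch.duration)
            out[name] = entry
        return out


def dose_at(schedule: TreatmentSchedule, t: float) -> np.ndarray:
    """Dose rates ``(v_M, v_I, v_L, v_Y)`` at time ``t`` (days)."""
    return np.array([ch.rate(t) for ch in schedule.channels], dtype=float)


def event_times(schedule: TreatmentSchedule, t_span: Tuple[float, float]) -> list:
    """Sorted, deduplicated dose on/off instants strictly inside ``t_span``.

    Dose discontinuities invalidate the equally-spaced history a multistep
    integrator relies on, so the solver restarts its startup ramp at each of
    these times.
    """
    t0, t1 = t_span
    times = set()
    for ch in schedule.channels:
        for t in ch.switch_times():
            if t0 < t < t1:
                times.add(float(t))
    return sorted(times)


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------

def lysis_fraction_D(T: float, L: float, params: ParameterSet) -> float:
    """Saturating fractional tumor kill rate by CD8+T cells (1/day).

    Evaluated as ``d * L**l / (s * T**l + L**l)``, which is algebraically
    identical to the effector-to-target form ``d (L/T)^l / (s + (L/T)^l)``
    for ``T > 0`` but remains defined on the boundary: ``D(T, 0) = 0`` and
    ``D(0, L>0) = d``, so the product ``D*T`` tends to 0 as ``T -> 0``.
    """
    if T < 0 or L < 0:
        raise ValueError("populations must be nonnegative")
    if L == 0.0:
        return 0.0
    Ll = L ** params.l
    Tl = T ** params.l if T > 0 else 0.0
    return params.d * Ll / (params.s * Tl + Ll)


def _as_state(y, n: int) -> np.ndarray:
    if isinstance(y, StateVector):
        return y.to_array(n)
    y = np.asarray(y, dtype=float)
    if y.shape != (n,):
        raise ValueError(f"expected a state of length {n}, got shape {y.shape}")
    return y


def rhs_untreated(state, params: ParameterSet) -> np.ndarray:
    """Time derivatives ``(dT, dN, dL, dY, dC, dI)/dt`` of the unforced system."""
    y = _as_state(state, 6)
    if not np.isfinite(y).all():
        raise ValueError("non-finite state")
    T, N, L, Y, C, I = y
    p = params
    D = lysis_fraction_D(T, L, p)
    T2 = T * T
    DT2 = (D * T) ** 2
    dT = p.a * T * (1 - p.b * T) - p.c * N * T - D * T - p.c1 * T / (p.a1 + T) * I
    dN = p.e * C - p.f * N + p.g * T2 / (p.h + T2) * N - p.p * N * T
    dL = (-p.m * L + p.j * DT2 / (p.k + DT2) * L - p.q * L * T
          + (p.r1 * N + p.r2 * C) * T - p.u * N * L * L
          + p.p_i * I / (p.g_i + I) * L)
    dY = p.beta1 * T / (p.alpha1 + T) * I - p.mu1 * Y - p.delta2 * T * Y
    dC = p.alpha - p.beta * C
    dI = -p.mu_i * I + p.beta2 * T / (p.alpha2 + T) * Y
    return np.array([dT, dN, dL, dY, dC, dI])


def rhs_untreated_terms(state, params: ParameterSet) -> list:
    """Individual additive terms of each untreated equation.

    Returns a list of six tuples (one per equation) whose entries sum to the
    corresponding component of :func:`rhs_untreated`.  Used to normalise
    equilibrium residuals by the magnitude of the largest competing term.
    """
    y = _as_state(state, 6)
    T, N, L, Y, C, I = y
    p = params
    D = lysis_fraction_D(T, L, p)
    T2 = T * T
    DT2 = (D * T) ** 2
    return [
        (p.a * T * (1 - p.b * T), -p.c * N * T, -D * T, -p.c1 * T / (p.a1 + T) * I),
        (p.e * C, -p.f * N, p.g * T2 / (p.h + T2) * N, -p.p * N * T),
        (-p.m * L, p.j * DT2 / (p.k + DT2) * L, -p.q * L * T,
         (p.r1 * N + p.r2 * C) * T, -p.u * N * L * L, p.p_i * I / (p.g_i + I) * L),
        (p.beta1 * T / (p.alpha1 + T) * I, -p.mu1 * Y, -p.delta2 * T * Y),
        (p.alpha, -p.beta * C),
        (-p.mu_i * I, p.beta2 * T / (p.alpha2 + T) * Y),
    ]


def rhs_treated(state, params: ParameterSet, doses) -> np.ndarray:
    """Derivatives of the seven-state treated system.

    ``doses`` is the 4-vector ``(v_M, v_I, v_L, v_Y)`` of dose rates.  With
    all doses zero and ``M = 0`` the first six components equal
    :func:`rhs_untreated` exactly; chemotherapy kill terms scale with the
    saturating factor ``1 - exp(-M)``.
    """
    y = _as_state(state, 7)
    doses = np.asarray(doses, dtype=float)
    if doses.shape != (4,):
        raise ValueError("doses must be a 4-vector (v_M, v_I, v_L, v_Y)")
    if (doses < 0).any():
        raise ValueError("doses must be nonnegative")
    vM, vI, vL, vY = doses
    p = params
    M = y[6]
    out = np.empty(7)
    out[:6] = rhs_untreated(y[:6], params)
    chemo = -math.expm1(-M)   # 1 - exp(-M), accurate for small M
    T, N, L, _, C, _ = y[:6]
    out[0] -= p.K_T * chemo * T
    out[1] -= p.K_N * chemo * N
    out[2] += -p.K_L * chemo * L + vL
    out[3] += vY
    out[4] -= p.K_C * chemo * C
    out[5] += vI
    out[6] = -p.gamma * M + vM
    return out


def make_rhs(params: ParameterSet, doses=(0.0, 0.0, 0.0, 0.0)):
    """Fast closure ``f(t, y) -> dy/dt`` for the 7-state system at fixed doses.

    The integrator splits time at dose discontinuities, so within a segment
    the doses are constants; binding them (and the parameters) into local
    floats keeps the per-step cost of the fixed-step solver low.
    """
    p = params
    a, a1, b, c, c1, d = p.a, p.a1, p.b, p.c, p.c1, p.d
    e_, f_, g, g_i, h, j, k = p.e, p.f, p.g, p.g_i, p.h, p.j, p.k
    KT, KN, KL, KC = p.K_T, p.K_N, p.K_L, p.K_C
    l, m, pp, p_i, q, r1, r2 = p.l, p.m, p.p, p.p_i, p.q, p.r1, p.r2
    s, u, al, al1, al2 = p.s, p.u, p.alpha, p.alpha1, p.alpha2
    be, be1, be2, ga, mu1, mui, de2 = (p.beta, p.beta1, p.beta2, p.gamma,
                                       p.mu1, p.mu_i, p.delta2)
    vM, vI, vL, vY = map(float, doses)
    exp = math.exp

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        T = y[0]; N = y[1]; L = y[2]; Y = y[3]; C = y[4]; I = y[5]; M = y[6]
        if L > 0.0:
            Ll = L ** l
            D = d * Ll / (s * (T ** l) + Ll) if T > 0.0 else d
        else:
            D = 0.0
        T2 = T * T
        DT = D * T
        DT2 = DT * DT
        chemo = 1.0 - exp(-M)
        TI = T / (a1 + T) * I
        return np.array((
            a * T * (1.0 - b * T) - c * N * T - DT - c1 * TI - KT * chemo * T,
            e_ * C - f_ * N + g * T2 / (h + T2) * N - pp * N * T - KN * chemo * N,
            -m * L + j * DT2 / (k + DT2) * L - q * L * T + (r1 * N + r2 * C) * T
            - u * N * L * L + p_i * I / (g_i + I) * L - KL * chemo * L + vL,
            be1 * T / (al1 + T) * I - mu1 * Y - de2 * T * Y + vY,
            al - be * C - KC * chemo * C,
            -mui * I + be2 * T / (al2 + T) * Y + vI,
            -ga * M + vM,
        ))

    return rhs
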