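"""Fixed-step Adams-Bashforth / Adams-Moulton predictor-corrector integrator.

The explicit Adams-Bashforth formula of order ``k`` advances

    y_n = y_{n-1} + dt * sum_{i=1..k} beta*_i f(t_{n-i}, y_{n-i})

and the implicit Adams-Moulton formula adds the node ``t_n``.  The combined
predictor-corrector (PECE) scheme predicts with Adams-Bashforth, evaluates
``f`` at the prediction and applies the Moulton formula once.  An order-``k``
step pairs the order-``k`` Bashforth predictor with the order-``k`` Moulton
corrector (``k-1`` history nodes plus the implicit node), the classical
same-order pairing whose global convergence order equals ``k``; a corrector
that keeps all ``k`` history nodes (one order higher) is available via
``SolverConfig.full_corrector``.

Coefficients are generated in exact rational arithmetic from the
interpolatory-quadrature conditions (the weights integrate every polynomial
of admissible degree exactly), avoiding transcription errors in published
high-order tables; floats are derived once and cached.

Multistep methods are not self-starting and their equally spaced history is
invalidated by dose discontinuities.  ``integrate`` therefore splits the time
span at the schedule's switching instants and, in each segment, builds its
history by an order ramp on a step-doubling fine grid: the first steps use
step ``dt/2**J`` at orders 1, 2, ... and the step doubles once enough history
has accumulated, so the low-order startup error is held at the level of the
order-``k`` local error rather than polluting the whole run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model import TreatmentSchedule, dose_at, event_times, make_rhs
from .parameters import ParameterSet

__all__ = [
    "MAX_ORDER",
    "AdamsCoefficients",
    "SolverConfig",
    "Trajectory",
    "SolverDivergence",
    "bashforth_coefficients",
    "moulton_coefficients",
    "adams_coefficients",
    "pc_step",
    "integrate",
    "integrate_treated",
]

MAX_ORDER = 12


class SolverDivergence(RuntimeError):
    """Raised when the solution leaves the admissible range or turns non-finite."""

    def __init__(self, t: float, state: np.ndarray, message: str = ""):
        self.t = t
        self.state = np.asarray(state)
        super().__init__(message or f"solution diverged at t={t:.6g}")


# ---------------------------------------------------------------------------
# coefficient generation (exact rational arithmetic)
# ---------------------------------------------------------------------------

def _solve_exact(A: List[List[Fraction]], b: List[Fraction]) -> List[Fraction]:
    """Gauss-Jordan elimination over the rationals (tiny systems only)."""
    n = len(b)
    M = [row[:] + [b[i]] for i, row in enumerate(A)]
    for col in range(n):
        pivot = next(r for r in range(col, n) if M[r][col] != 0)
        M[col], M[pivot] = M[pivot], M[col]
        pv = M[col][col]
        M[col] = [x / pv for x in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0:
                fac = M[r][col]
                M[r] = [x - fac * y for x, y in zip(M[r], M[col])]
    return [M[r][n] for r in range(n)]


@lru_cache(maxsize=None)
def bashforth_coefficients(k: int) -> Tuple[Fraction, ...]:
    """Adams-Bashforth weights ``beta*_1 .. beta*_k`` as exact rationals.

    The weights are the unique quadrature rule on the nodes
    ``t_{n-1}, ..., t_{n-k}`` (in step units: -1, ..., -k) that integrates
    every polynomial of degree <= k-1 exactly over the step [-1, 0].
    """
    if not 1 <= k <= MAX_ORDER:
        raise ValueError(f"order must be in 1..{MAX_ORDER}, got {k}")
    A = [[Fraction(-i) ** j for i in range(1, k + 1)] for j in range(k)]
    rhs = [Fraction((-1) ** j, j + 1) for j in range(k)]   # integral of x^j over [-1, 0]
    return tuple(_solve_exact(A, rhs))


@lru_cache(maxsize=None)
def moulton_coefficients(k: int) -> Tuple[Fraction, ...]:
    """Adams-Moulton weights ``beta_0 .. beta_k`` (k history nodes + implicit node).

    Exact for polynomials of degree <= k; ``moulton_coefficients(0)`` is the
    backward Euler weight [1] and ``moulton_coefficients(1)`` the trapezoidal
    rule [1/2, 1/2].
    """
    if not 0 <= k <= MAX_ORDER:
        raise ValueError(f"history length must be in 0..{MAX_ORDER}, got {k}")
    A = [[Fraction(-i) ** j for i in range(0, k + 1)] for j in range(k + 1)]
    rhs = [Fraction((-1) ** j, j + 1) for j in range(k + 1)]
    return tuple(_solve_exact(A, rhs))


@dataclass(frozen=True)
class AdamsCoefficients:
    """Exact predictor/corrector weights for one order, with float copies."""

    order: int
    bashforth: Tuple[Fraction, ...]
    moulton: Tuple[Fraction, ...]

    @property
    def bashforth_float(self) -> np.ndarray:
        return np.array([float(x) for x in self.bashforth])

    @property
    def moulton_float(self) -> np.ndarray:
        return np.array([float(x) for x in self.moulton])


def adams_coefficients(k: int) -> AdamsCoefficients:
    return AdamsCoefficients(k, bashforth_coefficients(k), moulton_coefficients(k))


@lru_cache(maxsize=None)
def _ab_float(k: int) -> np.ndarray:
    return np.array([float(x) for x in bashforth_coefficients(k)])


@lru_cache(maxsize=None)
def _am_float(k: int) -> np.ndarray:
    return np.array([float(x) for x in moulton_coefficients(k)])


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def pc_step(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    t_new: float,
    y_prev: np.ndarray,
    f_history: Sequence[np.ndarray],
    dt: float,
    order: Optional[int] = None,
    full_corrector: bool = False,
) -> np.ndarray:
    """One PECE step to ``t_new``.

    ``f_history`` holds the derivative evaluations at the ``k`` preceding
    equally spaced nodes, most recent first (``f_{n-1}, f_{n-2}, ...``).  The
    Bashforth prediction is corrected once with the Moulton formula evaluated
    at ``f(t_new, y*)``.
    """
    k = order if order is not None else len(f_history)
    if not 1 <= k <= min(len(f_history), MAX_ORDER):
        raise ValueError(f"order {k} needs {k} history entries (have {len(f_history)})")
    fs = np.asarray(f_history[:k])
    y_star = y_prev + dt * (_ab_float(k) @ fs)
    f_star = rhs(t_new, y_star)
    if not np.isfinite(f_star).all():
        raise SolverDivergence(t_new, y_star, f"non-finite derivative at t={t_new:.6g}")
    hist = k if full_corrector else k - 1
    am = _am_float(hist)
    y_new = y_prev + dt * (am[0] * f_star + (am[1:] @ fs[:hist] if hist else 0.0))
    return y_new


@dataclass
class SolverConfig:
    """Integrator settings.

    ``order`` up to 12 and the default step of ``2**-9`` day are the
    conditions under which the reference simulations are run; the divergence
    guard aborts when any component exceeds ``max_state_magnitude``.
    ``clip_negative`` zeroes components that undershoot zero after each
    accepted step (populations and concentrations are nonnegative and the
    lysis term is undefined for negative values).
    """

    order: int = 12
    dt: float = 2.0 ** -9
    max_state_magnitude: float = 1e30
    clip_negative: bool = True
    full_corrector: bool = False
    save_stride: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.order <= MAX_ORDER:
            raise ValueError(f"order must be in 1..{MAX_ORDER}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")


@dataclass
class Trajectory:
    """Time-ordered solution samples with solver metadata."""

    t: np.ndarray
    y: np.ndarray                      # shape (len(t), n_components)
    columns: Tuple[str, ...]
    order: int
    dt: float
    events: List[float] = field(default_factory=list)
    clip_count: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape[0] != self.t.shape[0]:
            raise ValueError("state row count must equal time count")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")

    def component(self, name: str) -> np.ndarray:
        return self.y[:, self.columns.index(name)]

    def final_state(self) -> np.ndarray:
        return self.y[-1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(self.columns))
        df.insert(0, "t", self.t)
        return df

    def to_csv(self, path: Union[str, Path], sidecar: bool = True) -> None:
        """Write samples as CSV (header ``t,T,N,L,Y,C,I,M``) plus a JSON sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            meta = {"order": self.order, "dt": self.dt, "events": list(self.events),
                    "clip_count": int(self.clip_count)}
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(meta, indent=2))


def _startup_levels(dt: float, order: int, t_scale: float) -> int:
    """Number of step-halvings for the startup grid.

    The first (order-1) startup step has local error O(delta**2); choosing
    ``delta = dt / 2**J`` with ``delta**2 <= dt**(order+1)`` keeps it at the
    level of the order-``k`` error.  J is capped so that ``delta`` stays
    resolvable in floating point relative to the times being advanced.
    """
    if order <= 1:
        return 0
    if dt < 1.0:
        J = math.ceil((order - 1) / 2 * math.log2(1.0 / dt))
    else:
        J = 2
    t_res = max(abs(t_scale), 1.0) * 2.0 ** -46
    J_cap = max(0, int(math.floor(math.log2(dt / t_res)))) if dt > t_res else 0
    return int(min(J, J_cap, 40))


def _integrate_segment(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    t0: float,
    t1: float,
    y0: np.ndarray,
    config: SolverConfig,
    record: Callable[[float, np.ndarray], None],
) -> Tuple[np.ndarray, int]:
    """Advance from t0 to t1 on a uniform grid with ramped, step-doubled startup.

    ``record`` is called at every coarse grid node (t0 itself excluded).
    Returns the final state and the number of clipped components.
    """
    k = config.order
    span = t1 - t0
    n_coarse = max(1, int(math.ceil(span / config.dt - 1e-12)))
    h = span / n_coarse
    J = _startup_levels(h, k, max(abs(t0), abs(t1)))
    delta0 = h / 2 ** J

    y = np.array(y0, dtype=float)
    clip_count = 0
    fy = rhs(t0, y)
    if not np.isfinite(fy).all():
        raise SolverDivergence(t0, y, f"non-finite derivative at t={t0:.6g}")
    hist: List[np.ndarray] = [fy]      # newest first, spacing `level` * delta0
    level = 0                          # spacing = delta0 * 2**level
    pos = 0                            # time = t0 + pos * delta0, pos in units of delta0
    n_total = n_coarse * 2 ** J
    coarse_stride = 2 ** J
    hist_max = 2 * k - 1

    while pos < n_total:
        spacing = 1 << level
        # decimate the history to double the step once enough points exist
        while level < J and len(hist) >= 2 * k - 1:
            hist = hist[::2]
            level += 1
            spacing = 1 << level
        if pos + spacing > n_total:
            # should not happen (n_total is a multiple of every 2**level <= 2**J)
            spacing = n_total - pos
        m = min(len(hist), k)
        step = spacing * delta0
        pos += spacing
        t_new = t0 + pos * delta0 if pos < n_total else t1
        fs = np.asarray(hist[:m])
        y_star = y + step * (_ab_float(m) @ fs)
        if config.clip_negative:
            np.clip(y_star, 0.0, None, out=y_star)
        f_star = rhs(t_new, y_star)
        if not np.isfinite(f_star).all():
            raise SolverDivergence(t_new, y_star, f"non-finite derivative at t={t_new:.6g}")
        hm = m if config.full_corrector else m - 1
        am = _am_float(hm)
        y_new = y + step * (am[0] * f_star + (am[1:] @ fs[:hm] if hm else 0.0))
        if not np.isfinite(y_new).all() or np.abs(y_new).max() > config.max_state_magnitude:
            raise SolverDivergence(t_new, y_new)
        if config.clip_negative:
            neg = y_new < 0.0
            if neg.any():
                clip_count += int(neg.sum())
                y_new[neg] = 0.0
        f_new = rhs(t_new, y_new)
        if not np.isfinite(f_new).all():
            raise SolverDivergence(t_new, y_new, f"non-finite derivative at t={t_new:.6g}")
        hist.insert(0, f_new)
        if len(hist) > hist_max:
            hist.pop()
        y = y_new
        if pos % coarse_stride == 0:
            record(t_new, y)
    return y, clip_count


def integrate(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    y0: Sequence[float],
    t_span: Tuple[float, float],
    config: Optional[SolverConfig] = None,
    events: Sequence[float] = (),
    columns: Optional[Sequence[str]] = None,
) -> Trajectory:
    """Integrate ``dy/dt = rhs(t, y)`` over ``t_span`` at fixed step.

    ``events`` lists interior times at which the multistep history must be
    rebuilt (dose discontinuities); the segments between consecutive events
    are integrated independently and concatenated.
    """
    config = config or SolverConfig()
    t0, t1 = map(float, t_span)
    if not (math.isfinite(t0) and math.isfinite(t1) and t1 > t0):
        raise ValueError("t_span must be finite with t1 > t0")
    y0 = np.asarray(y0, dtype=float)
    evs = sorted({float(e) for e in events if t0 < e < t1})
    bounds = [t0] + evs + [t1]

    ts: List[float] = [t0]
    ys: List[np.ndarray] = [y0.copy()]
    clip_total = 0
    stride_counter = 0

    def record(t: float, y: np.ndarray) -> None:
        nonlocal stride_counter
        stride_counter += 1
        if stride_counter % config.save_stride == 0:
            ts.append(t)
            ys.append(y.copy())

    y = y0
    for a, b in zip(bounds[:-1], bounds[1:]):
        y, clipped = _integrate_segment(rhs, a, b, y, config, record)
        clip_total += clipped
    if ts[-1] != bounds[-1]:           # make sure the endpoint is stored
        ts.append(bounds[-1])
        ys.append(y.copy())
    cols = tuple(columns) if columns is not None else tuple(
        f"y{i}" for i in range(y0.size))
    return Trajectory(np.array(ts), np.array(ys), cols, config.order, config.dt,
                      events=evs, clip_count=clip_total)


def integrate_treated(
    params: ParameterSet,
    y0: Sequence[float],
    t_span: Tuple[float, float],
    schedule: Optional[TreatmentSchedule] = None,
    config: Optional[SolverConfig] = None,
) -> Trajectory:
    """Integrate the 7-state treated system under a treatment schedule.

    Doses are piecewise constant, so each inter-event segment is integrated
    with the dose rates bound as constants.
    """
    schedule = schedule or TreatmentSchedule()
    config = config or SolverConfig()
    t0, t1 = map(float, t_span)
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (7,):
        raise ValueError("y0 must have 7 components (T, N, L, Y, C, I, M)")
    if (y0 < 0).any():
        raise ValueError("initial state must be nonnegative")
    evs = event_times(schedule, (t0, t1))
    bounds = [t0] + evs + [t1]

    ts: List[float] = [t0]
    ys: List[np.ndarray] = [y0.copy()]
    clip_total = 0
    stride_counter = 0

    def record(t: float, y: np.ndarray) -> None:
        nonlocal stride_counter
        stride_counter += 1
        if stride_counter % config.save_stride == 0:
            ts.append(t)
            ys.append(y.copy())

    y = y0
    for a, b in zip(bounds[:-1], bounds[1:]):
        doses = dose_at(schedule, 0.5 * (a + b))
        rhs = make_rhs(params, doses)
        y, clipped = _integrate_segment(rhs, a, b, y, config, record)
        clip_total += clipped
    if ts[-1] != bounds[-1]:
        ts.append(bounds[-1])
        ys.append(y.copy())
    return Trajectory(np.array(ts), np.array(ys),
                      ("T", "N", "L", "Y", "C", "I", "M"),
                      config.order, config.dt, events=evs, clip_count=clip_total)
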