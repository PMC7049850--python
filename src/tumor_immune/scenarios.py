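"""Named treatment scenarios: the no-treatment, continuous and pulsed studies.

Each scenario bundles a patient parameter set, an initial state, a treatment
schedule and a horizon.  A run integrates the treated system and derives an
:class:`Outcome`: the tumor counts as eradicated when its burden falls below
one cell and stays below it to the horizon (the unstable tumor-free state
means any surviving fraction of a cell would regrow, so the threshold is the
biologically meaningful one of less-than-one whole cell).

Horizons default to 60 days for no-treatment/continuous regimens and 100
days for pulsed regimens (long enough to cover the 9-pulse chemotherapy
course and a regrowth margin).  Initial IL-2 and drug concentrations are
zero unless a scenario states otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .adams import SolverConfig, Trajectory, integrate_treated
from .model import Channel, TreatmentSchedule, rhs_untreated
from .parameters import ParameterSet, patient1, patient2

__all__ = [
    "Scenario",
    "Outcome",
    "ERADICATION_THRESHOLD",
    "registry",
    "get_scenario",
    "run",
    "outcome_matrix",
    "phase_field",
]

#: A tumor below one whole cell that never recovers counts as eradicated.
ERADICATION_THRESHOLD = 1.0


@dataclass(frozen=True)
class Scenario:
    """One named experiment: patient, initial state, schedule, horizon."""

    name: str
    patient: str                      # "patient1" | "patient2"
    initial: Tuple[float, ...]        # (T, N, L, Y, C, I, M)
    schedule: TreatmentSchedule = field(default_factory=TreatmentSchedule)
    horizon: float = 60.0
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.initial) != 7:
            raise ValueError("initial state must have 7 components")
        if any(v < 0 for v in self.initial):
            raise ValueError("initial state must be nonnegative")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    def params(self) -> ParameterSet:
        return patient1() if self.patient == "patient1" else patient2()


@dataclass(frozen=True)
class Outcome:
    """Eradication verdict for one run."""

    eradicated: bool
    eradication_day: Optional[float]   # first crossing below threshold, if sustained
    min_tumor: float
    final_tumor: float
    threshold: float = ERADICATION_THRESHOLD


def _constant(intensity: float) -> Channel:
    return Channel(mode="constant", intensity=intensity)


def _pulsed(intensity: float, start: float, period: float, n: int,
            duration: float = 1.0) -> Channel:
    return Channel(mode="pulsed", intensity=intensity, start=start,
                   period=period, n_pulses=n, duration=duration)


def _state(T: float, N: float, L: float, Y: float, C: float,
           I: float = 0.0, M: float = 0.0) -> Tuple[float, ...]:
    return (T, N, L, Y, C, I, M)


def registry() -> List[Scenario]:
    """All printed regimens of the no-treatment, continuous and pulsed studies."""
    scenarios: List[Scenario] = []

    # --- no treatment, first patient ---
    base1 = dict(N=1e3, L=10.0, Y=1e6, C=6e8)
    scenarios += [
        Scenario("p1_notreat_1e5", "patient1", _state(1e5, **base1),
                 note="immune system clears a small tumor unaided"),
        Scenario("p1_notreat_1e7", "patient1", _state(1e7, **base1),
                 note="a large tumor escapes the unaided immune system"),
        Scenario("p1_notreat_1e7_strong", "patient1",
                 _state(1e7, N=1e3, L=1e2, Y=1e6, C=6e10),
                 note="strengthened immune system (more CD8+T and lymphocytes)"),
    ]

    # --- continuous therapy ---
    scenarios += [
        Scenario("p1_cd8_il2_continuous", "patient1", _state(1e6, **base1),
                 TreatmentSchedule(v_L=_constant(1e4), v_I=_constant(1e4)),
                 note="continuous CD8+T + IL-2 fails for the first patient"),
        Scenario("p1_cd4_continuous", "patient1", _state(1e6, **base1),
                 TreatmentSchedule(v_Y=_constant(1e6)),
                 note="continuous CD4+T alone succeeds for the first patient"),
    ]
    base2 = dict(N=1e3, L=1e2, Y=1e6, C=6e8)
    scenarios += [
        Scenario("p2_cd8_il2_continuous", "patient2", _state(1e6, **base2),
                 TreatmentSchedule(v_L=_constant(1e6), v_I=_constant(1e6))),
        Scenario("p2_cd4_continuous", "patient2", _state(1e6, **base2),
                 TreatmentSchedule(v_Y=_constant(1e6))),
        Scenario("p2_triple_continuous", "patient2", _state(1e6, **base2),
                 TreatmentSchedule(v_L=_constant(1e6), v_I=_constant(1e6),
                                   v_Y=_constant(1e6)),
                 note="combined CD8+T + IL-2 + CD4+T clears the tumor in ~10 days"),
    ]

    # --- pulsed therapy, first patient, T0 = 8e5 ---
    pulsed8 = _state(8e5, N=1e3, L=1e2, Y=1e6, C=6e8)
    chemo5 = _pulsed(5.0, start=6, period=5, n=5)
    cd8_7 = _pulsed(1e5, start=6, period=2, n=7)
    il2_7 = _pulsed(1e5, start=6, period=2, n=7)
    scenarios += [
        Scenario("p1_chemo5_T8e5", "patient1", pulsed8,
                 TreatmentSchedule(v_M=chemo5), horizon=100.0,
                 note="five 1-day chemotherapy infusions, 5-day period"),
        Scenario("p1_cd8_il2_pulsed_T8e5", "patient1", pulsed8,
                 TreatmentSchedule(v_L=cd8_7, v_I=il2_7), horizon=100.0),
        Scenario("p1_cd8_il2_cd4_pulsed_T8e5", "patient1", pulsed8,
                 TreatmentSchedule(v_L=cd8_7, v_I=il2_7,
                                   v_Y=_pulsed(1e7, start=6, period=2, n=5)),
                 horizon=100.0),
    ]

    # --- pulsed therapy, first patient, T0 = 3e6 ---
    pulsed3 = _state(3e6, N=1e3, L=10.0, Y=1e6, C=6e8)
    scenarios += [
        Scenario("p1_chemo5_T3e6", "patient1", pulsed3,
                 TreatmentSchedule(v_M=chemo5), horizon=100.0),
        Scenario("p1_chemo5_cd4_T3e6", "patient1", pulsed3,
                 TreatmentSchedule(v_M=chemo5,
                                   v_Y=_pulsed(6e6, start=6, period=2, n=5)),
                 horizon=100.0),
    ]

    # --- pulsed therapy, first patient, T0 = 1e7 (predecessor-model comparison) ---
    # Nine chemotherapy pulses from day 1 with 10-day period, six sub-day IL-2
    # pulses spread over days 8-11.5 (the printed six-pulses-in-four-days regimen
    # is implemented as six half-day infusions evenly spaced over that window)
    # and a single two-day CD8+T infusion covering days 7-8.  The comparison run
    # has no CD4+T compartment, hence Y(0) = 0.
    scenarios += [
        Scenario("p1_depillis_T1e7", "patient1",
                 _state(1e7, N=1e3, L=10.0, Y=0.0, C=6e8),
                 TreatmentSchedule(
                     v_M=_pulsed(5.0, start=1, period=10, n=9),
                     v_I=_pulsed(5e5, start=8, period=7.0 / 12.0, n=6, duration=0.5),
                     v_L=_pulsed(1e9, start=7, period=2, n=1, duration=2.0)),
                 horizon=100.0,
                 note="nine chemo pulses + intensive CD8+T/IL-2; no CD4 compartment"),
        Scenario("p1_chemo3_cd4_T1e7", "patient1",
                 _state(1e7, N=1e3, L=10.0, Y=1e6, C=6e8),
                 TreatmentSchedule(
                     v_M=_pulsed(5.0, start=1, period=10, n=3),
                     v_Y=_pulsed(4e7, start=6, period=2, n=5)),
                 horizon=100.0,
                 note="reduced chemotherapy with CD4+T support"),
    ]
    return scenarios


def get_scenario(name: str) -> Scenario:
    for sc in registry():
        if sc.name == name:
            return sc
    raise KeyError(f"unknown scenario {name!r}")


def _outcome_from(traj: Trajectory, threshold: float) -> Outcome:
    T = traj.component("T")
    below = T < threshold
    if below[-1]:
        above = np.flatnonzero(~below)
        first = int(above[-1]) + 1 if above.size else 0
        return Outcome(True, float(traj.t[first]), float(T.min()), float(T[-1]),
                       threshold)
    return Outcome(False, None, float(T.min()), float(T[-1]), threshold)


def run(
    scenario: Scenario,
    config: Optional[SolverConfig] = None,
    threshold: float = ERADICATION_THRESHOLD,
) -> Tuple[Trajectory, Outcome]:
    """Integrate one scenario and derive its eradication outcome."""
    config = config or SolverConfig()
    traj = integrate_treated(scenario.params(), np.asarray(scenario.initial),
                             (0.0, scenario.horizon), scenario.schedule, config)
    return traj, _outcome_from(traj, threshold)


def outcome_matrix(
    scenarios: Optional[List[Scenario]] = None,
    config: Optional[SolverConfig] = None,
) -> pd.DataFrame:
    """One row per scenario: verdict, eradication day, min/final tumor burden.

    A per-scenario failure is recorded as a row with ``error`` filled in
    rather than aborting the whole matrix.
    """
    scenarios = registry() if scenarios is None else scenarios
    rows = []
    for sc in scenarios:
        row = {"name": sc.name, "patient": sc.patient, "horizon": sc.horizon}
        try:
            _, outcome = run(sc, config)
            row.update(eradicated=outcome.eradicated,
                       eradication_day=outcome.eradication_day,
                       min_tumor=outcome.min_tumor,
                       final_tumor=outcome.final_tumor, error="")
        except Exception as exc:   # noqa: BLE001 - report, do not abort
            row.update(eradicated=None, eradication_day=None,
                       min_tumor=None, final_tumor=None, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows, columns=["name", "patient", "horizon", "eradicated",
                                       "eradication_day", "min_tumor",
                                       "final_tumor", "error"])


def phase_field(
    params: ParameterSet,
    fixed: Dict[str, float],
    T_range: Tuple[float, float],
    Y_range: Tuple[float, float],
    grid: Tuple[int, int] = (20, 20),
) -> pd.DataFrame:
    """Restricted (T, Y) vector field with the other four states frozen.

    ``fixed`` supplies N, L, C and I (typically the values of an equilibrium
    point); the tumor and CD4+T equations are evaluated on a ``grid`` of
    (T, Y) points for streamline plotting.  Returns one row per grid node
    with columns ``T, Y, dT_dt, dY_dt``.
    """
    for key in ("N", "L", "C", "I"):
        if key not in fixed:
            raise KeyError(f"fixed values must include {key}")
    nT, nY = grid
    if nT < 2 or nY < 2:
        raise ValueError("grid must be at least 2x2")
    Ts = np.linspace(T_range[0], T_range[1], nT)
    Ys = np.linspace(Y_range[0], Y_range[1], nY)
    rows = []
    for T in Ts:
        for Y in Ys:
            state = np.array([T, fixed["N"], fixed["L"], Y, fixed["C"], fixed["I"]])
            rates = rhs_untreated(state, params)
            rows.append({"T": T, "Y": Y, "dT_dt": rates[0], "dY_dt": rates[3]})
    return pd.DataFrame(rows)
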