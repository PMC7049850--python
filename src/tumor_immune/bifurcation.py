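"""One-parameter bifurcation sweeps over the equilibrium structure.

A sweep substitutes each grid value of a single model constant, enumerates
the equilibria on all three branches, classifies their stability and links
points across adjacent grid values into branches by nearest-neighbour
matching in log-state space.  Two kinds of events are then refined by
bisection on the parameter:

* ``stability_switch`` — the verdict along a branch changes sign;
* ``branch_created`` / ``branch_destroyed`` — the number of equilibria of a
  given branch tag changes.

For the tumor-free branch the refined stability switch has closed forms
(``a* = c*e*alpha/(f*beta)`` in an ``a``-sweep, ``c* = a*f*beta/(e*alpha)``
in a ``c``-sweep) against which the bisection result is cross-checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .equilibria import (
    EquilibriumPoint,
    classify,
    nonzero_cytokine_equilibria,
    tumor_free_stable,
    zero_cytokine_equilibria,
    zero_tumor_equilibrium,
)
from .parameters import PARAM_FIELDS, ParameterSet

__all__ = [
    "BranchSample",
    "BifurcationBranch",
    "BifurcationEvent",
    "default_grid",
    "sweep",
    "locate_events",
    "diagram_table",
]


@dataclass(frozen=True)
class BranchSample:
    value: float
    point: EquilibriumPoint
    verdict: str


@dataclass
class BifurcationBranch:
    """One equilibrium curve tracked across the parameter grid."""

    tag: str
    curve_id: int
    samples: List[BranchSample] = field(default_factory=list)

    @property
    def value_range(self) -> Tuple[float, float]:
        return self.samples[0].value, self.samples[-1].value

    def verdicts(self) -> List[str]:
        return [s.verdict for s in self.samples]


@dataclass(frozen=True)
class BifurcationEvent:
    parameter: str
    critical_value: float
    event_type: str                     # stability_switch | branch_created | branch_destroyed | censored
    branch_tag: str
    bracket: Tuple[float, float]
    tolerance: float
    closed_form: Optional[float] = None   # cross-check value where one exists


def default_grid(name: str, lo: float, hi: float) -> np.ndarray:
    """Default sweep grid: log-spaced body plus a linear refinement near zero.

    400 log-spaced samples between ``max(lo, hi*1e-7)`` and ``hi`` plus 100
    linear samples over the first quarter-decade resolve both the tiny
    tumor-free thresholds (~1e-5 scale relative to the range) and the
    branch-existence boundaries.
    """
    if hi <= 0 or hi <= lo:
        raise ValueError("need hi > max(lo, 0)")
    lo_pos = max(lo, hi * 1e-7)
    grid = np.logspace(math.log10(lo_pos), math.log10(hi), 400)
    grid = np.concatenate([grid, np.linspace(lo_pos, hi * 2.5e-3, 100)])
    return np.unique(grid)


def _enumerate_tagged(params: ParameterSet) -> Dict[str, List[EquilibriumPoint]]:
    return {
        "zero_tumor": [zero_tumor_equilibrium(params)],
        "nonzero_tumor_zero_cytokine": zero_cytokine_equilibria(params),
        "nonzero_tumor_nonzero_cytokine": nonzero_cytokine_equilibria(params),
    }


def _log_coords(point: EquilibriumPoint) -> np.ndarray:
    return np.log10(1.0 + point.state())


#: Maximum nearest-neighbour distance (in log10(1+state) space) for two
#: points at adjacent grid values to belong to the same branch.
LINK_THRESHOLD = 1.5


def sweep(
    params: ParameterSet,
    name: str,
    values: Sequence[float],
    classify_points: bool = True,
) -> List[BifurcationBranch]:
    """Track all equilibrium branches while ``name`` runs over ``values``."""
    if name not in PARAM_FIELDS:
        raise KeyError(f"unknown parameter {name!r}")
    values = np.asarray(sorted(float(v) for v in values))
    if (values <= 0).any():
        raise ValueError("swept values must be strictly positive")

    branches: List[BifurcationBranch] = []
    open_branches: List[BifurcationBranch] = []
    next_id = 1
    for v in values:
        pts = _enumerate_tagged(params.replace(**{name: v}))
        new_open: List[BifurcationBranch] = []
        for tag, points in pts.items():
            candidates = [b for b in open_branches if b.tag == tag]
            used = set()
            for point in points:
                verdict = classify(point, params.replace(**{name: v})).verdict \
                    if classify_points else "unclassified"
                best, best_d = None, LINK_THRESHOLD
                for b in candidates:
                    if id(b) in used:
                        continue
                    dist = float(np.abs(_log_coords(point)
                                        - _log_coords(b.samples[-1].point)).max())
                    if dist < best_d:
                        best, best_d = b, dist
                if best is None:
                    best = BifurcationBranch(tag, next_id)
                    next_id += 1
                    branches.append(best)
                used.add(id(best))
                best.samples.append(BranchSample(float(v), point, verdict))
                new_open.append(best)
        open_branches = new_open
    branches.sort(key=lambda b: b.curve_id)
    return branches


def _count_tag(params: ParameterSet, name: str, value: float, tag: str) -> int:
    return len(_enumerate_tagged(params.replace(**{name: value}))[tag])


def _refine_count_change(params: ParameterSet, name: str, tag: str,
                         lo: float, hi: float, tol: float) -> Tuple[float, float, float]:
    n_lo = _count_tag(params, name, lo, tag)
    while hi - lo > tol * max(abs(lo), abs(hi)):
        mid = 0.5 * (lo + hi)
        if _count_tag(params, name, mid, tag) == n_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), lo, hi


def _zero_tumor_margin(params: ParameterSet, name: str, value: float) -> float:
    point = zero_tumor_equilibrium(params.replace(**{name: value}))
    return classify(point, params.replace(**{name: value})).margin


def _refine_sign_change(fun: Callable[[float], float],
                        lo: float, hi: float, tol: float) -> Tuple[float, float, float]:
    f_lo = fun(lo)
    while hi - lo > tol * max(abs(lo), abs(hi)):
        mid = 0.5 * (lo + hi)
        if (fun(mid) > 0) == (f_lo > 0):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), lo, hi


def locate_events(
    branches: List[BifurcationBranch],
    params: ParameterSet,
    name: str,
    tol: float = 1e-4,
) -> List[BifurcationEvent]:
    """Refine branch creation/destruction and stability switches by bisection.

    ``tol`` is the relative bracket width.  Range-boundary ends of branches
    are reported as ``censored`` rather than as bifurcations.
    """
    events: List[BifurcationEvent] = []
    all_values = sorted({s.value for b in branches for s in b.samples})
    if not all_values:
        return events
    v_min, v_max = all_values[0], all_values[-1]

    # branch creation / destruction, per tag
    tags = {b.tag for b in branches}
    for tag in tags:
        if tag == "zero_tumor":
            continue            # exists at every parameter value by closed form
        counts = []
        for v in all_values:
            counts.append(sum(1 for b in branches if b.tag == tag
                              and any(s.value == v for s in b.samples)))
        for (v0, n0), (v1, n1) in zip(zip(all_values, counts), zip(all_values[1:], counts[1:])):
            if n0 == n1:
                continue
            crit, lo, hi = _refine_count_change(params, name, tag, v0, v1, tol)
            etype = "branch_created" if n1 > n0 else "branch_destroyed"
            events.append(BifurcationEvent(name, crit, etype, tag, (lo, hi), tol))

    # stability switches along each branch
    for b in branches:
        for s0, s1 in zip(b.samples, b.samples[1:]):
            if s0.verdict == s1.verdict or "marginal" in (s0.verdict, s1.verdict):
                continue
            if b.tag == "zero_tumor":
                crit, lo, hi = _refine_sign_change(
                    lambda v: _zero_tumor_margin(params, name, v),
                    s0.value, s1.value, tol)
                closed = None
                if name == "a":
                    closed = tumor_free_stable(params)[1]
                elif name == "c":
                    closed = tumor_free_stable(params)[2]
                events.append(BifurcationEvent(name, crit, "stability_switch",
                                               b.tag, (lo, hi), tol, closed_form=closed))
            else:
                # verdict change on a tracked nonzero branch: bisect on the
                # verdict of the nearest same-tag point
                ref = s0.point

                def margin_of(v: float) -> float:
                    pts = _enumerate_tagged(params.replace(**{name: v}))[b.tag]
                    if not pts:
                        return math.nan
                    best = min(pts, key=lambda q: float(
                        np.abs(_log_coords(q) - _log_coords(ref)).max()))
                    return classify(best, params.replace(**{name: v})).margin

                crit, lo, hi = _refine_sign_change(margin_of, s0.value, s1.value, tol)
                events.append(BifurcationEvent(name, crit, "stability_switch",
                                               b.tag, (lo, hi), tol))

    # censored branch ends at the swept range boundary
    for b in branches:
        for end, v in zip(("low", "high"), b.value_range):
            if v in (v_min, v_max):
                events.append(BifurcationEvent(name, v, "censored", b.tag,
                                               (v, v), 0.0))
    events.sort(key=lambda e: e.critical_value)
    return events


def branch_boundary(
    params: ParameterSet,
    name: str,
    tag: str,
    inside: float,
    outside: float,
    tol: float = 1e-4,
) -> float:
    """Bisect the parameter value where equilibria of ``tag`` (dis)appear.

    ``inside`` must be a parameter value at which at least one point of the
    tag exists and ``outside`` one at which none does.
    """
    n_in = _count_tag(params, name, inside, tag)
    n_out = _count_tag(params, name, outside, tag)
    if n_in == 0 or n_out != 0:
        raise ValueError("bracket does not straddle a branch boundary")
    lo, hi = (inside, outside) if inside < outside else (outside, inside)
    crit, _, _ = _refine_count_change(params, name, tag, lo, hi, tol)
    return crit


def diagram_table(
    branches: List[BifurcationBranch],
    events: Optional[List[BifurcationEvent]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format branch table plus events table for external plotting."""
    rows = []
    for b in branches:
        for s in b.samples:
            rows.append({"value": s.value, "curve": b.curve_id, "branch": b.tag,
                         "T_eq": s.point.T, "N_eq": s.point.N, "L_eq": s.point.L,
                         "Y_eq": s.point.Y, "I_eq": s.point.I, "verdict": s.verdict})
    branch_df = pd.DataFrame(rows, columns=["value", "curve", "branch", "T_eq",
                                            "N_eq", "L_eq", "Y_eq", "I_eq", "verdict"])
    ev_rows = []
    for e in events or []:
        ev_rows.append({"parameter": e.parameter, "critical_value": e.critical_value,
                        "event_type": e.event_type, "branch": e.branch_tag,
                        "bracket_lo": e.bracket[0], "bracket_hi": e.bracket[1],
                        "tolerance": e.tolerance, "closed_form": e.closed_form})
    event_df = pd.DataFrame(ev_rows, columns=["parameter", "critical_value", "event_type",
                                              "branch", "bracket_lo", "bracket_hi",
                                              "tolerance", "closed_form"])
    return branch_df, event_df
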