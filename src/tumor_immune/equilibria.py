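"""Equilibria and linear stability of the unforced tumor-immune system.

Setting the six untreated equations to zero splits the equilibria into three
branches:

* ``zero_tumor`` — the closed form ``(0, e*alpha/(f*beta), 0, 0, alpha/beta, 0)``;
* ``nonzero_tumor_zero_cytokine`` — tumor present, ``I = Y = 0``; found by
  scanning the tumor size, evaluating the NK and CD8+T populations consistent
  with the reduced equilibrium relations and bisecting the residual of the
  CD8+T balance;
* ``nonzero_tumor_nonzero_cytokine`` — the active CD4+T/cytokine loop; tumor
  sizes are the positive roots of a cubic whose coefficients involve only the
  CD4/cytokine constants, with the remaining components recovered from a
  one-dimensional solve in the cytokine concentration.

The tumor-free state is linearly stable iff ``a - c*e*alpha/(f*beta) < 0``;
the corresponding critical values of ``a`` and ``c`` drive the bifurcation
module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .model import lysis_fraction_D, rhs_untreated, rhs_untreated_terms
from .parameters import ParameterSet

__all__ = [
    "EquilibriumPoint",
    "StabilityReport",
    "BranchInvalidError",
    "zero_tumor_equilibrium",
    "zero_tumor_eigenvalues",
    "tumor_free_stable",
    "nk_at_tumor",
    "cd8_from_lysis",
    "zero_cytokine_equilibria",
    "cytokine_tumor_candidates",
    "nonzero_cytokine_equilibria",
    "enumerate_equilibria",
    "jacobian",
    "classify",
    "equilibria_table",
]

BRANCHES = ("zero_tumor", "nonzero_tumor_zero_cytokine", "nonzero_tumor_nonzero_cytokine")

#: Relative width of the marginal-stability band around Re(lambda) = 0.
MARGINAL_BAND = 1e-8


class BranchInvalidError(ValueError):
    """No physical equilibrium exists on the requested branch at this point."""


@dataclass(frozen=True)
class EquilibriumPoint:
    """One equilibrium state with its branch label and residual."""

    branch: str
    T: float
    N: float
    L: float
    Y: float
    C: float
    I: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        if self.branch not in BRANCHES:
            raise ValueError(f"unknown branch {self.branch!r}")
        for name in ("T", "N", "L", "Y", "C", "I"):
            if getattr(self, name) < 0:
                raise ValueError(f"equilibrium component {name} must be nonnegative")

    def state(self) -> np.ndarray:
        return np.array([self.T, self.N, self.L, self.Y, self.C, self.I])


@dataclass(frozen=True)
class StabilityReport:
    """Eigenvalues and verdict for one equilibrium."""

    point: EquilibriumPoint
    eigenvalues: Tuple[complex, ...]
    verdict: str            # "stable" | "unstable" | "marginal"
    margin: float           # max real part


def _relative_residual(state: np.ndarray, params: ParameterSet) -> float:
    """Residual of the six equations relative to the largest competing term."""
    rates = rhs_untreated(state, params)
    terms = rhs_untreated_terms(state, params)
    worst = 0.0
    for rate, eq_terms in zip(rates, terms):
        scale = max(abs(t) for t in eq_terms)
        if scale > 0:
            worst = max(worst, abs(rate) / scale)
    return worst


# ---------------------------------------------------------------------------
# zero-tumor branch (closed form)
# ---------------------------------------------------------------------------

def zero_tumor_equilibrium(params: ParameterSet) -> EquilibriumPoint:
    """The tumor-free steady state ``(0, e*alpha/(f*beta), 0, 0, alpha/beta, 0)``."""
    p = params
    N = p.e * p.alpha / (p.f * p.beta)
    C = p.alpha / p.beta
    state = np.array([0.0, N, 0.0, 0.0, C, 0.0])
    return EquilibriumPoint("zero_tumor", 0.0, N, 0.0, 0.0, C, 0.0,
                            residual=_relative_residual(state, params))


def zero_tumor_eigenvalues(params: ParameterSet) -> np.ndarray:
    """Closed-form eigenvalues at the tumor-free state.

    ``lambda_1 = a - c*e*alpha/(f*beta)`` governs tumor recurrence; the other
    five are the negated decay rates ``-f, -m, -mu1, -beta, -mu_i``.
    """
    p = params
    lam1 = p.a - p.c * p.e * p.alpha / (p.f * p.beta)
    return np.array([lam1, -p.f, -p.m, -p.mu1, -p.beta, -p.mu_i])


def tumor_free_stable(params: ParameterSet) -> Tuple[bool, float, float]:
    """Stability of the tumor-free state and the two critical parameter values.

    Returns ``(stable, a_crit, c_crit)`` where ``a_crit = c*e*alpha/(f*beta)``
    and ``c_crit = a*f*beta/(e*alpha)``; the state is stable iff
    ``a < a_crit`` (equivalently ``c > c_crit``).
    """
    p = params
    a_crit = p.c * p.e * p.alpha / (p.f * p.beta)
    c_crit = p.a * p.f * p.beta / (p.e * p.alpha)
    return p.a < a_crit, a_crit, c_crit


# ---------------------------------------------------------------------------
# reduced equilibrium relations for nonzero tumor
# ---------------------------------------------------------------------------

def nk_at_tumor(T: float, params: ParameterSet) -> float:
    """NK population in equilibrium with a tumor of size ``T``.

    Combines the NK and lymphocyte balances:
    ``N(T) = e*alpha*(h + T^2) / (beta*(p*T^3 + (f-g)*T^2 + p*h*T + f*h))``.
    Raises :class:`BranchInvalidError` if the denominator is not positive
    (no physical equilibrium at this tumor size).
    """
    if T < 0:
        raise ValueError("T must be nonnegative")
    p = params
    den = p.beta * (p.p * T**3 + (p.f - p.g) * T**2 + p.p * p.h * T + p.f * p.h)
    if den <= 0:
        raise BranchInvalidError(f"nonpositive NK denominator at T={T:.6g}")
    return p.e * p.alpha * (p.h + T * T) / den


def cd8_from_lysis(T: float, D_target: float, params: ParameterSet) -> float:
    """CD8+T population that produces lysis rate ``D_target`` against tumor ``T``.

    Inverts the saturating lysis relation:
    ``L = (s*D/(d-D))**(1/l) * T``; requires ``0 <= D_target < d``.
    """
    p = params
    if D_target < 0 or D_target >= p.d:
        raise BranchInvalidError(f"no CD8+T level yields lysis {D_target:.6g} (d={p.d})")
    if D_target == 0.0:
        return 0.0
    return (p.s * D_target / (p.d - D_target)) ** (1.0 / p.l) * T


def _lysis_demand(T: float, I: float, params: ParameterSet) -> float:
    """Lysis rate demanded by the tumor balance at equilibrium (may be invalid)."""
    p = params
    N = nk_at_tumor(T, p)
    return p.a * (1 - p.b * T) - p.c * N - p.c1 * I / (p.a1 + T)


def _cd8_residual(T: float, I: float, L: float, params: ParameterSet) -> float:
    """Residual of the CD8+T balance at equilibrium (zero at a true equilibrium)."""
    p = params
    N = nk_at_tumor(T, p)
    D = lysis_fraction_D(T, L, p)
    DT2 = (D * T) ** 2
    recruit = p.j * DT2 / (p.k + DT2)
    boost = p.p_i * I / (p.g_i + I)
    return (p.u * N * L * L + (p.m - recruit + p.q * T - boost) * L
            - (p.r1 * N + p.r2 * p.alpha / p.beta) * T)


def _branch_residual_in_T(T: float, params: ParameterSet) -> Optional[float]:
    """Zero-cytokine branch residual as a function of tumor size alone."""
    try:
        D = _lysis_demand(T, 0.0, params)
        if not 0.0 <= D < params.d:
            return None
        L = cd8_from_lysis(T, D, params)
    except BranchInvalidError:
        return None
    return _cd8_residual(T, 0.0, L, params)


def _bisect(fun: Callable[[float], Optional[float]], lo: float, hi: float,
            f_lo: float, rtol: float = 1e-10, log: bool = False) -> float:
    """Bisection on a sign change; ``None`` values abort toward the last bracket."""
    for _ in range(200):
        mid = math.sqrt(lo * hi) if log else 0.5 * (lo + hi)
        if hi - lo <= rtol * max(abs(lo), abs(hi)):
            return mid
        val = fun(mid)
        if val is None:
            return mid
        if val == 0.0:
            return mid
        if (val > 0) == (f_lo > 0):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _package_point(branch: str, T: float, N: float, L: float, Y: float,
                   I: float, params: ParameterSet) -> EquilibriumPoint:
    C = params.alpha / params.beta
    state = np.array([T, N, L, Y, C, I])
    return EquilibriumPoint(branch, T, N, L, Y, C, I,
                            residual=_relative_residual(state, params))


def zero_cytokine_equilibria(
    params: ParameterSet,
    t_grid: Optional[Tuple[float, float, int]] = None,
    residual_tol: float = 1e-6,
) -> List[EquilibriumPoint]:
    """Equilibria with tumor present and ``I = Y = 0``.

    Scans tumor size logarithmically over ``(1, 1/b)`` (2000 points by
    default), evaluates the lysis demand, NK level and the CD8+T population
    consistent with it, and refines sign changes of the CD8+T balance by
    bisection.  Tumor sizes whose lysis demand falls outside ``[0, d)`` are
    branch-invalid and skipped.
    """
    lo_T, hi_T, n = t_grid or (1.0, 1.0 / params.b, 2000)
    Ts = np.logspace(math.log10(lo_T), math.log10(hi_T), int(n))
    vals = [_branch_residual_in_T(T, params) for T in Ts]
    points: List[EquilibriumPoint] = []
    for i in range(len(Ts) - 1):
        v0, v1 = vals[i], vals[i + 1]
        if v0 is None or v1 is None or v0 * v1 > 0:
            continue
        T_root = _bisect(lambda T: _branch_residual_in_T(T, params),
                         Ts[i], Ts[i + 1], v0, rtol=1e-10, log=True)
        N = nk_at_tumor(T_root, params)
        D = _lysis_demand(T_root, 0.0, params)
        if not 0.0 <= D < params.d:
            continue
        L = cd8_from_lysis(T_root, D, params)
        point = _package_point("nonzero_tumor_zero_cytokine",
                               T_root, N, L, 0.0, 0.0, params)
        if point.residual < residual_tol:
            points.append(point)
    return points


def cytokine_tumor_candidates(params: ParameterSet, imag_tol: float = 1e-9) -> List[float]:
    """Positive real tumor sizes admitted by the active-cytokine balance.

    They are the roots of the cubic
    ``T^3 + (alpha1 + alpha2 + mu1/delta2 - beta1*beta2/(delta2*mu_i)) T^2
    + (alpha1*alpha2 + mu1*(alpha1 + alpha2)/delta2) T
    + mu1*alpha1*alpha2/delta2 = 0``
    solved via the companion matrix and polished with one Newton step.
    """
    p = params
    c2 = p.alpha1 + p.alpha2 + p.mu1 / p.delta2 - p.beta1 * p.beta2 / (p.delta2 * p.mu_i)
    c1 = p.alpha1 * p.alpha2 + p.mu1 * (p.alpha1 + p.alpha2) / p.delta2
    c0 = p.mu1 * p.alpha1 * p.alpha2 / p.delta2
    roots = np.roots([1.0, c2, c1, c0])
    out = []
    for r in roots:
        if abs(r.imag) > imag_tol * max(1.0, abs(r)):
            continue
        x = r.real
        if x <= 0:
            continue
        # one Newton polish on the cubic
        fx = ((x + c2) * x + c1) * x + c0
        dfx = (3.0 * x + 2.0 * c2) * x + c1
        if dfx != 0:
            x -= fx / dfx
        if x > 0:
            out.append(float(x))
    return sorted(out)


def nonzero_cytokine_equilibria(
    params: ParameterSet,
    i_grid: Optional[Tuple[float, float, int]] = None,
    residual_tol: float = 1e-6,
) -> List[EquilibriumPoint]:
    """Equilibria with the CD4+T/cytokine loop active (``I > 0``).

    For each tumor-size candidate from :func:`cytokine_tumor_candidates`,
    scans the cytokine concentration logarithmically, computes the CD8+T
    population consistent with the lysis demand at that ``(T, I)`` and
    bisects sign changes of the CD8+T balance; the CD4+T population follows
    from the cytokine balance, ``Y = mu_i*I*(alpha2 + T)/(beta2*T)``.
    """
    lo_I, hi_I, n = i_grid or (1e-3, 1e12, 4000)
    p = params
    points: List[EquilibriumPoint] = []
    for T in cytokine_tumor_candidates(params):
        def resid(I: float) -> Optional[float]:
            try:
                D = _lysis_demand(T, I, p)
                if not 0.0 <= D < p.d:
                    return None
                L = cd8_from_lysis(T, D, p)
            except BranchInvalidError:
                return None
            return _cd8_residual(T, I, L, p)

        Is = np.logspace(math.log10(lo_I), math.log10(hi_I), int(n))
        vals = [resid(I) for I in Is]
        for i in range(len(Is) - 1):
            v0, v1 = vals[i], vals[i + 1]
            if v0 is None or v1 is None or v0 * v1 > 0:
                continue
            I_root = _bisect(resid, Is[i], Is[i + 1], v0, rtol=1e-10, log=True)
            D = _lysis_demand(T, I_root, p)
            if not 0.0 <= D < p.d:
                continue
            L = cd8_from_lysis(T, D, p)
            Y = p.mu_i * I_root * (p.alpha2 + T) / (p.beta2 * T)
            point = _package_point("nonzero_tumor_nonzero_cytokine",
                                   T, nk_at_tumor(T, p), L, Y, I_root, p)
            if point.residual < residual_tol:
                points.append(point)
    return points


def enumerate_equilibria(params: ParameterSet) -> List[EquilibriumPoint]:
    """All equilibria on the three branches, zero-tumor first."""
    out = [zero_tumor_equilibrium(params)]
    out += zero_cytokine_equilibria(params)
    out += nonzero_cytokine_equilibria(params)
    return out


# ---------------------------------------------------------------------------
# linearization
# ---------------------------------------------------------------------------

def jacobian(state, params: ParameterSet, base_step: float = 1e-6,
             min_step: float = 1e-3) -> np.ndarray:
    """Finite-difference Jacobian of the untreated system at ``state``.

    Central differences with per-component step ``max(base_step*|x|,
    min_step)``; components at zero (where the lysis term is one-sided) use
    a forward difference instead.
    """
    x = np.asarray(state, dtype=float)
    if isinstance(state, EquilibriumPoint):
        x = state.state()
    if x.shape != (6,):
        raise ValueError("state must have 6 components")
    J = np.empty((6, 6))
    for i in range(6):
        step = max(base_step * abs(x[i]), min_step)
        hi = x.copy()
        hi[i] += step
        if x[i] - step < 0.0:
            f0 = rhs_untreated(x, params)
            J[:, i] = (rhs_untreated(hi, params) - f0) / step
        else:
            lo = x.copy()
            lo[i] -= step
            J[:, i] = (rhs_untreated(hi, params) - rhs_untreated(lo, params)) / (2 * step)
    return J


def classify(point: EquilibriumPoint, params: ParameterSet) -> StabilityReport:
    """Eigenvalues of the numerical Jacobian and a stability verdict.

    The verdict is ``stable`` iff every eigenvalue has negative real part,
    with a relative marginal band: if the leading real part is within
    ``1e-8`` of zero (relative to the spectral radius) the verdict is
    withheld as ``marginal`` — bifurcation sweeps pass through zero
    eigenvalues and a forced verdict there would be noise.
    """
    eig = np.linalg.eigvals(jacobian(point.state(), params))
    margin = float(eig.real.max())
    scale = max(1.0, float(np.abs(eig).max()))
    if abs(margin) < MARGINAL_BAND * scale:
        verdict = "marginal"
    else:
        verdict = "stable" if margin < 0 else "unstable"
    return StabilityReport(point, tuple(eig), verdict, margin)


def equilibria_table(params: ParameterSet) -> pd.DataFrame:
    """Tabular stability report over all equilibria (one row per point)."""
    rows = []
    for point in enumerate_equilibria(params):
        report = classify(point, params)
        rows.append({
            "branch": point.branch,
            "T": point.T, "N": point.N, "L": point.L,
            "Y": point.Y, "C": point.C, "I": point.I,
            "residual": point.residual,
            "verdict": report.verdict,
            "max_re_lambda": report.margin,
            "eigenvalues": ";".join(f"{z.real:.6g}{z.imag:+.6g}j" for z in report.eigenvalues),
        })
    return pd.DataFrame(rows)
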