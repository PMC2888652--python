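"""Deterministic analysis: fixed points, stability, bifurcations, limit cycles.

The Oct4-Sox2 sub-system is autonomous, so the analysis first solves the 1-D
OS steady state and then studies the Nanog (fluctuation scenario) or the
Nanog/X (oscillation scenario) sub-system at the fixed OS level.  Roots are
located by dense sign-change bracketing followed by Brent refinement — a
derivative-free strategy that is guaranteed for these bounded, saturating
right-hand sides.  Hopf points along the repression-strength axis are found
from the eigenvalues of the 2x2 Nanog/X Jacobian; limit cycles are measured
by long integration with transient discard and successive-maxima detection
(no continuation software).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import (ScenarioParams, Scenario, SystemState, hill,
                    _n_drift_core, _n_drift_osc, _os_drift, _x_drift)

__all__ = [
    "FixedPoint",
    "LimitCycle",
    "BifurcationBranch",
    "os_fixed_points",
    "nanog_fixed_points",
    "nanog_x_fixed_points",
    "scan_bifurcation",
    "find_limit_cycle",
]

#: residual tolerance for reported fixed points
ROOT_TOL = 1e-10
#: eigenvalue real parts within this window of zero are flagged marginal
MARGINAL_TOL = 1e-8


@dataclass(frozen=True)
class FixedPoint:
    """A stationary state with linear-stability classification."""

    os: float
    n: float
    x: Optional[float]
    stability: str               # "stable" | "unstable" | "saddle"
    eigenvalues: tuple

    @property
    def state(self) -> SystemState:
        return SystemState(t=0.0, os=self.os, n=self.n, x=self.x)


@dataclass(frozen=True)
class LimitCycle:
    """Periodic attractor of the Nanog/X sub-system (OS held at its root)."""

    period: float
    n_min: float
    n_max: float
    x_min: float
    x_max: float

    @property
    def found(self) -> bool:
        return True


@dataclass(frozen=True)
class NoCycle:
    """Sentinel result when a deterministic run settles to a fixed point."""

    reason: str = "converged to fixed point"

    @property
    def found(self) -> bool:
        return False


@dataclass
class BifurcationBranch:
    """One-parameter scan result for ``s4`` (folds) or ``s6`` (Hopf)."""

    parameter_name: str
    parameter_values: np.ndarray
    fixed_points: List[List[FixedPoint]]
    cycles: List[Optional[LimitCycle]]
    bistable_window: Optional[tuple]
    oscillatory_window: Optional[tuple]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: parameter, branch_id, type, os, n, x, period."""
        rows = []
        for pv, fps, cyc in zip(self.parameter_values, self.fixed_points,
                                self.cycles):
            for j, fp in enumerate(fps):
                rows.append(dict(parameter=pv, branch_id=j,
                                 type=f"fp_{fp.stability}",
                                 os=fp.os, n=fp.n, x=fp.x, period=np.nan))
            if cyc is not None and cyc.found:
                rows.append(dict(parameter=pv, branch_id=-1, type="cycle_min",
                                 os=np.nan, n=cyc.n_min, x=cyc.x_min,
                                 period=cyc.period))
                rows.append(dict(parameter=pv, branch_id=-1, type="cycle_max",
                                 os=np.nan, n=cyc.n_max, x=cyc.x_max,
                                 period=cyc.period))
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# root bracketing helpers
# ---------------------------------------------------------------------------

def _bracketed_roots(fun: Callable[[float], float], lo: float, hi: float,
                     n_grid: int = 4000) -> List[float]:
    """All sign-change roots of ``fun`` on [lo, hi] via dense scan + Brent."""
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([fun(g) for g in grid])
    roots: List[float] = []
    if abs(vals[0]) < ROOT_TOL:
        roots.append(grid[0])
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0 and i > 0:
            roots.append(grid[i])
        elif a * b < 0:
            try:
                roots.append(brentq(fun, grid[i], grid[i + 1],
                                    xtol=ROOT_TOL, rtol=8.9e-16))
            except ValueError as exc:  # pragma: no cover - diagnostic path
                raise RuntimeError(
                    f"root refinement failed in bracket "
                    f"[{grid[i]:.6g}, {grid[i+1]:.6g}]: {exc}")
    # deduplicate near-identical roots
    out: List[float] = []
    for r in roots:
        if not out or abs(r - out[-1]) > 1e-8 * max(1.0, abs(r)):
            out.append(r)
    return out


def _classify_scalar(slope: float) -> str:
    if abs(slope) < MARGINAL_TOL:
        raise ArithmeticError(
            f"marginal fixed point (|slope| = {abs(slope):.2e} < "
            f"{MARGINAL_TOL}); refine parameters")
    return "stable" if slope < 0 else "unstable"


def _classify_eigs(eigs: np.ndarray) -> str:
    re = eigs.real
    if np.any(np.abs(re) < MARGINAL_TOL):
        raise ArithmeticError("marginal fixed point (eigenvalue real part "
                              "within tie window of zero)")
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


# ---------------------------------------------------------------------------
# fixed points
# ---------------------------------------------------------------------------

def os_fixed_points(p: ScenarioParams) -> List[FixedPoint]:
    """All non-negative fixed points of the autonomous OS sub-system."""
    ceiling = p.os_production_ceiling / p.d_os
    hi = 2.0 * max(ceiling, 1.0)
    fun = lambda os: _os_drift(os, p)
    roots = _bracketed_roots(fun, 0.0, hi)
    out = []
    eps = 1e-7
    for r in roots:
        slope = (fun(r + eps) - fun(max(r - eps, 0.0))) / (
            (r + eps) - max(r - eps, 0.0))
        out.append(FixedPoint(os=r, n=math.nan, x=None,
                              stability=_classify_scalar(slope),
                              eigenvalues=(complex(slope),)))
    return out


def os_star(p: ScenarioParams) -> float:
    """The operating Oct4-Sox2 level: the largest stable OS fixed point."""
    fps = [fp for fp in os_fixed_points(p) if fp.stability == "stable"]
    return max(fp.os for fp in fps)


def nanog_fixed_points(p: ScenarioParams, os_level: float,
                       ) -> List[FixedPoint]:
    """Fixed points of the 1-D Nanog sub-system at a fixed OS level."""
    if os_level < 0:
        raise ValueError("os_level must be >= 0")
    n_max = 10.0 * (p.s3 + p.s4) / p.d_n
    fun = lambda n: _n_drift_core(os_level, n, p)
    roots = _bracketed_roots(fun, 0.0, n_max)
    out = []
    eps = 1e-7
    for r in roots:
        lo = max(r - eps, 0.0)
        slope = (fun(r + eps) - fun(lo)) / (r + eps - lo)
        out.append(FixedPoint(os=os_level, n=r, x=None,
                              stability=_classify_scalar(slope),
                              eigenvalues=(complex(slope),)))
    return out


def _nx_jacobian(p: ScenarioParams, os_level: float, n: float, x: float,
                 eps: float = 1e-6) -> np.ndarray:
    fn = lambda nn, xx: _n_drift_osc(os_level, nn, xx, p)
    fx = lambda nn, xx: _x_drift(nn, xx, p)
    J = np.empty((2, 2))
    J[0, 0] = (fn(n + eps, x) - fn(n - eps, x)) / (2 * eps)
    J[0, 1] = (fn(n, x + eps) - fn(n, x - eps)) / (2 * eps)
    J[1, 0] = (fx(n + eps, x) - fx(n - eps, x)) / (2 * eps)
    J[1, 1] = (fx(n, x + eps) - fx(n, x - eps)) / (2 * eps)
    return J


def nanog_x_fixed_points(p: ScenarioParams, os_level: float,
                         ) -> List[FixedPoint]:
    """Fixed points of the 2-D Nanog/X sub-system at a fixed OS level.

    X is eliminated through its own nullcline ``x*(n) = s5*H(n)/d_x``; the
    remaining 1-D problem is bracketed densely in n.  Stability comes from
    the eigenvalues of the full 2x2 Jacobian.
    """
    if not p.has_x:
        raise ValueError("nanog_x_fixed_points requires the oscillation "
                         "scenario")
    x_of_n = lambda n: p.s5 * hill(n, p.k5, p.gamma_n) / p.d_x
    fun = lambda n: _n_drift_osc(os_level, n, x_of_n(n), p)
    n_max = 10.0 * (p.s3 + p.s4) / p.d_n
    roots = _bracketed_roots(fun, 0.0, n_max)
    out = []
    for r in roots:
        x = x_of_n(r)
        eigs = np.linalg.eigvals(_nx_jacobian(p, os_level, r, x))
        out.append(FixedPoint(os=os_level, n=r, x=x,
                              stability=_classify_eigs(eigs),
                              eigenvalues=tuple(eigs)))
    return out


# ---------------------------------------------------------------------------
# limit cycle
# ---------------------------------------------------------------------------

def find_limit_cycle(p: ScenarioParams, os_level: Optional[float] = None,
                     t_max: float = 2000.0, initial: tuple = (1.0, 0.0),
                     rel_tol: float = 1e-4):
    """Detect and measure the deterministic Nanog/X limit cycle.

    Integrates the noise-free 2-D sub-system for ``t_max`` time units,
    discards the first half as transient, and measures the period from
    successive Nanog maxima.  Returns :class:`LimitCycle` on success or
    :class:`NoCycle` when the trajectory settles onto a fixed point (so
    parameter scans can proceed without exception handling).
    """
    if not p.has_x:
        return NoCycle(reason="no repressor X in this scenario")
    if os_level is None:
        os_level = os_star(p)

    def rhs(t, y):
        return [_n_drift_osc(os_level, y[0], y[1], p),
                _x_drift(y[0], y[1], p)]

    sol = solve_ivp(rhs, (0.0, t_max), list(initial), method="LSODA",
                    rtol=1e-9, atol=1e-10, dense_output=False,
                    max_step=t_max / 4000.0)
    t, n, x = sol.t, sol.y[0], sol.y[1]
    half = np.searchsorted(t, t[-1] / 2.0)
    t, n, x = t[half:], n[half:], x[half:]
    span = n.max() - n.min()
    if span < rel_tol * max(1.0, n.max()):
        return NoCycle()
    interior = (n[1:-1] > n[:-2]) & (n[1:-1] >= n[2:])
    peak_t = t[1:-1][interior]
    peak_n = n[1:-1][interior]
    # ignore numerical micro-peaks far below the global amplitude
    keep = peak_n > n.min() + 0.5 * span
    peak_t = peak_t[keep]
    if len(peak_t) < 3:
        return NoCycle(reason="fewer than 3 maxima after transient")
    periods = np.diff(peak_t)
    period = float(np.median(periods))
    if period <= 0 or np.std(periods) > 0.05 * period:
        return NoCycle(reason="maxima not periodic")
    # measure extrema over complete cycles only
    t0 = peak_t[0]
    k = int((peak_t[-1] - t0) / period)
    mask = (t >= t0) & (t <= t0 + k * period)
    return LimitCycle(period=period,
                      n_min=float(n[mask].min()), n_max=float(n[mask].max()),
                      x_min=float(x[mask].min()), x_max=float(x[mask].max()))


# ---------------------------------------------------------------------------
# one-parameter scans
# ---------------------------------------------------------------------------

def _window_from_mask(grid: np.ndarray, mask: np.ndarray) -> Optional[tuple]:
    if not mask.any():
        return None
    idx = np.flatnonzero(mask)
    # demand one contiguous interval
    if not np.all(np.diff(idx) == 1):
        runs = np.split(idx, np.flatnonzero(np.diff(idx) != 1) + 1)
        idx = max(runs, key=len)
    return (float(grid[idx[0]]), float(grid[idx[-1]]))


def scan_bifurcation(p: ScenarioParams, parameter_name: str,
                     grid: Sequence[float],
                     measure_cycles: bool = True) -> BifurcationBranch:
    """Sweep ``s4`` (bistable window) or ``s6`` (oscillatory window).

    For ``s4`` the Nanog sub-system is scanned for fold structure (3 roots =
    bistable).  For ``s6`` the Nanog/X fixed points are classified by their
    Jacobian eigenvalues; grid values whose only fixed point is an unstable
    spiral delimit the oscillatory window, inside which the limit-cycle
    extrema are measured by integration (``measure_cycles=False`` skips the
    integrations for coarse scans).
    """
    grid = np.asarray(grid, dtype=float)
    if parameter_name not in ("s4", "s6"):
        raise ValueError("parameter_name must be 's4' or 's6'")
    if np.any(grid < 0):
        raise ValueError("grid values must be >= 0")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    osl = os_star(p)
    fps_per: List[List[FixedPoint]] = []
    cycles: List[Optional[LimitCycle]] = []
    if parameter_name == "s4":
        for v in grid:
            fps_per.append(nanog_fixed_points(p.with_(s4=float(v)), osl))
            cycles.append(None)
        n_stable = np.array([sum(fp.stability == "stable" for fp in fps)
                             for fps in fps_per])
        window = (None if len(grid) < 2
                  else _window_from_mask(grid, n_stable >= 2))
        return BifurcationBranch(parameter_name, grid, fps_per, cycles,
                                 bistable_window=window,
                                 oscillatory_window=None)
    # s6 scan
    for v in grid:
        pv = p.with_(s6=float(v))
        fps = nanog_x_fixed_points(pv, osl)
        fps_per.append(fps)
    oscillatory = np.array([
        len(fps) > 0 and not any(fp.stability == "stable" for fp in fps)
        for fps in fps_per])
    for v, osc in zip(grid, oscillatory):
        if osc and measure_cycles:
            cyc = find_limit_cycle(p.with_(s6=float(v)), os_level=osl)
            cycles.append(cyc if cyc.found else None)
        else:
            cycles.append(None)
    window = (None if len(grid) < 2
              else _window_from_mask(grid, oscillatory))
    return BifurcationBranch(parameter_name, grid, fps_per, cycles,
                             bistable_window=None,
                             oscillatory_window=window)
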