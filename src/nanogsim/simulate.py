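"""Euler-Maruyama simulation of single cells and independent-cell ensembles.

The update rule per step of size ``dt`` is the deterministic drift step plus
a Gaussian increment ``sigma * g(OS) * sqrt(dt) * eta`` added to the Nanog
component only (``eta`` standard normal); Oct4-Sox2 and the repressor X
integrate deterministically.  ``g(OS)`` couples the noise amplitude to the
Oct4-Sox2-dependent Nanog promoter activity, normalized so that ``g = 1`` at
the unperturbed OS steady state: every baseline simulation sees exactly the
Table-level amplitude ``sigma``, while a collapsed pluripotency network
(OS -> 0) is transcriptionally silent and produces no Nanog noise.

Negative-concentration handling (``clamp``):

* ``"truncate"`` (default) -- the state itself is clamped, ``[N] =
  max([N], 0)`` after every step.
* ``"output"`` -- the latent state may range over the whole real line
  (regulatory production vanishes below zero, first-order decay restores);
  only the *recorded* concentrations are truncated at zero.  This variant
  reproduces the bimodal population distribution with its ~20% Nanog-low
  mode; see the methods note for the dichotomy between the two readings.

Reproducibility: per-cell generators are spawned from the master seed via
``numpy.random.SeedSequence``, so ensembles are bit-reproducible and a
one-cell ensemble equals ``simulate_cell`` run with the first spawned child.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model import (ScenarioParams, Scenario, SignalParams, SystemState,
                    hill, _n_drift_core, _n_drift_osc, _os_drift, _x_drift)
from . import steady_state as ss

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "Ensemble",
    "simulate_cell",
    "simulate_population",
    "convergence_check",
    "derive_cell_seeds",
    "DEFAULT_DT",
]

#: per-scenario default step sizes (time units).  The fluctuation value
#: resolves the ~4e-3 t.u. Nanog-low sojourns (several dozen steps each);
#: the oscillation value resolves the ~86 t.u. limit cycle to ~0.1%.
DEFAULT_DT = {Scenario.FLUCTUATION: 5e-5, Scenario.OSCILLATION: 2e-3}

_CHUNK = 2048  # noise draws per generator call; fixed so streams reproduce


@dataclass
class SimulationConfig:
    """Integration settings shared by single-cell and ensemble runs."""

    dt: float
    t_end: float
    seed: int
    record_every: int = 1
    n_cells: int = 1
    initial_condition: Union[str, SystemState] = "high"
    clamp: str = "truncate"
    noise_coupling: str = "os"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_end < self.dt:
            raise ValueError("t_end must be >= dt")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.clamp not in ("truncate", "output"):
            raise ValueError("clamp must be 'truncate' or 'output'")
        if self.noise_coupling not in ("os", "constant"):
            raise ValueError("noise_coupling must be 'os' or 'constant'")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


@dataclass
class Trajectory:
    """Recorded time course of one cell.  Concentrations are >= 0."""

    times: np.ndarray
    os: np.ndarray
    n: np.ndarray
    x: Optional[np.ndarray]
    params: ScenarioParams
    seed: object

    @property
    def final_state(self) -> SystemState:
        x = None if self.x is None else float(self.x[-1])
        return SystemState(t=float(self.times[-1]), os=float(self.os[-1]),
                           n=float(self.n[-1]), x=x)

    def to_frame(self, cell_id: int = 0) -> pd.DataFrame:
        d = dict(t=self.times, os=self.os, n=self.n)
        d["x"] = self.x if self.x is not None else np.full_like(self.n,
                                                                np.nan)
        d["cell_id"] = cell_id
        return pd.DataFrame(d)


@dataclass
class Ensemble:
    """Snapshot matrices (cells x recorded times) of independent cells."""

    times: np.ndarray
    os: np.ndarray
    n: np.ndarray
    x: Optional[np.ndarray]
    params: ScenarioParams
    config: SimulationConfig

    def snapshot(self, index: int = -1) -> np.ndarray:
        """Nanog concentrations of all cells at one recorded time."""
        return self.n[:, index].copy()

    @property
    def n_cells(self) -> int:
        return self.n.shape[0]

    def trajectory(self, cell: int) -> Trajectory:
        return Trajectory(times=self.times, os=self.os[cell],
                          n=self.n[cell],
                          x=None if self.x is None else self.x[cell],
                          params=self.params, seed=(self.config.seed, cell))

    def to_frame(self) -> pd.DataFrame:
        frames = [self.trajectory(c).to_frame(cell_id=c)
                  for c in range(self.n_cells)]
        return pd.concat(frames, ignore_index=True)


def derive_cell_seeds(seed: int, n_cells: int):
    """Deterministic per-cell seed sequences spawned from the master seed."""
    return np.random.SeedSequence(seed).spawn(n_cells)


def _ic_rng(seed) -> np.random.Generator:
    """Generator for initial-condition sampling, independent of the noise
    streams."""
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed.spawn(1)[0])
    return np.random.default_rng(np.random.SeedSequence((int(seed), 0x1C)))


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

def _cycle_samples(p: ScenarioParams, os_level: float, n_points: int = 2048):
    """States uniformly spaced in time along the deterministic limit cycle."""
    cyc = ss.find_limit_cycle(p, os_level=os_level)
    if not cyc.found:
        raise ValueError("no limit cycle at these parameters; cannot draw "
                         "cycle-phase initial conditions")
    from scipy.integrate import solve_ivp
    rhs = lambda t, y: [_n_drift_osc(os_level, y[0], y[1], p),
                        _x_drift(y[0], y[1], p)]
    # converge onto the attractor, then sample one period densely
    warm = solve_ivp(rhs, (0.0, 20.0 * cyc.period), [1.0, 0.0],
                     method="LSODA", rtol=1e-9, atol=1e-10)
    y0 = warm.y[:, -1]
    t_eval = np.linspace(0.0, cyc.period, n_points, endpoint=False)
    sol = solve_ivp(rhs, (0.0, cyc.period), y0, method="LSODA",
                    rtol=1e-9, atol=1e-10, t_eval=t_eval)
    return sol.y[0], sol.y[1]


def _resolve_initial(p: ScenarioParams, cfg: SimulationConfig,
                     rng: np.random.Generator):
    """(os0, n0, x0) arrays of length n_cells for the configured rule."""
    nc = cfg.n_cells
    ic = cfg.initial_condition
    if isinstance(ic, SystemState):
        os0 = np.full(nc, float(ic.os))
        n0 = np.full(nc, float(ic.n))
        x0 = np.full(nc, 0.0 if ic.x is None else float(ic.x))
        return os0, n0, x0
    osl = ss.os_star(p)
    if ic == "high":
        if p.has_x:
            ncyc, xcyc = _cycle_samples(p, osl, n_points=512)
            i = int(np.argmax(ncyc))
            return (np.full(nc, osl), np.full(nc, ncyc[i]),
                    np.full(nc, xcyc[i]))
        fps = ss.nanog_fixed_points(p, osl)
        n_high = max(fp.n for fp in fps if fp.stability == "stable")
        return np.full(nc, osl), np.full(nc, n_high), np.zeros(nc)
    if ic == "low":
        if p.has_x:
            ncyc, xcyc = _cycle_samples(p, osl, n_points=512)
            i = int(np.argmin(ncyc))
            return (np.full(nc, osl), np.full(nc, ncyc[i]),
                    np.full(nc, xcyc[i]))
        fps = ss.nanog_fixed_points(p, osl)
        n_low = min(fp.n for fp in fps if fp.stability == "stable")
        return np.full(nc, osl), np.full(nc, n_low), np.zeros(nc)
    if ic == "cycle":
        if not p.has_x:
            raise ValueError("'cycle' initial condition requires the "
                             "oscillation scenario")
        ncyc, xcyc = _cycle_samples(p, osl)
        idx = rng.integers(0, len(ncyc), size=nc)
        return np.full(nc, osl), ncyc[idx].copy(), xcyc[idx].copy()
    raise ValueError(f"unknown initial condition rule {ic!r}")


def _noise_gain_ref(p: ScenarioParams, cfg: SimulationConfig) -> float:
    """Normalization of the OS-coupled noise gain (1 at the OS operating
    point)."""
    if cfg.noise_coupling == "constant":
        return 1.0
    href = float(hill(ss.os_star(p), p.k3, p.gamma_os))
    # degenerate parameter sets (no positive OS state) fall back to a
    # constant-amplitude noise term
    return href if href > 0.0 else 1.0


# ---------------------------------------------------------------------------
# integrators
# ---------------------------------------------------------------------------

def simulate_cell(p: ScenarioParams, cfg: SimulationConfig,
                  signal: Optional[SignalParams] = None,
                  gate_mode: str = "onset") -> Trajectory:
    """Integrate one cell; reproducible given ``cfg.seed``.

    ``signal`` applies the differentiation signal Y to the OS production
    term.  With ``gate_mode="onset"`` the Nanog level at the moment the
    signal window opens is latched and decides transmission for the whole
    window (the state the signal *hits*); ``"instantaneous"`` re-evaluates
    the gate at the current Nanog level every step.
    """
    if gate_mode not in ("onset", "instantaneous"):
        raise ValueError("gate_mode must be 'onset' or 'instantaneous'")
    rng = np.random.default_rng(cfg.seed)
    cfg1 = replace(cfg, n_cells=1)
    os0, n0, x0 = _resolve_initial(p, cfg1, _ic_rng(cfg.seed))
    os_, n, x = float(os0[0]), float(n0[0]), float(x0[0])

    dt = cfg.dt
    sqdt = math.sqrt(dt)
    n_steps = cfg.n_steps
    rec = cfg.record_every
    n_rec = n_steps // rec + 1
    t_out = np.empty(n_rec)
    os_out = np.empty(n_rec)
    n_out = np.empty(n_rec)
    x_out = np.empty(n_rec) if p.has_x else None

    state_clamp = cfg.clamp == "truncate"
    href = _noise_gain_ref(p, cfg)
    couple = cfg.noise_coupling == "os"
    # hoisted parameters; the loop body is pure scalar arithmetic because it
    # runs for 10^6-10^7 steps in the residence-time analyses
    s3, s4, k3, k4, d_n = p.s3, p.s4, p.k3, p.k4, p.d_n
    k1, k2, d_os = p.k1, p.k2, p.d_os
    g_os, g_n = p.gamma_os, p.gamma_n
    A = p.os_production_ceiling
    sigma = p.sigma
    has_x = p.has_x
    if has_x:
        s5, s6, k5, g_x, d_x = p.s5, p.s6, p.k5, p.gamma_x, p.d_x
    sig_on = signal is not None
    gate_level = None  # latched Nanog level; None until window opens
    if sig_on:
        t_on, t_off = signal.t_on, signal.t_off
        kg = signal.k_gate ** signal.gamma_gate
        g_gate, amp = signal.gamma_gate, signal.amplitude

    def record(j, t):
        t_out[j] = t
        os_out[j] = os_ if os_ > 0.0 else 0.0
        n_out[j] = n if n > 0.0 else 0.0
        if x_out is not None:
            x_out[j] = x if x > 0.0 else 0.0

    record(0, 0.0)
    j = 1
    noise = rng.standard_normal(min(_CHUNK, n_steps)).tolist()
    ni = 0
    for i in range(n_steps):
        if ni >= len(noise):
            noise = rng.standard_normal(min(_CHUNK, n_steps - i)).tolist()
            ni = 0
        # differentiation signal acting on OS production
        y = 0.0
        if sig_on:
            t = i * dt
            if t_on <= t < t_off:
                if gate_mode == "onset":
                    if gate_level is None:
                        gate_level = n if n > 0.0 else 0.0
                    ng = gate_level
                else:
                    ng = n if n > 0.0 else 0.0
                ngg = ng ** g_gate
                y = amp * (1.0 - ngg / (kg + ngg))
        # drifts (regulatory inputs vanish for negative latent states)
        osc_ = os_ if os_ > 0.0 else 0.0
        nc_ = n if n > 0.0 else 0.0
        og = osc_ ** g_os
        h_os3 = og / (k3 + og)
        d_os_dt = (A * (og / (k1 + og)) * (og / (k2 + og)) / (1.0 + y)
                   - d_os * os_)
        ng_pow = nc_ ** g_n
        if has_x:
            xc_ = x if x > 0.0 else 0.0
            dn = (s3 * h_os3 + s4 * ng_pow / (k4 + ng_pow + s6 * xc_ ** g_x)
                  - d_n * n)
            dx = s5 * ng_pow / (k5 + ng_pow) - d_x * x
            x = x + dt * dx
            if x < 0.0:
                x = 0.0
        else:
            dn = s3 * h_os3 + s4 * ng_pow / (k4 + ng_pow) - d_n * n
        gain = (h_os3 / href) if couple else 1.0
        n = n + dt * dn + sigma * gain * sqdt * noise[ni]
        ni += 1
        os_ = os_ + dt * d_os_dt
        if os_ < 0.0:
            os_ = 0.0
        if state_clamp and n < 0.0:
            n = 0.0
        if not (-1e12 < n < 1e12):
            raise FloatingPointError(
                f"state diverged at t={i*dt:.4g}; reduce dt (currently {dt})")
        if (i + 1) % rec == 0:
            record(j, (i + 1) * dt)
            j += 1
    return Trajectory(times=t_out[:j], os=os_out[:j], n=n_out[:j],
                      x=None if x_out is None else x_out[:j],
                      params=p, seed=cfg.seed)


def simulate_population(p: ScenarioParams, cfg: SimulationConfig,
                        initial_override: Optional[tuple] = None) -> Ensemble:
    """Integrate ``cfg.n_cells`` statistically independent cells (vectorized).

    Each cell has its own noise stream spawned from the master seed.
    ``initial_override`` may supply explicit ``(os0, n0, x0)`` arrays (used
    by the sorting experiments to continue a selected subpopulation).
    """
    seeds = derive_cell_seeds(cfg.seed, cfg.n_cells)
    rngs = [np.random.default_rng(s) for s in seeds]
    ic_rng = _ic_rng(cfg.seed)
    if initial_override is not None:
        os_, n, x = (np.array(a, dtype=float, copy=True)
                     for a in initial_override)
    else:
        os_, n, x = _resolve_initial(p, cfg, ic_rng)

    dt, sqdt = cfg.dt, math.sqrt(cfg.dt)
    n_steps, rec = cfg.n_steps, cfg.record_every
    nc = cfg.n_cells
    n_rec = n_steps // rec + 1
    times = np.empty(n_rec)
    os_out = np.empty((nc, n_rec))
    n_out = np.empty((nc, n_rec))
    x_out = np.empty((nc, n_rec)) if p.has_x else None
    state_clamp = cfg.clamp == "truncate"
    href = _noise_gain_ref(p, cfg)
    couple = cfg.noise_coupling == "os"
    sigma = p.sigma

    def record(j, t):
        times[j] = t
        np.maximum(os_, 0.0, out=os_out[:, j])
        np.maximum(n, 0.0, out=n_out[:, j])
        if x_out is not None:
            np.maximum(x, 0.0, out=x_out[:, j])

    record(0, 0.0)
    j = 1
    block = np.empty((nc, 0))
    bi = 0
    for i in range(n_steps):
        if bi >= block.shape[1]:
            width = min(_CHUNK, n_steps - i)
            block = np.empty((nc, width))
            for c in range(nc):
                block[c] = rngs[c].standard_normal(width)
            bi = 0
        osc_ = np.maximum(os_, 0.0)
        ncl = np.maximum(n, 0.0)
        h_os3 = hill(osc_, p.k3, p.gamma_os)
        if p.has_x:
            xcl = np.maximum(x, 0.0)
            dn = _n_drift_osc(osc_, n, xcl, p)
            dx = _x_drift(ncl, x, p)
        else:
            dn = _n_drift_core(osc_, n, p)
        gain = (h_os3 / href) if couple else 1.0
        n = n + dt * dn + sigma * gain * sqdt * block[:, bi]
        bi += 1
        os_ = os_ + dt * _os_drift(osc_, p)
        if p.has_x:
            x = np.maximum(x + dt * dx, 0.0)
        os_ = np.maximum(os_, 0.0)
        if state_clamp:
            n = np.maximum(n, 0.0)
        if (i + 1) % rec == 0:
            if not np.all(np.isfinite(n)):
                raise FloatingPointError(
                    f"state diverged by t={(i+1)*dt:.4g}; reduce dt")
            record(j, (i + 1) * dt)
            j += 1
    return Ensemble(times=times[:j], os=os_out[:, :j], n=n_out[:, :j],
                    x=None if x_out is None else x_out[:, :j],
                    params=p, config=cfg)


def convergence_check(p: ScenarioParams, cfg: SimulationConfig) -> dict:
    """Step-halving report for the deterministic (sigma = 0) integrator.

    Runs the forward-Euler limit at ``dt``, ``dt/2`` and a ``dt/100``
    reference, measures the terminal-state error against the reference and
    reports the observed convergence order (~1 for Euler).
    """
    p0 = p.with_(sigma=0.0)

    def final_n(dt):
        c = replace(cfg, dt=dt, record_every=max(1, int(round(
            cfg.t_end / dt / 4))))
        return simulate_cell(p0, c).n[-1]

    ref = final_n(cfg.dt / 100.0)
    e1 = abs(final_n(cfg.dt) - ref)
    e2 = abs(final_n(cfg.dt / 2.0) - ref)
    order = math.log2(e1 / e2) if e2 > 0 else math.nan
    return dict(dt=cfg.dt, error_dt=e1, error_half=e2,
                observed_order=order, reference_dt=cfg.dt / 100.0)
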