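"""In-silico experiment drivers.

End-to-end protocols built on the simulator and the observables:

* ``run_sort_and_reestablish`` -- FACS-style sorting of a stationary
  population into Nanog-low or Nanog-high cells and observation of how the
  bimodal distribution re-establishes.  Noise-driven bistable switching
  relaxes aperiodically; the limit-cycle mechanism behaves like a
  synchronized population and shows damped oscillations of the state
  fractions with a transient over-shoot into the opposing state.
* ``run_differentiation_challenge`` -- a transient differentiation signal Y
  applied when the cell is Nanog-low or Nanog-high.  High Nanog blocks the
  signal (gate-keeper); a signal hitting a Nanog-low cell collapses
  Oct4-Sox2 irreversibly.
* ``reproduce`` -- writes CSV/JSON result bundles for the standard analyses
  (bifurcation diagrams, population distributions, residence-time
  distributions, sorting and challenge protocols).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (ScenarioParams, Scenario, SignalParams,
                    preset, PRESETS)
from . import steady_state as ss
from .simulate import (SimulationConfig, Ensemble, Trajectory,
                       simulate_cell, simulate_population, DEFAULT_DT)
from .observables import (LOW, HIGH, StateThresholds, default_thresholds,
                          classify_states, fraction_low,
                          residence_statistics, population_histogram)

__all__ = [
    "SortExperimentResult",
    "ChallengeResult",
    "run_sort_and_reestablish",
    "run_differentiation_challenge",
    "default_signal_params",
    "stationary_ensemble",
    "preset",
    "reproduce",
]

MAINTAINED, DIFFERENTIATED = "MAINTAINED", "DIFFERENTIATED"


@dataclass
class SortExperimentResult:
    scenario: Scenario
    sorted_state: str
    times: np.ndarray
    fraction_low: np.ndarray
    equilibrium_fraction: float
    overshoot: bool
    overshoot_magnitude: float
    n_cells: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(t=self.times,
                                 fraction_low=self.fraction_low))


@dataclass
class ChallengeResult:
    scenario: Scenario
    trigger: str
    signal: SignalParams
    outcome: str
    final_os: float
    os_unstable: float
    t_signal_on: float
    n_at_signal: float
    post_collapse_transitions: int
    times: np.ndarray
    os: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(t=self.times, os=self.os, n=self.n))


# ---------------------------------------------------------------------------
# stationary populations
# ---------------------------------------------------------------------------

#: burn-in durations (time units) that pass the stationarity check
#: (snapshot distributions at t and 2t agree); see docs/methods.md
DEFAULT_BURNIN = {Scenario.FLUCTUATION: 5.0, Scenario.OSCILLATION: 30.0}


def stationary_ensemble(p: ScenarioParams, n_cells: int, seed: int,
                        dt: Optional[float] = None,
                        burnin: Optional[float] = None,
                        clamp: str = "truncate") -> Ensemble:
    """Ensemble relaxed to its stationary state.

    Fluctuation scenario: all cells start at the Nanog-high fixed point and
    burn in past the switching transient.  Oscillation scenario: cells start
    on the deterministic limit cycle at independent uniformly random phases
    (the stationary phase distribution) followed by a short noisy burn-in.
    """
    dt = DEFAULT_DT[p.scenario] if dt is None else dt
    burnin = DEFAULT_BURNIN[p.scenario] if burnin is None else burnin
    ic = "cycle" if p.has_x else "high"
    cfg = SimulationConfig(dt=dt, t_end=burnin, seed=seed,
                           record_every=max(1, int(round(burnin / dt))),
                           n_cells=n_cells, initial_condition=ic,
                           clamp=clamp)
    return simulate_population(p, cfg)


# ---------------------------------------------------------------------------
# sorting experiment
# ---------------------------------------------------------------------------

def run_sort_and_reestablish(p: ScenarioParams, cfg: SimulationConfig,
                             sorted_state: str,
                             thresholds: Optional[StateThresholds] = None,
                             burnin: Optional[float] = None,
                             ) -> SortExperimentResult:
    """Sort a stationary population and follow the state fractions in time.

    ``cfg`` configures the post-sort observation run (``cfg.n_cells`` is the
    pre-sort population size; the sorted subpopulation is whatever fraction
    falls on the selected side of the cut).  The over-shoot predicate is
    true when the opposing-state fraction exceeds its equilibrium value by
    more than two Monte-Carlo standard errors at two consecutive recorded
    times.
    """
    if sorted_state not in (LOW, HIGH):
        raise ValueError("sorted_state must be 'LOW' or 'HIGH'")
    th = thresholds if thresholds is not None else default_thresholds(p)
    base = stationary_ensemble(p, cfg.n_cells, seed=cfg.seed,
                               dt=cfg.dt, burnin=burnin, clamp=cfg.clamp)
    snap = base.snapshot(-1)
    eq_frac_low = fraction_low(snap, th)
    mask = snap < th.cut if sorted_state == LOW else snap >= th.cut
    m = int(mask.sum())
    if m == 0:
        raise ValueError(f"sorted {sorted_state} subpopulation is empty")
    os0 = base.os[mask, -1]
    n0 = base.n[mask, -1]
    x0 = base.x[mask, -1] if base.x is not None else np.zeros(m)
    follow = replace(cfg, n_cells=m, seed=cfg.seed + 1)
    ens = simulate_population(p, follow, initial_override=(os0, n0, x0))
    frac = np.mean(ens.n < th.cut, axis=0)
    if m == 1:
        # degenerate single-cell series: no equilibrium or overshoot claims
        return SortExperimentResult(p.scenario, sorted_state, ens.times,
                                    frac, math.nan, False, math.nan, 1)
    # over-shoot of the opposing state
    if sorted_state == LOW:
        opp = 1.0 - frac
        opp_eq = 1.0 - eq_frac_low
    else:
        opp = frac
        opp_eq = eq_frac_low
    se = math.sqrt(max(opp_eq * (1 - opp_eq), 1e-12) / m)
    exc = opp - opp_eq
    above = exc > 2.0 * se
    consecutive = bool(np.any(above[1:] & above[:-1]))
    return SortExperimentResult(
        scenario=p.scenario, sorted_state=sorted_state, times=ens.times,
        fraction_low=frac, equilibrium_fraction=eq_frac_low,
        overshoot=consecutive,
        overshoot_magnitude=float(max(exc.max(), 0.0)), n_cells=m)


# ---------------------------------------------------------------------------
# differentiation challenge
# ---------------------------------------------------------------------------

def default_signal_params(p: ScenarioParams,
                          duration: float = 10.0,
                          thresholds: Optional[StateThresholds] = None,
                          ) -> SignalParams:
    """Signal defaults calibrated from the deterministic OS sub-system.

    The amplitude is the smallest value on a coarse doubling grid that,
    unopposed by Nanog, removes the high OS fixed point, times a 4x margin
    so that the partially gated signal (the gate transmits only part of the
    amplitude at the latched Nanog level) still drives OS below its unstable
    point well within the window.  The gate half-blocking level is the
    unstable Nanog fixed point (between the low and high states).
    """
    th = thresholds if thresholds is not None else default_thresholds(p)
    amplitude = None
    for amp in (0.5, 1.0, 2.0, 4.0, 8.0, 16.0):
        # with production scaled by 1/(1+amp), does the high branch vanish?
        scaled = p.with_(u=p.u / (1.0 + amp))
        highs = [fp for fp in ss.os_fixed_points(scaled) if fp.os > 1e-6]
        if not highs:
            amplitude = 4.0 * amp
            break
    if amplitude is None:
        raise RuntimeError("no amplitude on the grid removes the high OS "
                           "state")
    return SignalParams(t_on=0.0, t_off=duration, amplitude=amplitude,
                        k_gate=th.cut, gamma_gate=2.0)


def run_differentiation_challenge(p: ScenarioParams, cfg: SimulationConfig,
                                  sig: Optional[SignalParams] = None,
                                  trigger: str = LOW,
                                  thresholds: Optional[
                                      StateThresholds] = None,
                                  gate_mode: str = "onset",
                                  recovery: float = 30.0,
                                  ) -> ChallengeResult:
    """Apply a transient differentiation signal when the cell enters
    ``trigger``.

    A scout run (same seed, no signal) locates the first entry into the
    trigger state; the signal window is then anchored there and the cell is
    re-simulated with the signal, for ``recovery`` extra time units beyond
    the window.  The outcome is DIFFERENTIATED when the final Oct4-Sox2
    level lies below the unstable OS fixed point, otherwise MAINTAINED;
    LOW->HIGH Nanog transitions after the OS collapse are counted.
    """
    if trigger not in (LOW, HIGH):
        raise ValueError("trigger must be 'LOW' or 'HIGH'")
    th = thresholds if thresholds is not None else default_thresholds(p)
    if sig is None:
        sig = default_signal_params(p, thresholds=th)
    duration = sig.t_off - sig.t_on
    scout = simulate_cell(p, cfg)
    states, _ = classify_states(scout, th)
    hits = np.flatnonzero(states == trigger)
    if hits.size == 0:
        raise RuntimeError(
            f"cell never entered the {trigger} state within t_end="
            f"{cfg.t_end}; extend the run")
    t_on = float(scout.times[hits[0]])
    sig_placed = SignalParams(t_on=t_on, t_off=t_on + duration,
                              amplitude=sig.amplitude, k_gate=sig.k_gate,
                              gamma_gate=sig.gamma_gate)
    total = t_on + duration + recovery
    cfg_full = replace(cfg, t_end=total)
    traj = simulate_cell(p, cfg_full, signal=sig_placed, gate_mode=gate_mode)
    os_u = [fp.os for fp in ss.os_fixed_points(p)
            if fp.stability == "unstable"]
    os_unstable = os_u[0] if os_u else 0.0
    final_os = float(traj.os[-1])
    outcome = DIFFERENTIATED if final_os < os_unstable else MAINTAINED
    post = 0
    if outcome == DIFFERENTIATED:
        below = np.flatnonzero(traj.os < os_unstable)
        tail = traj.times >= traj.times[below[0]]
        sub = Trajectory(times=traj.times[tail], os=traj.os[tail],
                         n=traj.n[tail],
                         x=None if traj.x is None else traj.x[tail],
                         params=traj.params, seed=traj.seed)
        _, recs = classify_states(sub, th)
        post = sum(1 for r in recs if r.state == LOW and not r.censored)
    idx_n = int(np.searchsorted(traj.times, t_on))
    return ChallengeResult(
        scenario=p.scenario, trigger=trigger, signal=sig_placed,
        outcome=outcome, final_os=final_os, os_unstable=os_unstable,
        t_signal_on=t_on, n_at_signal=float(traj.n[max(idx_n - 1, 0)]),
        post_collapse_transitions=post,
        times=traj.times, os=traj.os, n=traj.n)


# ---------------------------------------------------------------------------
# figure-analysis bundles
# ---------------------------------------------------------------------------

def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float))


def reproduce(figure_id: str, out_dir, seed: int = 0,
              cells: Optional[int] = None,
              residence_sojourns: int = 300) -> dict:
    """Re-run one of the standard analyses and write its CSV/JSON bundle.

    ``fig2``: fluctuation bifurcation diagram (s4), example trajectory,
    stationary population histogram.  ``fig3``: the same for the
    oscillation scenario (s6 scan) plus the Nanog/X phase portrait with and
    without noise.  ``fig4``: sorting experiments (both scenarios, LOW and
    HIGH sorts).  ``fig5``: residence-time distributions for both
    scenarios.  ``fig6``: differentiation challenges (both scenarios,
    LOW and HIGH triggers).

    Deterministic given ``seed``; re-running overwrites identical files.
    Returns a manifest mapping written file names to short descriptions.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    if figure_id == "fig2":
        p = preset("fluctuation")
        grid = np.linspace(0.0, 30.0, 61)
        branch = ss.scan_bifurcation(p, "s4", grid)
        branch.to_frame().to_csv(out / "fig2_bifurcation.csv", index=False)
        manifest["fig2_bifurcation.csv"] = "Nanog fixed points vs s4"
        cfg = SimulationConfig(dt=DEFAULT_DT[p.scenario], t_end=2.0,
                               seed=seed, record_every=10)
        simulate_cell(p, cfg).to_frame().to_csv(
            out / "fig2_trajectory.csv", index=False)
        manifest["fig2_trajectory.csv"] = "single-cell time course"
        nc = 2000 if cells is None else cells
        snap = stationary_ensemble(p, nc, seed=seed).snapshot(-1)
        hist = population_histogram(snap)
        pd.DataFrame(dict(grid_log10=hist.density_grid,
                          density=hist.density)).to_csv(
            out / "fig2_density.csv", index=False)
        th = default_thresholds(p)
        _write_json(out / "fig2_summary.json", dict(
            n_cells=nc, fraction_low=fraction_low(snap, th),
            bimodal=hist.bimodal, n_modes=hist.n_modes,
            bistable_window=branch.bistable_window))
        manifest["fig2_density.csv"] = "population density estimate"
        manifest["fig2_summary.json"] = "fractions and window"
    elif figure_id == "fig3":
        p = preset("oscillation")
        grid = np.linspace(0.0, 10.0, 26)
        branch = ss.scan_bifurcation(p, "s6", grid, measure_cycles=False)
        branch.to_frame().to_csv(out / "fig3_bifurcation.csv", index=False)
        manifest["fig3_bifurcation.csv"] = "Nanog/X fixed points vs s6"
        cyc = ss.find_limit_cycle(p)
        cfg = SimulationConfig(dt=DEFAULT_DT[p.scenario],
                               t_end=3.0 * cyc.period, seed=seed,
                               record_every=25, initial_condition="cycle",
                               n_cells=1)
        traj = simulate_cell(p, cfg)
        traj.to_frame().to_csv(out / "fig3_trajectory.csv", index=False)
        det = simulate_cell(p.with_(sigma=0.0), cfg)
        pd.DataFrame(dict(t=det.times, n_det=det.n, x_det=det.x,
                          n_noisy=traj.n, x_noisy=traj.x)).to_csv(
            out / "fig3_phase_portrait.csv", index=False)
        nc = 2000 if cells is None else cells
        snap = stationary_ensemble(p, nc, seed=seed).snapshot(-1)
        hist = population_histogram(snap)
        pd.DataFrame(dict(grid_log10=hist.density_grid,
                          density=hist.density)).to_csv(
            out / "fig3_density.csv", index=False)
        th = default_thresholds(p)
        _write_json(out / "fig3_summary.json", dict(
            n_cells=nc, fraction_low=fraction_low(snap, th),
            bimodal=hist.bimodal, period=cyc.period,
            n_min=cyc.n_min, n_max=cyc.n_max,
            oscillatory_window=branch.oscillatory_window))
        manifest.update({k: "oscillation-scenario output" for k in
                         ("fig3_trajectory.csv", "fig3_phase_portrait.csv",
                          "fig3_density.csv", "fig3_summary.json")})
    elif figure_id == "fig4":
        for name in PRESETS:
            p = preset(name)
            nc = (1000 if cells is None else cells)
            horizon = (0.5 if p.scenario is Scenario.FLUCTUATION
                       else 4.0 * ss.find_limit_cycle(p).period)
            cfg = SimulationConfig(
                dt=DEFAULT_DT[p.scenario], t_end=horizon, seed=seed,
                record_every=max(1, int(horizon / DEFAULT_DT[p.scenario]
                                        / 60)), n_cells=nc)
            for state in (LOW, HIGH):
                res = run_sort_and_reestablish(p, cfg, state)
                fname = f"fig4_{name}_sorted_{state.lower()}.csv"
                res.to_frame().to_csv(out / fname, index=False)
                manifest[fname] = (
                    f"fraction_low after sorting {state}; overshoot="
                    f"{res.overshoot}")
    elif figure_id == "fig5":
        for name in PRESETS:
            p = preset(name)
            stats = residence_analysis(p, seed=seed,
                                       min_sojourns=residence_sojourns)
            rows = []
            for state, st in stats.items():
                mids = 0.5 * (st["hist_edges"][1:] + st["hist_edges"][:-1])
                for mid, cnt in zip(mids, st["hist_counts"]):
                    rows.append(dict(state=state, duration_mid=mid,
                                     count=int(cnt)))
            pd.DataFrame(rows).to_csv(out / f"fig5_{name}_residence.csv",
                                      index=False)
            _write_json(out / f"fig5_{name}_summary.json",
                        {s: {k: v for k, v in st.items()
                             if not k.startswith("hist")}
                         for s, st in stats.items()})
            manifest[f"fig5_{name}_residence.csv"] = "residence histograms"
    elif figure_id == "fig6":
        for name in PRESETS:
            p = preset(name)
            horizon = (3.0 if p.scenario is Scenario.FLUCTUATION
                       else 2.5 * ss.find_limit_cycle(p).period)
            cfg = SimulationConfig(dt=DEFAULT_DT[p.scenario], t_end=horizon,
                                   seed=seed, record_every=20)
            for trig in (LOW, HIGH):
                res = run_differentiation_challenge(p, cfg, trigger=trig)
                fname = f"fig6_{name}_trigger_{trig.lower()}.csv"
                res.to_frame().to_csv(out / fname, index=False)
                manifest[fname] = f"outcome={res.outcome}"
    else:
        raise ValueError(
            f"unknown figure id {figure_id!r}; valid: fig2..fig6")
    _write_json(out / f"{figure_id}_manifest.json", manifest)
    return manifest


def residence_analysis(p: ScenarioParams, seed: int = 0,
                       min_sojourns: int = 300,
                       dt: Optional[float] = None,
                       thresholds: Optional[StateThresholds] = None) -> dict:
    """Long single-cell run collecting at least ``min_sojourns`` uncensored
    LOW sojourns; returns :func:`residence_statistics` output.

    The run length is predicted from the scenario's characteristic switching
    time (mean LOW sojourn ~ one normalized time unit) with a 40% margin,
    and extended once if the target count is missed.
    """
    th = thresholds if thresholds is not None else default_thresholds(p)
    dt = DEFAULT_DT[p.scenario] if dt is None else dt
    if p.scenario is Scenario.FLUCTUATION:
        # LOW sojourns take ~1/f t.u. and recur every ~90/f t.u.
        t_end = 1.4 * min_sojourns * 90.0 / p.f
    else:
        t_end = 1.4 * min_sojourns * 5.5 * p.f  # one LOW sojourn per period
    ic = "cycle" if p.has_x else "high"
    for attempt in range(2):
        cfg = SimulationConfig(dt=dt, t_end=t_end, seed=seed,
                               initial_condition=ic)
        traj = simulate_cell(p, cfg)
        _, records = classify_states(traj, th)
        n_low = sum(1 for r in records if r.state == LOW and not r.censored)
        if n_low >= min_sojourns:
            break
        t_end *= 1.0 + 1.2 * (min_sojourns / max(n_low, 1))
    return residence_statistics(records, p=p)
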