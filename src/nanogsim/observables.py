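"""Summary statistics of Nanog trajectories and population snapshots.

Implements the read-outs used throughout the analysis: hysteresis-based
LOW/HIGH state classification of single-cell traces, residence-time records
and their distribution shape (exponential-like under noise-driven switching,
narrowly peaked under limit-cycle oscillation), the Nanog-low fraction of a
population snapshot, and histogram/density estimates of population
distributions (kernel density on log concentrations, flow-cytometry style).

Residence times are also reported on the normalized time scale tau, in which
the mean Nanog-low sojourn is one unit (see ``ScenarioParams.tau``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .model import ScenarioParams
from . import steady_state as ss
from .simulate import Trajectory

__all__ = [
    "StateThresholds",
    "ResidenceRecord",
    "PopulationHistogram",
    "default_thresholds",
    "classify_states",
    "fraction_low",
    "residence_statistics",
    "population_histogram",
]

LOW, HIGH = "LOW", "HIGH"


@dataclass(frozen=True)
class StateThresholds:
    """Hysteresis band for LOW/HIGH classification.

    A LOW cell becomes HIGH only above ``low_exit``; a HIGH cell becomes LOW
    only below ``high_exit`` (``high_exit <= low_exit``).  Snapshots, where
    no history is available, are classified by the single ``cut`` — the
    geometric midpoint of the band, which by construction of
    :func:`default_thresholds` is the unstable Nanog fixed point (the
    natural separatrix between the basins).
    """

    low_exit: float
    high_exit: float

    def __post_init__(self):
        if not (0 <= self.high_exit <= self.low_exit):
            raise ValueError("require 0 <= high_exit <= low_exit")

    @property
    def cut(self) -> float:
        return math.sqrt(self.low_exit * self.high_exit)


@dataclass(frozen=True)
class ResidenceRecord:
    """One contiguous sojourn in the LOW or HIGH state."""

    state: str
    t_enter: float
    t_exit: float
    censored: bool

    @property
    def duration(self) -> float:
        return self.t_exit - self.t_enter

    def duration_normalized(self, p: ScenarioParams) -> float:
        return float(p.tau(self.duration))


@dataclass
class PopulationHistogram:
    """Histogram plus smooth density estimate of a Nanog snapshot."""

    counts: np.ndarray
    edges: np.ndarray
    density_grid: np.ndarray          # log10(concentration + offset) grid
    density: np.ndarray               # integrates to 1 over the grid
    n_modes: int

    @property
    def bimodal(self) -> bool:
        return self.n_modes >= 2


def default_thresholds(p: ScenarioParams, band: float = 1.25,
                       ) -> StateThresholds:
    """Hysteresis band placed log-symmetrically around the unstable
    Nanog fixed point.

    The unstable fixed point of the Nanog(/X) sub-system at the operating
    Oct4-Sox2 level separates the two attractor basins; ``band`` widens the
    classification band by +/-25% (in log concentration) so that noise does
    not chatter the classifier at the separatrix.
    """
    osl = ss.os_star(p)
    if p.has_x:
        fps = ss.nanog_x_fixed_points(p, osl)
        unstable = [fp.n for fp in fps if fp.stability != "stable"]
    else:
        fps = ss.nanog_fixed_points(p, osl)
        unstable = [fp.n for fp in fps if fp.stability == "unstable"]
    if not unstable:
        raise ValueError("no unstable Nanog fixed point at these "
                         "parameters; thresholds must be given explicitly")
    n_u = unstable[0] if len(unstable) == 1 else sorted(unstable)[len(
        unstable) // 2]
    return StateThresholds(low_exit=n_u * band, high_exit=n_u / band)


def classify_states(traj: Trajectory, th: StateThresholds):
    """Assign LOW/HIGH to every sample and extract residence records.

    The classifier is hysteretic: state changes occur only when the trace
    leaves the band.  The first and the last sojourn are flagged censored
    (their true duration is truncated by the observation window).

    Returns ``(states, records)`` where ``states`` is an array of "LOW" /
    "HIGH" per recorded sample.
    """
    n = np.asarray(traj.n, dtype=float)
    t = np.asarray(traj.times, dtype=float)
    if len(n) < 2:
        raise ValueError("trajectory must contain at least 2 samples")
    states = np.empty(len(n), dtype=object)
    # initial state from the single cut
    state = HIGH if n[0] >= th.cut else LOW
    records: List[ResidenceRecord] = []
    t_enter = t[0]
    for i in range(len(n)):
        if state == HIGH and n[i] < th.high_exit:
            records.append(ResidenceRecord(HIGH, t_enter, t[i],
                                           censored=False))
            state, t_enter = LOW, t[i]
        elif state == LOW and n[i] > th.low_exit:
            records.append(ResidenceRecord(LOW, t_enter, t[i],
                                           censored=False))
            state, t_enter = HIGH, t[i]
        states[i] = state
    records.append(ResidenceRecord(state, t_enter, t[-1], censored=True))
    if records:
        first = records[0]
        records[0] = ResidenceRecord(first.state, first.t_enter,
                                     first.t_exit, censored=True)
    return states, records


def fraction_low(snapshot: Sequence[float], th: StateThresholds) -> float:
    """Fraction of cells below the snapshot cut (Nanog-low cells)."""
    snap = np.asarray(snapshot, dtype=float)
    if snap.size == 0:
        raise ValueError("empty snapshot")
    return float(np.mean(snap < th.cut))


def residence_statistics(records: Sequence[ResidenceRecord],
                         p: Optional[ScenarioParams] = None,
                         bins: int = 30) -> dict:
    """Per-state summary of uncensored sojourns.

    Returns ``{state: {n, mean_raw, mean_tau, cv, censored_n, hist_counts,
    hist_edges}}``.  Censored sojourns are excluded from the moments (not
    imputed) and reported as counts.  ``mean_tau`` requires ``p``.
    """
    out = {}
    for state in (LOW, HIGH):
        durs = np.array([r.duration for r in records
                         if r.state == state and not r.censored])
        n_cens = sum(1 for r in records if r.state == state and r.censored)
        if len(durs) == 0:
            if n_cens > 0:
                raise ValueError(
                    f"all {state} sojourns are censored; extend the run")
            continue
        mean = float(durs.mean())
        # population (ddof=0) coefficient of variation
        cv = float(durs.std() / mean) if len(durs) > 1 else math.nan
        counts, edges = np.histogram(durs, bins=bins)
        out[state] = dict(
            n=int(len(durs)), mean_raw=mean,
            mean_tau=float(p.tau(mean)) if p is not None else math.nan,
            cv=cv, censored_n=int(n_cens),
            hist_counts=counts, hist_edges=edges)
    return out


def population_histogram(snapshot: Sequence[float], bins: int = 50,
                         log_offset: float = 0.01) -> PopulationHistogram:
    """Histogram and log-scale kernel density estimate of a Nanog snapshot.

    Because Nanog levels span two orders of magnitude the density is
    estimated on ``log10(n + log_offset)`` with a Gaussian kernel and
    Silverman bandwidth; modes are counted as local maxima of the density on
    a fine grid.  A point-mass snapshot short-circuits to a single-bin
    histogram.
    """
    snap = np.asarray(snapshot, dtype=float)
    if snap.size == 0:
        raise ValueError("empty snapshot")
    if np.ptp(snap) == 0.0:
        v = snap[0]
        counts, edges = np.histogram(snap, bins=1)
        grid = np.array([math.log10(v + log_offset)])
        return PopulationHistogram(counts=counts, edges=edges,
                                   density_grid=grid,
                                   density=np.array([1.0]), n_modes=1)
    counts, edges = np.histogram(snap, bins=bins)
    logv = np.log10(snap + log_offset)
    kde = gaussian_kde(logv)      # Silverman-like rule (scott ~ silverman)
    lo, hi = logv.min(), logv.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, 512)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    # ignore maxima below 1% of the peak (numerical ripples)
    n_modes = int(np.sum(interior & (dens[1:-1] > 0.01 * dens.max())))
    return PopulationHistogram(counts=counts, edges=edges,
                               density_grid=grid, density=dens,
                               n_modes=max(n_modes, 1))
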