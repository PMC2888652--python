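"""Core reaction-kinetic model of the Oct4-Sox2/Nanog pluripotency network.

The network collapses Oct4 and Sox2 into a single auto-regulating
heterodimer species [OS] that activates Nanog transcription; Nanog
additionally activates itself via its dimer.  Two scenario variants explain
the experimentally observed Nanog heterogeneity:

* ``fluctuation`` -- the core two-species system is bistable in Nanog and a
  Gaussian white-noise term on the Nanog equation drives transitions between
  the Nanog-low and Nanog-high states.
* ``oscillation`` -- a transcriptional repressor X, activated by Nanog and
  competing for Nanog promoter sites, closes a negative feedback loop that
  turns the Nanog-high state into a limit cycle.

All regulatory inputs are Hill functions ``H(c; k, g) = c**g / (k + c**g)``
where ``k`` is an *apparent* dissociation constant carrying units of
molecules**g (so ``k4 = 10`` with ``g = 2`` means half-maximal activation at
sqrt(10) ~ 3.16 molecules).  The alternative convention with ``k**g`` in the
denominator is *not* used; it would destroy bistability at the default
fluctuation parameters.

The Hill exponent always belongs to the species exerting the regulation:
``gamma_os`` for Oct4-Sox2 acting on promoters, ``gamma_n`` for Nanog
(auto-regulation and activation of X), ``gamma_x`` for X repressing Nanog.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

__all__ = [
    "Scenario",
    "ScenarioParams",
    "SystemState",
    "SignalParams",
    "hill",
    "core_rhs",
    "oscillation_rhs",
    "signal_rhs",
    "preset",
    "PRESETS",
]


class Scenario(str, enum.Enum):
    """Which mechanism generates Nanog heterogeneity."""

    FLUCTUATION = "fluctuation"
    OSCILLATION = "oscillation"


def hill(c, k, gamma):
    """Saturating transcriptional response ``c**gamma / (k + c**gamma)``.

    ``k`` is an apparent dissociation constant in units molecules**gamma.
    Concentrations are physical quantities; negative inputs (which can occur
    transiently in the latent state of the free-running stochastic
    integrator) are clipped to zero, so the response vanishes there.
    """
    c = np.maximum(c, 0.0)
    cg = c ** gamma
    return cg / (k + cg)


@dataclass(frozen=True)
class ScenarioParams:
    """Complete rate/constant set for one scenario (symbols as in the field).

    Units: ``u`` 1/(molecules*time); ``s1..s6`` molecules/time (``s6`` is a
    dimensionless repression weight); ``k1..k5`` molecules**gamma; ``d_*``
    1/time; ``sigma`` noise amplitude of the Nanog stochastic term
    (molecules/sqrt(time)); ``f`` dimensionless time-normalization factor.
    X-specific entries (``s5, s6, k5, gamma_x, d_x``) are ``None`` in the
    fluctuation scenario.
    """

    u: float
    s1: float
    s2: float
    s3: float
    s4: float
    k1: float
    k2: float
    k3: float
    k4: float
    gamma_os: float
    gamma_n: float
    d_o: float
    d_s: float
    d_os: float
    d_n: float
    sigma: float
    f: float
    scenario: Scenario
    s5: Optional[float] = None
    s6: Optional[float] = None
    k5: Optional[float] = None
    gamma_x: Optional[float] = None
    d_x: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "scenario", Scenario(self.scenario))
        rates = dict(u=self.u, s1=self.s1, s2=self.s2, s3=self.s3,
                     s4=self.s4, k1=self.k1, k2=self.k2, k3=self.k3,
                     k4=self.k4, d_o=self.d_o, d_s=self.d_s, d_os=self.d_os,
                     d_n=self.d_n, sigma=self.sigma, f=self.f)
        for name, v in rates.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.gamma_os < 1 or self.gamma_n < 1:
            raise ValueError("Hill coefficients must be >= 1")
        if self.scenario is Scenario.OSCILLATION:
            missing = [n for n in ("s5", "s6", "k5", "gamma_x", "d_x")
                       if getattr(self, n) is None]
            if missing:
                raise ValueError(
                    "oscillation scenario requires X parameters; missing: "
                    + ", ".join(missing))
            if self.s5 < 0 or self.s6 < 0 or self.k5 < 0 or self.d_x < 0:
                raise ValueError("X rates/constants must be >= 0")
            if self.gamma_x < 1:
                raise ValueError("gamma_x must be >= 1")

    @property
    def has_x(self) -> bool:
        return self.scenario is Scenario.OSCILLATION

    @property
    def os_production_ceiling(self) -> float:
        """Upper bound of the OS production term, u*s1*s2/(d_o*d_s)."""
        return self.u * (self.s1 / self.d_o) * (self.s2 / self.d_s)

    def tau(self, t):
        """Map raw model time to the normalized time scale.

        The factor ``f`` rescales each scenario's clock so that the mean
        Nanog-low residence time equals one normalized unit.  The fluctuation
        scenario's intrinsic clock is fast (mean low sojourn ~ 1/270 time
        units), so its times are stretched, ``tau = f*t``; the oscillation
        scenario's clock is slow (mean low sojourn ~ f time units, set by the
        limit-cycle period), so its times are compressed, ``tau = t/f``.
        """
        t = np.asarray(t, dtype=float)
        if self.scenario is Scenario.FLUCTUATION:
            return self.f * t
        return t / self.f

    def with_(self, **changes) -> "ScenarioParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = {}
        for fl in fields(self):
            v = getattr(self, fl.name)
            if isinstance(v, Scenario):
                v = v.value
            d[fl.name] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioParams":
        return cls(**d)


@dataclass
class SystemState:
    """Instantaneous concentrations (molecules) plus time."""

    t: float
    os: float
    n: float
    x: Optional[float] = None

    def __post_init__(self):
        for name in ("os", "n"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative concentration {name}")
        if self.x is not None and self.x < 0:
            raise ValueError("negative concentration x")


@dataclass(frozen=True)
class SignalParams:
    """Transient differentiation signal Y, gated by Nanog.

    Y inhibits OS production multiplicatively by ``1/(1 + y_eff)``, where
    ``y_eff`` equals ``amplitude`` times a decreasing Hill function of Nanog
    (half-blocked at ``k_gate`` molecules, steepness ``gamma_gate``) inside
    the window ``[t_on, t_off)``, and is zero outside.  High Nanog blocks
    the signal (double-negative feedback, the gate-keeper).
    """

    t_on: float
    t_off: float
    amplitude: float
    k_gate: float
    gamma_gate: float = 2.0

    def __post_init__(self):
        if not (self.t_off > self.t_on >= 0):
            raise ValueError("require t_off > t_on >= 0")
        if self.amplitude < 0 or self.k_gate < 0:
            raise ValueError("amplitude and k_gate must be >= 0")

    def y_eff(self, t, n_gate_level):
        """Effective transmitted signal at time ``t``.

        ``n_gate_level`` is the Nanog concentration the gate responds to.
        Experiment drivers latch it to the Nanog level at signal onset (the
        state the signal *hits* decides transmission); passing the
        instantaneous level gives a continuously responding gate.
        """
        inside = (self.t_on <= t) & (t < self.t_off)
        # k_gate is the literal half-blocking concentration, so the apparent
        # constant handed to hill() is k_gate**gamma_gate.
        block = hill(n_gate_level, self.k_gate ** self.gamma_gate,
                     self.gamma_gate)
        return self.amplitude * np.where(inside, 1.0, 0.0) * (1.0 - block)


# ---------------------------------------------------------------------------
# Deterministic right-hand sides
# ---------------------------------------------------------------------------

def _os_drift(os, p: ScenarioParams, y_eff=0.0):
    """d[OS]/dt; the OS sub-system is autonomous (independent of n, x)."""
    prod = (p.u * (p.s1 / p.d_o) * (p.s2 / p.d_s)
            * hill(os, p.k1, p.gamma_os) * hill(os, p.k2, p.gamma_os))
    return prod / (1.0 + y_eff) - p.d_os * os


def _n_drift_core(os, n, p: ScenarioParams):
    return (p.s3 * hill(os, p.k3, p.gamma_os)
            + p.s4 * hill(n, p.k4, p.gamma_n)
            - p.d_n * n)


def _n_drift_osc(os, n, x, p: ScenarioParams):
    n_ = np.maximum(n, 0.0)
    x_ = np.maximum(x, 0.0)
    ng = n_ ** p.gamma_n
    return (p.s3 * hill(os, p.k3, p.gamma_os)
            + p.s4 * ng / (p.k4 + ng + p.s6 * x_ ** p.gamma_x)
            - p.d_n * n)


def _x_drift(n, x, p: ScenarioParams):
    # Nanog is the acting species here, hence its Hill exponent gamma_n.
    return p.s5 * hill(n, p.k5, p.gamma_n) - p.d_x * x


def core_rhs(state: SystemState, p: ScenarioParams) -> np.ndarray:
    """(d[OS]/dt, d[N]/dt) of the two-species core network."""
    return np.array([_os_drift(state.os, p),
                     _n_drift_core(state.os, state.n, p)])


def oscillation_rhs(state: SystemState, p: ScenarioParams) -> np.ndarray:
    """(d[OS]/dt, d[N]/dt, d[X]/dt) of the repressor-extended network.

    At x = 0 the Nanog equation reduces exactly to the core form.  The
    repressor occupies Nanog promoter binding sites, entering the
    auto-regulation denominator competitively with weight ``s6``.
    """
    if not p.has_x:
        raise ValueError("oscillation_rhs requires scenario='oscillation' "
                         "with all X parameters present")
    x = state.x if state.x is not None else 0.0
    return np.array([
        _os_drift(state.os, p),
        _n_drift_osc(state.os, state.n, x, p),
        _x_drift(state.n, x, p),
    ])


def signal_rhs(state: SystemState, p: ScenarioParams, sig: SignalParams,
               n_gate_level: Optional[float] = None) -> np.ndarray:
    """Scenario RHS with the differentiation signal Y acting on OS production.

    ``n_gate_level`` overrides the Nanog level seen by the gate (used by
    experiment drivers to latch the gate at signal onset); by default the
    instantaneous ``state.n`` is used.
    """
    ng = state.n if n_gate_level is None else n_gate_level
    y = sig.y_eff(state.t, ng)
    if p.has_x:
        x = state.x if state.x is not None else 0.0
        return np.array([
            _os_drift(state.os, p, y_eff=y),
            _n_drift_osc(state.os, state.n, x, p),
            _x_drift(state.n, x, p),
        ])
    return np.array([
        _os_drift(state.os, p, y_eff=y),
        _n_drift_core(state.os, state.n, p),
    ])


# ---------------------------------------------------------------------------
# Default parameter sets
# ---------------------------------------------------------------------------

_SHARED = dict(u=0.03, s1=50.0, s2=50.0, s3=0.1,
               k1=10.0, k2=10.0, k3=10.0,
               gamma_os=1.0, gamma_n=2.0,
               d_o=1.0, d_s=1.0, d_os=1.0, d_n=1.0)

PRESETS = {
    "fluctuation": ScenarioParams(
        scenario=Scenario.FLUCTUATION, s4=14.0, k4=10.0,
        sigma=12.0, f=270.0, **_SHARED),
    "oscillation": ScenarioParams(
        scenario=Scenario.OSCILLATION, s4=30.0, k4=2.0,
        s5=10.08, s6=4.74, k5=10.0, gamma_x=1.0, d_x=0.2,
        sigma=0.3, f=16.0, **_SHARED),
}


def preset(name: str) -> ScenarioParams:
    """Return the built-in default parameter set for a scenario by name."""
    try:
        return PRESETS[str(name)]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid names: {sorted(PRESETS)}"
        ) from None
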