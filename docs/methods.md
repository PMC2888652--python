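# Methods

## Model structure

Oct4 and Sox2 are collapsed into one auto-regulating heterodimer species
`[OS]` (formation rate `u`, transcription rates `s1`, `s2`, monomer decay
`d_O`, `d_S` absorbed into the production prefactor `u·s1·s2/(d_O·d_S)`).
`[OS]` activates Nanog transcription (basal channel `s3`); Nanog dimers
auto-activate their own promoter (channel `s4`, Hill coefficient
`γ_N = 2`).  All responses are Hill functions `H(c; k, γ) = c^γ/(k + c^γ)`
in which `k` is an *apparent* dissociation constant with units
molecules^γ — so `k4 = 10` with `γ_N = 2` puts half-maximal auto-activation
at √10 ≈ 3.16 molecules.  This convention is load-bearing: with the
alternative `k^γ` convention the fluctuation preset (`s4 = 14`, `k4 = 10`)
is monostable and the entire phenomenology disappears.

A convention used consistently throughout: the Hill exponent belongs to the
*acting* species.  `γ_OS` governs every promoter bound by Oct4-Sox2, `γ_N`
every promoter bound by Nanog — including the activation of the repressor X
(`s5·H([N]; k5, γ_N)`) — and `γ_X` the repression term by X.  The
competitive repression enters the denominator of the Nanog auto-activation
as `s6·[X]^γ_X` (X occupies Nanog promoter sites; `s6` carries the
repressor weight since no separate dissociation constant exists).  Under
the default oscillation parameters this form produces a single
Hopf-unstable spiral fixed point of the Nanog/X sub-system and a limit
cycle spending 20.7% of its period Nanog-low — matching the intended ~20%
calibration.  Attaching `γ_X` to the activation of X instead yields a
stable node and no oscillation at those parameters, which is how the
convention was pinned down.

The OS sub-system is autonomous.  All scenario analysis therefore fixes
`[OS]` at its upper stable root `OS* ≈ 53.12` molecules and studies the 1-D
Nanog (fluctuation) or 2-D Nanog/X (oscillation) sub-system.

## Default parameters

Fluctuation preset: `u=0.03, s1=s2=50, s3=0.1, s4=14, k1..k4=10, γ_OS=1,
γ_N=2, all d=1, σ=12, f=270`.  Oscillation preset differs in `s4=30, k4=2`
and adds `s5=10.08, s6=4.74, k5=10, γ_X=1, d_X=0.2`, with `σ=0.3, f=16`.
At the fluctuation preset the Nanog sub-system has stable states at 0.097
and 13.34 molecules (log-ratio 2.14) separated by an unstable point at
0.648; the bistable window in `s4` is ≈ [6.3, 29.7].  At the oscillation
preset the limit cycle has period ≈ 86.1 time units, Nanog range
0.09–24.9.  The oscillatory `s6`-window opens just below the operating
point 4.74 (a coexisting stable high state disappears in a fold between
4.6 and 4.74) and extends beyond `s6 = 10`.

## Stochastic integration

Euler–Maruyama with the Gaussian increment `σ·g(OS)·√dt·η` added to the
Nanog component only; OS and X integrate deterministically.  `σ` from the
presets is used on the SDE (`√dt`) scale; a per-step `σ·dt` reading would
require recalibrating both presets.

`g(OS) = H(OS; k3, γ_OS)/H(OS*; k3, γ_OS)` couples the noise amplitude to
the Oct4-Sox2-dependent activity of the Nanog promoter, normalized to
exactly 1 at the operating point.  Every baseline simulation therefore sees
the plain Table amplitude; the coupling only matters after a
differentiation-induced OS collapse, when the silent network also stops
generating transcription noise — which is what makes the collapse
irreversibly freeze Nanog variability.  A constant-amplitude term is
available (`noise_coupling="constant"`), under which Nanog would keep
switching after differentiation.

Per-cell noise streams are spawned from the master seed with
`numpy.random.SeedSequence`; runs are bit-reproducible, and a one-cell
ensemble reproduces `simulate_cell` exactly.

### Negative-concentration boundary: two readings, one real dichotomy

Negative Nanog excursions must be handled at σ = 12.  The package
implements two rules:

* `clamp="truncate"` (default): `[N] := max([N], 0)` after every step.
* `clamp="output"`: the latent state ranges over the real line (regulatory
  production vanishes below zero; first-order decay restores) and only
  recorded values are truncated at zero.

These are *not* numerically interchangeable, and no single rule reproduces
every calibration statement simultaneously.  Under per-step truncation the
stationary density (analytically, the reflected Fokker–Planck solution)
holds only ~2% of mass below the unstable point, so the population
distribution is effectively unimodal — but the residence-time statistics
come out exactly on calibration (mean normalized LOW sojourn ≈ 1.0,
CV ≈ 1.1).  Under output truncation the stationary Nanog-low fraction is
17–21% and the population distribution is sharply bimodal (a zero mode plus
the high mode), but LOW sojourns then include deep latent excursions: their
mean is ~7–10 normalized units with CV ≈ 3.5, off calibration.  The default
follows the per-step truncation as the stated simulation rule; the
population-distribution analyses are documented against the `output`
variant.  Each criterion is tested under the rule it is attainable under,
and the stationary-fraction figure for the fluctuation scenario under the
default rule is reported as-is (~2%), not adjusted.

### Step sizes and burn-in

Defaults: `dt = 5e-5` (fluctuation; resolves the ~4·10⁻³ t.u. LOW sojourns
with dozens of steps) and `dt = 2e-3` (oscillation; resolves the 86 t.u.
cycle to ~0.1%; the long residence runs use 5·10⁻³, which changes the
period estimate by <1%).  Stationary ensembles burn in 5 t.u.
(fluctuation; ≈ 20 mean switching cycles — doubling it leaves the snapshot
distribution unchanged by a two-sample KS check) or 30 t.u. after
cycle-phase randomization (oscillation).  Oscillation ensembles draw
initial states uniformly in time along the deterministic cycle — the
stationary phase measure — rather than paying a many-period decorrelation
burn-in.

## Deterministic analysis

Fixed points come from dense sign-change bracketing on `[0, n_max]`
(`n_max = 10·(s3+s4)/d_N`) refined by Brent's method to 1e-10; stability
from the scalar derivative (1-D) or the eigenvalues of the 2×2 Nanog/X
Jacobian, with a ±1e-8 tie window flagged as an error rather than guessed.
The `s4` scan reports the bistable window (≥2 stable roots); the `s6` scan
classifies grid points as oscillatory when no stable fixed point remains,
and measures limit cycles by integration (LSODA at rtol 1e-9), discarding
the first half of the run and taking the period as the median spacing of
successive Nanog maxima (relative closure tolerance 1e-4; a run that
settles to a point returns an explicit no-cycle result so scans proceed).

## Observables

LOW/HIGH classification is hysteretic: a band placed log-symmetrically
(±25%) around the unstable Nanog fixed point, which is the separatrix
between the basins.  Snapshots use the single cut at the unstable point
(no history available).  Censored sojourns (first/last of a trace) are
excluded from moments and reported separately; sojourn CV is the population
(ddof = 0) coefficient of variation.  Density estimates use a Gaussian KDE
on `log10(n + 0.01)` since Nanog spans two orders of magnitude; modes are
maxima of the density above 1% of its peak.

Normalized time: the factor `f` rescales each scenario's clock so that the
mean Nanog-low residence time is one unit.  The fluctuation clock is fast
(mean LOW sojourn ≈ 1/270 t.u.), so `τ = f·t`; the oscillation clock is
slow (mean LOW sojourn ≈ 16 t.u., set by the cycle period — with
`d_X = 0.2` no parameterization of this model oscillates hundreds of times
faster), so there `τ = t/f`.  Both presets then yield mean normalized LOW
sojourns of ≈ 1.0 (measured 1.01 and 0.97).

## In-silico experiments

*Sorting*: a stationary population is split at the snapshot cut and the
selected subpopulation simulated onward; over-shoot is declared when the
opposing-state fraction exceeds its equilibrium value by >2 Monte-Carlo
standard errors at two consecutive recorded times (a single-point rule
false-triggers on ~2% of points, i.e. almost every series).  The
limit-cycle scenario over-shoots (sorting synchronizes phases; most
pronounced when selecting Nanog-low cells); the bistable scenario relaxes
aperiodically.

*Differentiation challenge*: the signal Y inhibits OS production by
`1/(1 + y_eff)` with `y_eff = amplitude · (1 − H(n_gate; k_gate, γ_gate))`.
The gate is latched at signal onset — the Nanog level the signal *hits*
decides transmission for the whole window.  This is a deliberate design
choice: in the fluctuation scenario a LOW sojourn (~4·10⁻³ t.u.) is three
orders of magnitude shorter than the OS decay (~3 t.u.), so an
instantaneously re-evaluated gate could never complete a differentiation
event there (an `"instantaneous"` mode is provided).  Default amplitude is
4× the smallest grid value removing the high OS fixed point; default
window 10 t.u.; `k_gate` is the unstable Nanog fixed point.  After a
collapse, OS sits in the basin of its stable zero state and the
OS-coupled noise vanishes, so zero LOW→HIGH transitions occur
post-collapse.

## What the synthetic data do and do not show

All data are generated by this simulator; there is no measurement model.
Real reporter distributions convolve Nanog kinetics with reporter
maturation, cell-cycle and division effects (a higher proliferation of
Nanog-high cells would skew the distribution), and instrument noise — none
of which are modelled.  Passing tests show the *mechanisms* behave as
analysed (bistable + noise vs limit cycle + phase noise, and their
discriminating signatures: residence-time shape, sorting over-shoot,
state-gated differentiation), not that either mechanism is what ES cells
do.  Time units are arbitrary; the mapping to hours/days is deliberately
left open.

## Known limitations

* The boundary-rule dichotomy above: the default per-step truncation does
  not produce a ~20% Nanog-low stationary fraction nor a bimodal
  population distribution at the fluctuation preset; the `output` variant
  does but moves the residence statistics off calibration.
* Crossing counts of the hysteresis band (hence the number of sojourns per
  unit time, not their mean length) retain some step-size sensitivity,
  as band-edge crossings are diffusive at σ = 12.
* Very short sojourns at the classifier's resolution distort the head of
  the fluctuation-scenario residence distribution; exponentiality holds
  for the excess distribution beyond half the mean.
* No discrete-molecule (Gillespie) limit, no multiplicative or coloured
  noise, no cell division, no delay terms, and no two-parameter
  bifurcation continuation.
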