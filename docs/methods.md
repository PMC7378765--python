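# Methods

## The model

Two boundedly rational populations play a repeated inspection game.
Vaccine manufacturers choose *self-discipline* (qualified production,
revenue `RV1`) or *non-self-discipline* (defective production, revenue
`RV2 > RV1`, but penalty-plus-reputation loss `FV1` and rectification cost
`FV2` if caught, on top of the inspection-cooperation cost `CV`).  The
government regulator chooses *active supervision* (proactive inspection,
effective cost `CG1/π`, detection probability `α`) or *passive
supervision* (inspection only after a third-party report, which arrives
with probability `λ` when a firm cheats; effective cost `CG2/ψ`, detection
probability `β`, with `0 < α < β ≤ 1` — reacting to a concrete report is
more likely to succeed, but the reactive apparatus is costlier overall:
`CG2/ψ > CG1/π > 0`).  `π` scales the strictness of government power and
regulations (stricter ⇒ cheaper active supervision), `ψ` the level of
public awareness feeding the passive channel (stronger ⇒ cheaper passive
supervision).  Discovering a violator is worth `RG ≥ 0` to the regulator.
All payoffs are dimensionless "payoff units"; no monetary calibration is
attempted, and bribery/rent-seeking between the parties is excluded by
assumption.

With `x` the share of self-disciplined manufacturers and `y` the share of
actively supervising regulators, each side's strategy share follows a
replicator equation: writing `D = RV2 + FV1 + FV2` for the violator's
total exposure,

    dx/dt = x(1−x) · A(y),   A(y) = yD(α − βλ) + RV1 − RV2 + βλD
    dy/dt = y(1−y) · B(x),   B(x) = (α − βλ)RG(1−x) + λ·CG2/ψ − CG1/π

where `A` and `B` are the expected-payoff advantages of self-discipline
and of active supervision.  The dimensionless time of the replicator flow
has no physical unit.

### Cost notation

The literature this model comes from writes the supervision costs as
products (`CG1π`, `CG2ψ`) while stating that larger `π`, `ψ` *lower* the
costs, and its interior-equilibrium formula is only consistent with the
quotient reading.  This package therefore implements the costs as
quotients `CG1/π` and `CG2/ψ` throughout.  At the baseline calibration
`π = ψ = 1`, so every baseline number is identical under either reading.

### Derived scalars

The analysis is organised by the profit–loss ratio

    ε = (RV2 − RV1) / (RV2 + FV1 + FV2) ∈ (0, 1),

the temptation of cheating relative to its total downside, compared
against the two detection probabilities `α` (active) and `βλ` (passive
channel: report *and* successful inspection).  The penalty coefficient
`μ = FV1/RV2 > 1` ("the fine should exceed the illicit revenue") is a
modelling assumption the baseline calibration itself violates
(`μ = 4/6`); it is treated as a validation *warning*, not an error, so
the baseline experiments remain runnable as published.

## Equilibria and stability

The four corners of the unit square are rest points for every parameter
set.  An interior mixed rest point

    x* = 1 − (λ·CG2/ψ − CG1/π) / ((βλ − α)RG),
    y* = (RV1 − RV2 + βλD) / (D(βλ − α)) = (βλ − ε)/(βλ − α)

exists iff both coordinates are strictly inside (0, 1); `y* ∈ (0,1)`
requires exactly that `ε` lie strictly between `α` and `βλ`, and
`x* ∈ (0,1)` additionally constrains the cost gap `λ·CG2/ψ − CG1/π`
against `(βλ − α)RG`.  When `βλ = α` or `RG = 0` the formulas are
singular and the enumeration reports a "degenerate" flag instead of a
point.

The Jacobian at a corner is diagonal, so stability reduces to the signs
of `a11 = ±A`, `a22 = ±B` there: an equilibrium is an ESS (locally
asymptotically stable) iff `tr J < 0` and `det J > 0`, i.e. both diagonal
entries negative.  At the interior point `A = B = 0` forces
`a11 = a22 = 0`, so the trace vanishes *identically*: the interior point
is at best a neutrally stable center (`det J > 0`, purely imaginary
eigenvalues, closed orbits) and never an ESS.  Classification tolerances:
a decisive quantity within `1e−9` of zero yields `non-hyperbolic`
(corners) or falls through to `center`/`non-hyperbolic` (interior) rather
than a guessed sign.

### Regimes

Ordering `ε` against `α` and `βλ`, and comparing `λ·CG2/ψ` with `CG1/π`,
gives the enumerated regimes: a *cycling transition period* when `ε` lies
strictly between the detection probabilities (no ESS; closed orbits
around the interior center when it exists), and four ESS regimes —
`(0,0)` / `(1,0)` when the λ-weighted passive cost is below the active
cost, `(0,1)` / `(1,1)` when it is above, with the manufacturer's
coordinate set by whether `ε` is above or below both detection
probabilities.  The strict inequality chains are evaluated on the raw
floats with no epsilon-padding; quantities within `1e−9` of a boundary
are reported as `critical` and the set is labelled `outside_enumerated`.

Two deliberate design choices here:

- **Fallback sign analysis, always.**  The enumerated conditions do not
  cover the parameter space — notably, the baseline calibration has
  `ε > βλ > α` but the *opposite* cost sign (`λ·CG2/ψ = 2 > CG1/π = 1`),
  so it falls outside every enumerated case.  `classify_regime` therefore
  always also runs direct corner-by-corner sign analysis and reports both.
  At the baseline the unique stable corner by sign analysis is `(0,1)`
  (manufacturers cheat, the regulator supervises actively), even though
  the full-defection outcome `(0,0)` is often quoted as the baseline
  attractor; `verify_claimed_ess` makes such conflicts explicit — `(0,0)`
  is a saddle there (`a11 = −0.16 < 0 < a22 = 0.94`) — instead of
  silently favouring either answer.  Simulation from any interior start
  confirms convergence to `(0,1)`.
- **The closed-orbit regime needs the center to exist.**  The cycling
  condition is usually stated as the ε-ordering alone, but that ordering
  does not guarantee `x* ∈ (0,1)`; e.g. the baseline with `FV1 = 5` has
  cycle-case ordering yet `x* < 0`, and `(0,1)` is then an ESS by sign
  analysis.  `classify_regime` assigns `cycle_case` on the ordering (and
  reports `interior_exists` separately); the sampler's cycle-case
  targeting and the prediction-vs-simulation property enforce interior
  existence, which is where the closed-orbit behavior actually holds.

## Numerics

- **Integration.**  `scipy.integrate.solve_ivp` (RK45), `rtol 1e−8`,
  `atol 1e−10`; tight enough that closed orbits around the zero-trace
  center do not artificially spiral over the horizons used here, so
  cycling is distinguishable from slow spiralling.  States are recorded
  at accepted steps and clamped onto `[0,1]`; an excursion beyond `1e−9`
  is an integration error, not silently repaired.
- **Long-run labels.**  A vertex label requires the state to stay within
  `1e−3` (Chebyshev) of a corner over the final 10 % of the time span — a
  settle *window*, so a transient pass near a saddle corner does not
  count as convergence.  `cycling` requires persistent oscillation:
  comparable amplitude in the two halves of the trajectory's second half
  (ratio ≥ 0.5, both > 10× the vertex tolerance) plus recurrence of the
  final state.  Default horizon 500 time units; the chunked driver
  `simulate_until_settled` (chunks of 150, cap 1500 by default) stops as
  soon as a vertex is reached, since convergence to a stable corner is
  exponential.
- **Threshold finding.**  The critical fine is the root of
  `ε(FV1) − βλ`, located by bisection on `[0, 20]` to `1e−6` and
  cross-checked against the closed form
  `FV1* = (RV2 − RV1)/(βλ) − RV2 − FV2` (= 4.5 at baseline).  The
  analytic criterion reproduces the simulated cooperation threshold
  exactly and is robust at desk scale, unlike reading the crossing off
  simulated trajectories.
- **Sweeps.**  Default initial state `(0.5, 0.5)` — the unbiased
  midpoint, matching symmetric ignorance about both populations.  Grids
  are configurable; defaults span the closed-form regime boundaries with
  6–10 points.
- **Output formatting.**  CSV/JSON floats at 10 significant digits, so
  identical configurations produce byte-identical reports across runs.

## The parameter sampler

`sample_parameters` draws uniformly from ranges spanning the baseline
calibration with room on both sides (e.g. `α ∈ (0.05, 0.95)`,
`FV1 ∈ (0, 15)`, `π, ψ ∈ (0.5, 2)`) and rejects draws violating the hard
invariants; options restrict to `μ > 1`, to a target regime, or to sets
admitting the interior equilibrium.  When targeting a regime for the
prediction-vs-simulation property, every decisive gap (`|ε − α|`,
`|ε − βλ|`, `|βλ − α|`, the cost gap) must exceed a margin of 0.05 so
sampled sets sit well inside an open regime; near-boundary sets converge
arbitrarily slowly and test the integrator, not the theory.  Sampling is
deterministic per seed.

What the sampler emulates is parameter heterogeneity, not data: this is
an analytic model with no empirical inputs, so passing tests show
internal consistency (equations ↔ equilibria ↔ simulations) and the
stated thresholds — they say nothing about how real regulators or
manufacturers behave, which the model's stylised payoffs only caricature.

## Test problem sizes

Property tests use 200 random parameter sets for the bracket/payoff
oracle, 50 targeted sets × 10 interior starts for
prediction-vs-simulation, 10 cycling-regime sets (horizon up to 8 orbital
periods, capped at 4000 time units, with the period estimated as
`2π/√det J` at the center), and grids of step 0.15 for the fine-sweep
boundary check; these sizes keep the full suite under a minute while
exercising every regime.

## Known limitations

- Deterministic, infinite-population replicator dynamics only: no
  finite-population (Moran/Fermi) noise, no more-than-two players or
  strategies.
- No Lyapunov function or first integral is constructed for the center
  case; "cycling" is certified numerically (bounded, non-decaying,
  recurrent orbits), not symbolically.
- Basins of attraction are explored by sampling starts, not computed.
- Plot rendering is out of scope; trajectories and sweeps are exported
  as CSV for external plotting.
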