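# vaxgame

Evolutionary game analysis of vaccine-manufacturer self-discipline under
government regulation.

Defective-vaccine scandals are a classic inspection-game problem: each
manufacturer weighs the extra revenue of cutting corners against the
penalty if caught, while the regulator weighs the cost of proactive
inspections against reacting only when a third party reports a violator.
`vaxgame` implements this interaction as a two-population evolutionary
game and is aimed at researchers and policy analysts who want to explore
when fines, inspection success rates, reporting probabilities, or
regulatory strictness actually tip an industry toward compliance.

## Model

Let `x` be the share of self-disciplined manufacturers (revenue `RV1`;
cheating earns `RV2 > RV1` but costs `FV1 + FV2` if detected) and `y` the
share of actively supervising regulators (effective cost `CG1/π`,
detection probability `α`; passive supervision costs `CG2/ψ` and detects
with probability `β > α`, but only fires after a third-party report,
probability `λ`).  The state evolves by replicator dynamics on the unit
square — with `D = RV2 + FV1 + FV2`:

    dx/dt = x(1−x)[ yD(α − βλ) + RV1 − RV2 + βλD ]
    dy/dt = y(1−y)[ (α − βλ)RG(1−x) + λ·CG2/ψ − CG1/π ]

The four corners are always equilibria; stability follows from the signs
of the diagonal Jacobian entries (ESS ⇔ `tr J < 0`, `det J > 0`).  The
dynamic regime is governed by the profit–loss ratio
`ε = (RV2 − RV1)/D` compared against the detection probabilities `α` and
`βλ`: when `ε` lies strictly between them the game has no ESS and orbits
an interior center `(x*, y*)` where the Jacobian trace vanishes
identically; otherwise one corner is the attractor, selected by the sign
of `λ·CG2/ψ − CG1/π`.  Raising the fine `FV1` lowers `ε` monotonically,
with the compliance threshold in closed form:
`FV1* = (RV2 − RV1)/(βλ) − RV2 − FV2` (= 4.5 at the baseline
calibration).  See `docs/methods.md` for assumptions, tolerances and
design choices.

## Worked example

```python
import vaxgame as vg

p = vg.GameParameters.baseline()
reg = vg.classify_regime(p)
print("case:", reg.case_id)
print("ordering:", reg.ordering)
print("sign-analysis ESS:", [s.as_tuple() for s in reg.sign_analysis_ess])

traj, out = vg.simulate_until_settled(p, (0.5, 0.5))
print("long run from (0.5, 0.5):", out.label)

th = vg.find_critical_fine(p)
print("critical fine:", round(th.critical_value, 6), "closed form:", th.closed_form)

sw = vg.sweep_parameter(p, "FV1", [3, 4, 5, 6, 8, 10])
print(sw.to_dataframe().to_string(index=False))
```

prints

```
case: outside_enumerated
ordering: epsilon > beta*lambda > alpha
sign-analysis ESS: [(0.0, 1.0)]
long run from (0.5, 0.5): vertex(0,1)
critical fine: 4.5 closed form: 4.499999999999998
 value  valid            case_id     outcome   terminal_x  terminal_y
   3.0   True outside_enumerated vertex(0,1) 7.327210e-27         1.0
   4.0   True outside_enumerated vertex(0,1) 6.899901e-11         1.0
   5.0   True         cycle_case vertex(0,1) 3.684150e-07         1.0
   6.0   True           case3_11 vertex(1,1) 1.000000e+00         1.0
   8.0   True           case3_11 vertex(1,1) 1.000000e+00         1.0
  10.0   True           case3_11 vertex(1,1) 1.000000e+00         1.0
```

Reading the output: at the baseline calibration the temptation of
cheating (`ε = 1/3`) exceeds both detection probabilities while the
λ-weighted passive cost exceeds the active cost, a combination outside
the enumerated regimes — direct sign analysis shows the unique stable
corner is `(0, 1)` (manufacturers cheat, the regulator supervises
actively), and simulation from the midpoint confirms it.  Note this
conflicts with the full-defection outcome `(0,0)` sometimes quoted for
this calibration; `vg.verify_claimed_ess(p)` reports that `(0,0)` is in
fact a saddle here.  Sweeping the fine: below the threshold `FV1* = 4.5`
nothing changes, between 4.5 and 16/3 the game enters the no-ESS
transition regime, and from `FV1 = 6` on the system settles at full
compliance with active supervision, `(1, 1)` — severe punishment works.

The same analyses are available from the shell:

```
vaxgame threshold
vaxgame --set FV1=10 classify
vaxgame simulate --init 0.5,0.5 --csv trajectory.csv
vaxgame sweep --name FV1 --values 3,4,5,6,8,10
```

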