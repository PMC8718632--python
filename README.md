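# dripship

Temporospatial decision modelling for prehospital transport of suspected
large-vessel-occlusion (LVO) stroke patients.

When a stroke with a suspected LVO starts outside the catchment of an
EVT-enabled hospital (CSC), paramedics face a dilemma: **Drip-and-Ship**
(nearest alteplase-only facility, PSC, first — thrombolysis, then
inter-facility transfer of confirmed EVT-eligible patients) or
**Mothership** (bypass straight to the CSC). `dripship` scores every
candidate scene location in the PSC catchment on two objectives —
expected probability of an excellent outcome (90-day modified Rankin
Scale 0–1) and expected transport cost — under both strategies, with the
inter-facility transfer conditionally carried by rotary-wing air
ambulance, and renders the four-colour decision maps used by health-system
planners.

## Model

**Air transfer.** The rotary time advantage is
ΔT = t<sub>PSC→CSC|ground</sub> − (t<sub>alarm→wheels-up</sub> + t<sub>airbase→PSC|air</sub> + t<sub>on-ground@PSC</sub> + t<sub>PSC→CSC|air</sub>),
mapped through a piecewise-linear consideration probability (0 for
ΔT ≤ 10 min, 1 for ΔT ≥ 40 min, linear between), then

Pr{Air} = Pr{consideration} · Pr{airworthy weather} · Pr{availability},  Pr{Ground} = 1 − Pr{Air}.

**Outcomes.** A screen-positive patient (LAMS ≥ 4) is a mixture of final
diagnoses (LVO 45.38%, non-LVO ischemic 10.92%, ICH 34.45%, mimic
9.24%), with LVO split into EVT-eligible (Y) and ineligible fractions.
Each branch's excellent-outcome probability is a non-increasing function
of its onset-to-needle / onset-to-puncture time; the Drip-and-Ship
expectation additionally averages the EVT-eligible branch over the
transfer mode with weights Pr{Ground}/Pr{Air}.

**Costs** (CAD, per screen-positive patient). Mothership:
F<sub>G</sub> + 2·V<sub>G</sub>·D<sub>scene→CSC</sub>. Drip-and-Ship:
the same ground formula for the scene→PSC leg plus
α·Y·[Pr{Ground}·(F′<sub>G</sub> + 2·V<sub>G</sub>·D<sub>PSC→CSC</sub>) + Pr{Air}·(F<sub>A</sub> + V<sub>A</sub>·(D<sub>airbase→PSC</sub> + D<sub>PSC→CSC</sub>))].
Ground variable costs are doubled to reflect the system strain of
displacing a ground ambulance; the air variable cost is not.

Each scene is coloured **red** (DS better on both objectives), **green**
(MS better on both), **purple** (DS better outcome, MS cheaper) or
**blue** (MS better outcome, DS cheaper).

## Worked example

`python examples/transfer_probability.py` prints the transfer
probability at the four standard separations (airbase at the CSC):

```
sep (min)     km  dT (min)  consider  Pr{Air}
       60     80    -12.80    0.0000    0.00%
      120    160      9.41    0.0000    0.00%
      180    240     31.61    0.7205   62.85%
      240    320     53.82    1.0000   87.24%
```

At 60/120 min the helicopter never saves the 10-min minimum, so every
transfer drives; at 240 min the 53.8-min saving means air is always
considered and Pr{Air} is capped only by weather × availability.

`python examples/probe_scene.py` scores a scene 20 km north of the PSC
with the CSC 240 km south (base case: inefficient PSC, Y = 50%):

```
Mothership: onset-to-needle none min, onset-to-puncture 345 min
 DS ground: onset-to-needle 135 min, onset-to-puncture 405 min
    DS air: onset-to-needle 135 min, onset-to-puncture 313 min

Pr{Air} = 62.85% (time advantage 31.6 min)
P(excellent): MS 0.2688 vs DS 0.3377
cost (CAD):   MS 3100.00 vs DS 2113.97
map colour:   red
```

Mothership would arrive past the 4.5-h alteplase window (needle "none")
and reach puncture late; Drip-and-Ship treats at 135 min and, thanks to
the likely air transfer, punctures earlier *and* costs less — both
objectives agree on Drip-and-Ship (red).

Full scenario runs (maps + tables + manifest) via the CLI:

```sh
dripship run --preset A --out out/scenarioA
dripship probe --preset A --separation-min 180 --x 0 --y 20
dripship validate --preset A --n 200000
```

Presets: A (inefficient PSC, Y=0.5), B (inefficient, 0.7),
C (efficient, 0.5), D (efficient, 0.7), each at 60/120/180/240-min
separations.

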