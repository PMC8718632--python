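# Methods

## Scope and geometry

The model compares two prehospital transport strategies for a patient
who screens positive for a large-vessel-occlusion (LVO) stroke in the
field, at every candidate scene location inside the catchment of an
alteplase-only facility (PSC). Geometry is planar Euclidean and route
distance equals straight-line distance for both ground and air travel —
a deliberate simplification that slightly favours ground transport in
practice, where road distances exceed great-circle distances. One PSC,
one CSC (EVT-enabled facility) and one helicopter airbase exist per map;
by default the airbase is co-located with the CSC, which is the
placement consistent with the reference transfer-probability operating
points, and the CSC is drawn due south of the PSC. The catchment is the
disc of scenes within 60 min of ground driving from the PSC (80 km at
the default 80 km/h), sampled on a 1-km square lattice with real-valued
distances (no raster rounding).

## Time chains

All chains share the prehospital prefix: onset-to-first-medical-contact
(default 30 min; a 20-min variant is sometimes used in the field and is
configurable) + response (15) + on-scene (15), treated as strictly
additive. Then:

* **Mothership**: drive to CSC; needle at arrival + DTN_CSC (30),
  puncture at arrival + door-to-puncture for direct arrivals (90).
* **Drip-and-Ship / ground**: drive to PSC; needle at arrival + DTN_PSC;
  door-out at needle + NTDO; drive to CSC; puncture after the
  transferred-arrival door-to-puncture (30).
* **Drip-and-Ship / air**: the helicopter alarm is raised at
  thrombolysis time; puncture = needle point + alarm-to-wheels-up (15) +
  flight airbase→PSC + on-ground at PSC (20) + flight PSC→CSC + 30.
  NTDO applies to ground transfers only.

A useful identity, property-tested in the suite:
`puncture(DS, ground) − puncture(DS, air) = ΔT + NTDO`, where ΔT is the
air time advantage defined below.

A needle time is dropped (no alteplase) when the candidate
onset-to-needle exceeds the 4.5-h window; such patients still transfer
for EVT using the same door-out anchor, assuming equivalent
door-in-door-out times for patients with contraindications. CSC
process times (DTN 30, door-to-puncture 90 direct / 30 transferred) are
modelling assumptions, not measured values, and are configurable;
the transferred-arrival value is lower because imaging and work-up are
completed before departure.

## Air-transfer probability

ΔT = ground inter-facility time − (alarm-to-wheels-up + flight
airbase→PSC + on-ground at PSC + flight PSC→CSC). Consideration of air
transport is piecewise linear in ΔT with knots at 10 and 40 min (0 at or
below the first, 1 at or beyond the second, continuous at both), and
Pr{Air} multiplies consideration by airworthy-weather (0.904) and
resource-availability (0.965) probabilities. Pr{Ground} is the exact
complement — a transfer that cannot fly always drives. Pr{Air} is a
per-layout constant (it depends only on the PSC–CSC and airbase–PSC
distances), computed once per scenario. At a 180-min separation these
constants give Pr{Air} = 62.85%, at 240 min 87.24%; the commonly quoted
62.79/87.15% correspond to an availability of 96.4% rather than 96.5% —
a 0.1-pp discrepancy the package surfaces but does not resolve (tests
require agreement within 0.1 pp).

## Outcome model

Excellent outcome is 90-day mRS 0–1. A screen-positive patient is a
mixture over final diagnoses — LVO 45.38%, non-LVO ischemic 10.92%, ICH
34.45%, mimic 9.24% (printed weights total 99.99% and are renormalized)
— with the LVO weight split by EVT eligibility Y. ICH and mimic
outcomes are transport-invariant constants. Treated non-LVO and
ineligible-LVO patients follow alteplase decay curves in onset-to-needle
time; eligible-LVO patients follow the EVT decay curve in
onset-to-puncture time under the default "evt-dominates" combine rule
(a "max" rule is selectable). EVT has no hard time cutoff by default —
benefit decays through the curve — and an optional cutoff is available.

The decay curves are logistic, `P(t) = 1/(1+exp(−(β0+β1 t)))` with
β1 ≤ 0. The meta-analysis coefficients used by the upstream
conditional-probability outcome model are not reproduced here, so the
shipped defaults are the package's own documented choices, picked once
to be clinically plausible (EVT: β0 = 0.35, β1 = −0.0035, i.e. ~51% at
90 min falling to ~35% at 4.5 h; LVO alteplase: β0 = −0.10, β1 = −0.006;
non-LVO alteplase: β0 = 1.2, β1 = −0.0045; untreated LVO 0.10, untreated
non-LVO 0.40, ICH 0.15, mimic 0.90). The LVO-alteplase decay is steeper
than the EVT decay, reflecting alteplase's stronger time dependence.
Consequences: map *values* and exact region boundaries are not
comparable to externally reported figures — region structure (existence, ordering
and direction of change across scenarios) is, and that is what the test
suite asserts. All cost results are curve-independent.

The Drip-and-Ship expectation is Pr{Ground}·E[outcome | ground times] +
Pr{Air}·E[outcome | air times]; only the EVT-eligible branch depends on
the mode, since no other diagnosis transfers.

## Cost model

Per screen-positive patient, in CAD. Every ground leg costs a fixed
charge plus twice the per-km variable cost (the doubling is a proxy for
the system strain of displacing a ground ambulance); the air leg charges
its variable cost once over airbase→PSC + PSC→CSC. Only confirmed
EVT-eligible LVO patients (fraction α·Y, α = 0.4538) transfer, including
patients beyond the alteplase window. Defaults: F_G = 500,
F_G′ = 400 (inter-facility ground transfers start cheaper than scene
responses), F_A = 2500, V_G = 5/km, V_A = 12/km. No return-to-base leg,
no downstream hospital costs, no discounting.

The cost formula's α is the printed 45.38% while the simulation oracle
draws the diagnosis from the renormalized mixture (45.385%); the
resulting systematic offset (~0.2 CAD at the largest layouts) is three
orders of magnitude below the Monte-Carlo standard error at n = 200,000
and is accepted.

## Classification and rendering

red = DS better on both objectives, green = MS better on both, purple =
DS better outcome / MS cheaper, blue = MS better outcome / DS cheaper.
Differences within ε (10⁻⁹ on outcome probability, 0.005 CAD on cost)
count as ties and resolve toward Mothership, the single-transport
default; this suppresses salt-and-pepper noise at region boundaries.
Maps draw 5-min concentric drive-time rings around the PSC (circle
marker), a diamond at the CSC, and dashed white/yellow arcs where the
onset-to-needle time exceeds 4.5 h at the PSC/CSC respectively. With the
default 60-min catchment and an inefficient PSC the white arc lies
outside the map (maximum PSC needle time 180 min); it appears when the
catchment is enlarged or the window shortened.

## Monte-Carlo oracle

The analytic expectations are mixtures; an independent patient-level
simulator draws, per patient, the final diagnosis (categorical over the
renormalized mixture), EVT eligibility (Bernoulli Y) and, for
Drip-and-Ship, the transfer mode (Bernoulli Pr{Air}), then averages the
realized branch outcome probability and realized transport cost. The
suite requires agreement within 3 standard errors at n = 200,000 at 20
random scenes per scenario; with all-constant degenerate mixtures the
oracle reproduces the constant with (numerically) zero spread. All
randomness flows through a seeded `numpy` generator; identical seeds
give identical estimates.

## Problem sizes and numerical choices

Grid tests run at 1-km resolution over the 60-min catchment (~20,100
scenes per map, about a second per map); module tests use coarser grids
where only structure matters. The acceptance script evaluates the four
standard layouts analytically and cross-checks five random scenes
against the simulator before writing results. Ties at piecewise knots
follow the closed/open convention above (ΔT exactly at the lower knot
gives consideration 0). Scene grids are never empty: a resolution
larger than the catchment radius is rejected as a configuration error.

## Known limitations

Planar geometry without road networks, terrain or no-fly zones; a single
PSC/CSC pair; deterministic service times; no helicopter queueing,
mission aborts or return legs; fixed-wing transport out of scope; the
outcome-curve coefficients are plausible defaults rather than fitted
values, so absolute outcome probabilities should not be read as
predictions — the model's comparative structure (which strategy wins
where, and how scenarios shift the boundary) is the supported output.
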