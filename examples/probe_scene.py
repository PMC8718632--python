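"""Score one scene location under both transport strategies.

Places a stroke scene 20 km north of the alteplase-only facility with
the EVT centre 240 km south, then prints the treatment-time chains, the
two objectives (expected probability of 90-day mRS 0-1, expected
transport cost) and the resulting map colour.  Red/green mean both
objectives agree on DS/MS; purple and blue mark divergence.
"""

from dripship import (
    FacilityLayout,
    OutcomePair,
    ScenarioConfig,
    classify,
    cost_dripship,
    dripship_air_times,
    dripship_ground_times,
    expected_outcome_dripship,
    expected_outcome_mothership,
    mothership_times,
    scene_from_xy,
    transfer_probabilities,
)

cfg = ScenarioConfig()  # base case: inefficient PSC, 50% EVT eligibility
layout = FacilityLayout.from_separation_km(240.0)
scene = scene_from_xy(0.0, 20.0, layout)

for label, t in (
    ("Mothership", mothership_times(scene, cfg)),
    ("DS ground", dripship_ground_times(scene, cfg)),
    ("DS air", dripship_air_times(scene, cfg)),
):
    needle = f"{t.t_needle:.0f}" if t.t_needle is not None else "none"
    print(f"{label:>10}: onset-to-needle {needle} min, onset-to-puncture {t.t_puncture:.0f} min")

probs = transfer_probabilities(scene, cfg)
pair = OutcomePair(
    p_ms=expected_outcome_mothership(scene, cfg),
    p_ds=expected_outcome_dripship(scene, cfg),
)
cb = cost_dripship(scene, probs, cfg)
print(f"\nPr{{Air}} = {probs.p_air:.2%} (time advantage {probs.delta_t:.1f} min)")
print(f"P(excellent): MS {pair.p_ms:.4f} vs DS {pair.p_ds:.4f}")
print(f"cost (CAD):   MS {cb.tc_ms:.2f} vs DS {cb.tc_ds:.2f}")
print(f"map colour:   {classify(pair, cb)}")
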