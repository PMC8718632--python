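"""Validate the analytic expectations with patient-level simulation.

Samples 200,000 simulated patients at one scene — drawing the final
diagnosis, EVT eligibility, and transfer mode — and compares the average
realized outcome probability and transport cost against the closed-form
mixture expectations.  Agreement within ~3 standard errors confirms the
analytic model and the simulator describe the same process.
"""

from dripship import (
    FacilityLayout,
    ScenarioConfig,
    cost_dripship,
    expected_outcome_dripship,
    monte_carlo_oracle,
    scene_from_xy,
    transfer_probabilities,
)

cfg = ScenarioConfig()
layout = FacilityLayout.from_separation_km(240.0)
scene = scene_from_xy(15.0, -30.0, layout)

out_est, cost_est = monte_carlo_oracle(scene, cfg, n=200_000, seed=1)
p_ds = expected_outcome_dripship(scene, cfg)
tc_ds = cost_dripship(scene, transfer_probabilities(scene, cfg), cfg).tc_ds

print(f"outcome: analytic {p_ds:.5f}, simulated {out_est.mean:.5f} "
      f"(SE {out_est.se:.5f}, z = {(out_est.mean - p_ds) / out_est.se:+.2f})")
print(f"cost:    analytic {tc_ds:.2f}, simulated {cost_est.mean:.2f} "
      f"(SE {cost_est.se:.2f}, z = {(cost_est.mean - tc_ds) / cost_est.se:+.2f})")
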