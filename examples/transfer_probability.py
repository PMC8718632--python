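"""How likely is a helicopter transfer at each inter-facility distance?

Builds the standard layout (PSC at the origin, CSC due south, airbase at
the CSC) for the four ground-drive separations and prints the rotary
time advantage and Pr{Air}.  A transfer flies only when the time saved
over the ground leg clears the 10-min consideration threshold and both
weather and the aircraft cooperate, so Pr{Air} is 0 at short separations
and saturates near weather x availability (~87%) at long ones.
"""

from dripship import FacilityLayout, ScenarioConfig, km_from_minutes, transfer_probabilities

cfg = ScenarioConfig()
print(f"{'sep (min)':>9} {'km':>6} {'dT (min)':>9} {'consider':>9} {'Pr{Air}':>8}")
for sep in (60, 120, 180, 240):
    d = km_from_minutes(sep, cfg.v_ground)
    p = transfer_probabilities(FacilityLayout.from_separation_km(d), cfg)
    print(f"{sep:>9} {d:>6.0f} {p.delta_t:>9.2f} {p.p_consideration:>9.4f} {p.p_air:>8.2%}")
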