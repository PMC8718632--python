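"""Render one temporospatial decision map.

Evaluates scenario C (efficient alteplase-only facility, 50% EVT
eligibility) at a 180-min inter-facility separation over a 2-km grid and
writes the four-colour map plus its per-scene table.  The printed
category counts summarise how much of the catchment favours each
strategy; the blue/purple counts are the divergent regions where outcome
and cost disagree.
"""

from pathlib import Path

from dripship import FacilityLayout, PRESETS, evaluate_grid, km_from_minutes, render

cfg = PRESETS["C"].config()
layout = FacilityLayout.from_separation_km(km_from_minutes(180, cfg.v_ground))
grid = evaluate_grid(layout, cfg, resolution=2.0)

out = Path("scratch") / "scenario_C_180min.png"
png, csv = render(grid, out)
print(f"Pr{{Air}} = {grid.probs.p_air:.2%}")
print("category counts:", grid.category_counts())
print(f"wrote {png} and {csv}")
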