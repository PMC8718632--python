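"""Scenario presets, configuration files and batch runs.

Four named scenarios span the cross of alteplase-only-facility
efficiency and EVT eligibility:

====  ===========  ============  ===============
name  efficiency   DTN / NTDO    EVT eligibility
====  ===========  ============  ===============
A     inefficient  60 / 60 min   50%
B     inefficient  60 / 60 min   70%
C     efficient    30 / 20 min   50%
D     efficient    30 / 20 min   70%
====  ===========  ============  ===============

Each scenario is run at four inter-facility separations — 60, 120, 180
and 240 min of ground driving, converted to km at the ground speed —
producing one temporospatial map and per-scene table per increment plus
a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Tuple

import yaml

from . import __version__
from .air_transfer import transfer_probabilities
from .config import ConfigError, FacilityLayout, OutcomeParams, ScenarioConfig
from .decision_map import evaluate_grid, render
from .geometry import km_from_minutes

logger = logging.getLogger("dripship")

SEPARATIONS_MIN = (60, 120, 180, 240)


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    psc_efficiency: str  #: "efficient" or "inefficient"
    dtn_psc: float
    ntdo_psc: float
    y: float

    def config(self, base: ScenarioConfig | None = None) -> ScenarioConfig:
        base = base or ScenarioConfig()
        return base.with_updates(dtn_psc=self.dtn_psc, ntdo_psc=self.ntdo_psc, y=self.y)


PRESETS: Mapping[str, ScenarioPreset] = {
    "A": ScenarioPreset("A", "inefficient", 60.0, 60.0, 0.5),
    "B": ScenarioPreset("B", "inefficient", 60.0, 60.0, 0.7),
    "C": ScenarioPreset("C", "efficient", 30.0, 20.0, 0.5),
    "D": ScenarioPreset("D", "efficient", 30.0, 20.0, 0.7),
}

_LAYOUT_FIELDS = {"psc_xy", "csc_xy", "airbase_xy", "catchment_radius_min"}


def _coerce_xy(v):
    if v is None:
        return None
    return tuple(float(x) for x in v)


def load_config(path: str | Path | None) -> Tuple[ScenarioConfig, FacilityLayout]:
    """Load a YAML/JSON scenario file; omitted fields keep their defaults.

    The file mirrors the :class:`ScenarioConfig` and
    :class:`FacilityLayout` field names one-to-one, either flat at top
    level or under ``scenario:`` / ``layout:`` sections; ``outcome_params``
    is a nested block.  An empty file yields the full defaults.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"scenario file must contain a mapping, got {type(raw).__name__}")

    scenario_raw = dict(raw.get("scenario", {}))
    layout_raw = dict(raw.get("layout", {}))
    for key, value in raw.items():
        if key in ("scenario", "layout"):
            continue
        (layout_raw if key in _LAYOUT_FIELDS else scenario_raw)[key] = value

    cfg_fields = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = [k for k in scenario_raw if k not in cfg_fields]
    unknown += [k for k in layout_raw if k not in _LAYOUT_FIELDS]
    if unknown:
        raise ConfigError(f"unknown configuration field(s): {', '.join(sorted(unknown))}")

    if "outcome_params" in scenario_raw:
        op = scenario_raw["outcome_params"]
        if not isinstance(op, dict):
            raise ConfigError("outcome_params must be a mapping")
        op_fields = {f.name for f in dataclasses.fields(OutcomeParams)}
        bad = [k for k in op if k not in op_fields]
        if bad:
            raise ConfigError(f"unknown outcome_params field(s): {', '.join(sorted(bad))}")
        scenario_raw["outcome_params"] = OutcomeParams(**op)
    if "mix" in scenario_raw:
        scenario_raw["mix"] = tuple(float(w) for w in scenario_raw["mix"])

    for key in ("psc_xy", "csc_xy", "airbase_xy"):
        if key in layout_raw:
            layout_raw[key] = _coerce_xy(layout_raw[key])

    cfg = ScenarioConfig(**scenario_raw)
    layout = FacilityLayout(**layout_raw)
    return cfg, layout


def _config_echo(cfg: ScenarioConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["mix"] = list(d["mix"])
    return d


def run_scenario(
    preset_or_config: str | ScenarioConfig,
    out_dir: str | Path,
    separations_min: Tuple[int, ...] = SEPARATIONS_MIN,
    resolution_km: float = 1.0,
    catchment_radius_min: float = 60.0,
    seed: int = 0,
) -> dict:
    """Run one scenario at each separation increment; write maps, tables
    and a JSON manifest.  Returns the manifest dict."""
    if isinstance(preset_or_config, str):
        preset = PRESETS.get(preset_or_config.upper())
        if preset is None:
            raise ConfigError(
                f"unknown preset {preset_or_config!r}; choose from {sorted(PRESETS)}"
            )
        cfg = preset.config()
        name = preset.name
    else:
        cfg = preset_or_config
        name = "custom"

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory {out_dir} is not writable")

    manifest = {
        "scenario": name,
        "version": __version__,
        "seed": seed,
        "resolution_km": resolution_km,
        "catchment_radius_min": catchment_radius_min,
        "config": _config_echo(cfg),
        "increments": [],
    }
    for sep in separations_min:
        d_km = km_from_minutes(sep, cfg.v_ground)
        layout = FacilityLayout.from_separation_km(
            d_km, catchment_radius_min=catchment_radius_min
        )
        probs = transfer_probabilities(layout, cfg)
        logger.info(
            "scenario %s, separation %d min (%.0f km): Pr{Air} = %.4f",
            name, sep, d_km, probs.p_air,
        )
        grid = evaluate_grid(layout, cfg, resolution=resolution_km)
        png, csv = render(grid, out_dir / f"scenario_{name}_{sep}min.png")
        manifest["increments"].append({
            "separation_min": sep,
            "d_psc_csc_km": d_km,
            "p_air": probs.p_air,
            "delta_t_min": probs.delta_t,
            "category_counts": grid.category_counts(),
            "png": png.name,
            "csv": csv.name,
        })
    manifest_path = out_dir / f"scenario_{name}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    logger.info("wrote %s", manifest_path)
    return manifest
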