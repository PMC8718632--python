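"""Scene-grid construction and distance/time conversion.

Geometry is planar Euclidean: ground route distance equals straight-line
distance, the same distance used for air travel.  A scene grid samples the
PSC catchment (a ground-drive-time disc) on a square lattice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .config import ConfigError, FacilityLayout, ScenarioConfig


def minutes_from_km(d: float, v: float) -> float:
    """Travel time in minutes to cover ``d`` km at ``v`` km/h."""
    if v <= 0:
        raise ConfigError(f"speed must be > 0, got {v}")
    if d < 0:
        raise ValueError(f"distance must be >= 0, got {d}")
    return 60.0 * d / v


def km_from_minutes(t: float, v: float) -> float:
    """Distance in km covered in ``t`` minutes at ``v`` km/h."""
    if v <= 0:
        raise ConfigError(f"speed must be > 0, got {v}")
    return t * v / 60.0


@dataclass(frozen=True)
class ScenePoint:
    """A candidate stroke-onset location with its layout distances (km)."""

    xy: Tuple[float, float]
    d_scene_psc: float
    d_scene_csc: float
    d_psc_csc: float
    d_airbase_psc: float


def scene_from_xy(x: float, y: float, layout: FacilityLayout) -> ScenePoint:
    """Build a :class:`ScenePoint` at planar coordinates ``(x, y)`` km."""
    return ScenePoint(
        xy=(float(x), float(y)),
        d_scene_psc=math.dist((x, y), layout.psc_xy),
        d_scene_csc=math.dist((x, y), layout.csc_xy),
        d_psc_csc=layout.d_psc_csc,
        d_airbase_psc=layout.d_airbase_psc,
    )


def build_scene_grid(layout: FacilityLayout, cfg: ScenarioConfig,
                     resolution: float = 1.0) -> List[ScenePoint]:
    """Sample the PSC catchment on a square lattice of spacing ``resolution`` km.

    Every lattice point whose ground drive time to the PSC is at most
    ``layout.catchment_radius_min`` is included.  The lattice is centred
    on the PSC.
    """
    if resolution <= 0:
        raise ConfigError(f"resolution must be > 0, got {resolution}")
    r_km = km_from_minutes(layout.catchment_radius_min, cfg.v_ground)
    if resolution > r_km:
        raise ConfigError(
            f"resolution {resolution} km exceeds the catchment radius "
            f"({r_km:.1f} km); the grid would not resolve the catchment"
        )
    px, py = layout.psc_xy
    n = int(math.floor(r_km / resolution))
    points: List[ScenePoint] = []
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            x = px + i * resolution
            y = py + j * resolution
            d_psc = math.hypot(i * resolution, j * resolution)
            if minutes_from_km(d_psc, cfg.v_ground) <= layout.catchment_radius_min:
                points.append(scene_from_xy(x, y, layout))
    if not points:
        raise ConfigError(
            f"empty scene grid: resolution {resolution} km exceeds the "
            f"{layout.catchment_radius_min}-min catchment radius ({r_km:.1f} km)"
        )
    return points


def arc_masks(grid: List[ScenePoint], cfg: ScenarioConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean masks for the thrombolysis-window arcs.

    ``white``: scenes whose Drip-and-Ship onset-to-needle time at the
    alteplase-only facility exceeds the alteplase window, so no alteplase
    can be given there.  ``yellow``: scenes whose Mothership
    onset-to-needle time at the EVT-enabled facility exceeds the window.
    """
    if not grid:
        raise ValueError("arc_masks requires a non-empty grid")
    prefix = cfg.t_onset_fmc + cfg.t_response + cfg.t_onscene
    white = np.array([
        prefix + minutes_from_km(p.d_scene_psc, cfg.v_ground) + cfg.dtn_psc > cfg.tpa_window
        for p in grid
    ])
    yellow = np.array([
        prefix + minutes_from_km(p.d_scene_csc, cfg.v_ground) + cfg.dtn_csc > cfg.tpa_window
        for p in grid
    ])
    return white, yellow
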