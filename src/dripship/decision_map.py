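"""Grid evaluation, four-colour classification, rendering and the
Monte-Carlo validation oracle.

Each scene location in the catchment is scored on two objectives —
expected probability of an excellent outcome and expected transport cost
— under both strategies, then classified:

* ``red``    — Drip-and-Ship better on both objectives;
* ``green``  — Mothership better on both;
* ``purple`` — Drip-and-Ship better outcome but Mothership cheaper;
* ``blue``   — Mothership better outcome but Drip-and-Ship cheaper.

Ties (within a small epsilon on each objective) resolve toward
Mothership, the single-transport default, which avoids salt-and-pepper
category noise along region boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Circle, Patch

from .air_transfer import TransferProbabilities, transfer_probabilities
from .config import FacilityLayout, ScenarioConfig
from .costs import (
    CostBreakdown,
    cost_dripship,
    cost_mothership,
    cost_scene_psc,
    cost_transfer_air,
    cost_transfer_ground,
)
from .geometry import ScenePoint, arc_masks, build_scene_grid, km_from_minutes
from .outcomes import (
    OutcomePair,
    curves_for,
    expected_outcome_dripship,
    expected_outcome_mothership,
    outcome_for_diagnosis,
)
from .treatment_times import dripship_air_times, dripship_ground_times, mothership_times

CATEGORIES = ("red", "green", "purple", "blue")

CATEGORY_COLORS = {
    "red": (0.84, 0.15, 0.16),
    "green": (0.17, 0.63, 0.17),
    "purple": (0.58, 0.40, 0.74),
    "blue": (0.12, 0.47, 0.71),
}

#: tie tolerances; agreement within these resolves toward Mothership
EPS_OUTCOME = 1e-9
EPS_COST = 0.005


def classify(
    outcomes: OutcomePair,
    costs: CostBreakdown | Tuple[float, float],
    eps_outcome: float = EPS_OUTCOME,
    eps_cost: float = EPS_COST,
) -> str:
    """Four-colour category from the two strategy comparisons.

    ``costs`` may be a :class:`CostBreakdown` or a ``(tc_ms, tc_ds)`` pair.
    """
    if isinstance(costs, CostBreakdown):
        tc_ms, tc_ds = costs.tc_ms, costs.tc_ds
    else:
        tc_ms, tc_ds = costs
    for v in (outcomes.p_ms, outcomes.p_ds, tc_ms, tc_ds):
        if not math.isfinite(v):
            raise ValueError("classify requires finite objectives")
    ds_outcome_better = outcomes.p_ds > outcomes.p_ms + eps_outcome
    ds_cheaper = tc_ds < tc_ms - eps_cost
    if ds_outcome_better and ds_cheaper:
        return "red"
    if ds_outcome_better:
        return "purple"
    if ds_cheaper:
        return "blue"
    return "green"


@dataclass
class DecisionGrid:
    """Per-scene objectives and categories over a catchment grid."""

    points: List[ScenePoint]
    outcomes: List[OutcomePair]
    costs: List[CostBreakdown]
    categories: List[str]
    white: np.ndarray
    yellow: np.ndarray
    probs: TransferProbabilities
    layout: FacilityLayout
    cfg: ScenarioConfig
    resolution: float = 1.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_km": [p.xy[0] for p in self.points],
            "y_km": [p.xy[1] for p in self.points],
            "p_ms": [o.p_ms for o in self.outcomes],
            "p_ds": [o.p_ds for o in self.outcomes],
            "tc_ms": [c.tc_ms for c in self.costs],
            "tc_ds": [c.tc_ds for c in self.costs],
            "category": self.categories,
            "white_arc": self.white.astype(bool),
            "yellow_arc": self.yellow.astype(bool),
        })

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for c in self.categories:
            counts[c] += 1
        return counts


def evaluate_grid(
    layout: FacilityLayout,
    cfg: ScenarioConfig,
    resolution: float = 1.0,
    eps_outcome: float = EPS_OUTCOME,
    eps_cost: float = EPS_COST,
) -> DecisionGrid:
    """Evaluate both objectives and classify every scene in the catchment."""
    grid = build_scene_grid(layout, cfg, resolution)
    probs = transfer_probabilities(layout, cfg)
    white, yellow = arc_masks(grid, cfg)
    outcomes, costs, categories = [], [], []
    for scene in grid:
        pair = OutcomePair(
            p_ms=expected_outcome_mothership(scene, cfg),
            p_ds=expected_outcome_dripship(scene, cfg),
        )
        cb = cost_dripship(scene, probs, cfg)
        outcomes.append(pair)
        costs.append(cb)
        categories.append(classify(pair, cb, eps_outcome, eps_cost))
    return DecisionGrid(
        points=grid, outcomes=outcomes, costs=costs, categories=categories,
        white=white, yellow=yellow, probs=probs, layout=layout, cfg=cfg,
        resolution=resolution,
    )


@dataclass(frozen=True)
class MCEstimate:
    mean: float
    se: float
    n: int
    seed: int


def monte_carlo_oracle(
    scene: ScenePoint,
    cfg: ScenarioConfig,
    n: int = 200_000,
    seed: int = 0,
    strategy: str = "DS",
) -> Tuple[MCEstimate, MCEstimate]:
    """Patient-level simulation of one strategy at one scene.

    Samples, per simulated patient, the final diagnosis (categorical over
    the renormalized mixture), EVT eligibility (Bernoulli Y) and, for
    Drip-and-Ship transfers, the transfer mode (Bernoulli Pr{Air}); then
    averages the realized outcome probability and realized transport
    cost.  Returns (outcome estimate, cost estimate), each with its
    standard error.  Used as an independent brute-force check on the
    analytic expectations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if strategy not in ("DS", "MS"):
        raise ValueError(f"strategy must be 'DS' or 'MS', got {strategy!r}")
    rng = np.random.default_rng(seed)
    w_lvo, w_nonlvo, w_ich, w_mimic = cfg.mix_normalized
    diag = rng.choice(4, size=n, p=[w_lvo, w_nonlvo, w_ich, w_mimic])
    eligible = rng.random(n) < cfg.y
    probs = transfer_probabilities(scene, cfg)
    air = rng.random(n) < probs.p_air

    curves = curves_for(cfg)
    t_ms = mothership_times(scene, cfg)
    t_dsg = dripship_ground_times(scene, cfg)
    t_dsa = dripship_air_times(scene, cfg)

    tg = cost_transfer_ground(scene.d_psc_csc, cfg)
    ta = cost_transfer_air(scene.d_airbase_psc, scene.d_psc_csc, cfg)
    ms_cost = cost_mothership(scene.d_scene_csc, cfg)
    ds_scene_cost = cost_scene_psc(scene.d_scene_psc, cfg)

    # realized outcome/cost depend only on the sampled branch, so evaluate
    # each branch once and gather per patient
    is_lvo = diag == 0
    other = np.select(
        [diag == 1, diag == 2, diag == 3], [1, 2, 3], default=0
    )  # 0 placeholder for LVO rows
    if strategy == "MS":
        branch_vals = np.array([
            outcome_for_diagnosis("lvo_eligible", t_ms, curves, cfg),
            outcome_for_diagnosis("nonlvo", t_ms, curves, cfg),
            outcome_for_diagnosis("ich", t_ms, curves, cfg),
            outcome_for_diagnosis("mimic", t_ms, curves, cfg),
        ])
        lvo_inel = outcome_for_diagnosis("lvo_ineligible", t_ms, curves, cfg)
        outcome = branch_vals[other]
        outcome[is_lvo & eligible] = branch_vals[0]
        outcome[is_lvo & ~eligible] = lvo_inel
        cost = np.full(n, ms_cost)
    else:
        branch_vals = np.array([
            0.0,  # placeholder, LVO rows filled below
            outcome_for_diagnosis("nonlvo", t_dsg, curves, cfg),
            outcome_for_diagnosis("ich", t_dsg, curves, cfg),
            outcome_for_diagnosis("mimic", t_dsg, curves, cfg),
        ])
        outcome = branch_vals[other]
        outcome[is_lvo & ~eligible] = outcome_for_diagnosis(
            "lvo_ineligible", t_dsg, curves, cfg)
        outcome[is_lvo & eligible & ~air] = outcome_for_diagnosis(
            "lvo_eligible", t_dsg, curves, cfg)
        outcome[is_lvo & eligible & air] = outcome_for_diagnosis(
            "lvo_eligible", t_dsa, curves, cfg)
        transfers = is_lvo & eligible
        cost = np.full(n, ds_scene_cost)
        cost[transfers & ~air] += tg
        cost[transfers & air] += ta
    out_est = MCEstimate(
        mean=float(outcome.mean()),
        se=float(outcome.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        n=n, seed=seed,
    )
    cost_est = MCEstimate(
        mean=float(cost.mean()),
        se=float(cost.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        n=n, seed=seed,
    )
    return out_est, cost_est


def _arc_radius_km(dtn: float, cfg: ScenarioConfig) -> float | None:
    """Ground radius at which onset-to-needle hits the alteplase window."""
    slack = cfg.tpa_window - (cfg.t_onset_fmc + cfg.t_response + cfg.t_onscene + dtn)
    if slack < 0:
        return None
    return km_from_minutes(slack, cfg.v_ground)


def render(grid: DecisionGrid, out_path: str | Path) -> Tuple[Path, Path]:
    """Write the temporospatial diagram (PNG) and the per-scene table (CSV).

    ``out_path`` is the PNG path; the CSV sits beside it with the same
    stem.  The map shows the four category colours, a circle at the
    alteplase-only facility, a diamond at the EVT-enabled facility,
    concentric 5-min drive-time rings, and dashed white/yellow arcs where
    the alteplase window is exceeded (when they intersect the catchment).
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    csv_path = out_path.with_suffix(".csv")

    df = grid.to_dataframe()
    df.to_csv(csv_path, index=False, float_format="%.10g")

    res = grid.resolution
    xs = df["x_km"].to_numpy()
    ys = df["y_km"].to_numpy()
    x0, x1 = xs.min(), xs.max()
    y0, y1 = ys.min(), ys.max()
    nx = int(round((x1 - x0) / res)) + 1
    ny = int(round((y1 - y0) / res)) + 1
    img = np.ones((ny, nx, 3))
    ix = np.rint((xs - x0) / res).astype(int)
    iy = np.rint((ys - y0) / res).astype(int)
    for k, cat in enumerate(grid.categories):
        img[iy[k], ix[k]] = CATEGORY_COLORS[cat]

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(
        img, origin="lower",
        extent=(x0 - res / 2, x1 + res / 2, y0 - res / 2, y1 + res / 2),
        interpolation="nearest",
    )
    psc, csc = grid.layout.psc_xy, grid.layout.csc_xy
    cfg = grid.cfg
    ring_km = km_from_minutes(5.0, cfg.v_ground)
    max_km = km_from_minutes(grid.layout.catchment_radius_min, cfg.v_ground)
    k = 1
    while k * ring_km <= max_km + 1e-9:
        ax.add_patch(Circle(psc, k * ring_km, fill=False, lw=0.4, ec="0.55"))
        k += 1
    for dtn, color in ((cfg.dtn_psc, "white"), (cfg.dtn_csc, "yellow")):
        center = psc if color == "white" else csc
        r = _arc_radius_km(dtn, cfg)
        if r is not None and r < max_km + math.dist(psc, center):
            ax.add_patch(Circle(center, r, fill=False, lw=1.2, ec=color, ls="--"))
    ax.plot(*psc, marker="o", ms=8, mfc="black", mec="white", zorder=5)
    ax.plot(*csc, marker="D", ms=9, mfc="black", mec="white", zorder=5,
            clip_on=False)
    handles = [
        Patch(fc=CATEGORY_COLORS["red"], label="Drip-and-Ship best (both)"),
        Patch(fc=CATEGORY_COLORS["green"], label="Mothership best (both)"),
        Patch(fc=CATEGORY_COLORS["purple"], label="DS outcome / MS cost"),
        Patch(fc=CATEGORY_COLORS["blue"], label="MS outcome / DS cost"),
    ]
    ax.legend(handles=handles, loc="upper right", fontsize=7, framealpha=0.9)
    ax.set_xlabel("km")
    ax.set_ylabel("km")
    ax.set_title(
        f"PSC–CSC {grid.points[0].d_psc_csc:.0f} km, "
        f"Pr{{Air}} = {grid.probs.p_air:.1%}"
    )
    ax.set_xlim(x0 - res, x1 + res)
    fig.savefig(out_path, dpi=150, metadata={"Software": "dripship"})
    plt.close(fig)
    return out_path, csv_path
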