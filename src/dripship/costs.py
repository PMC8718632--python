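"""Transport-cost model (CAD) for Mothership and Drip-and-Ship.

Every leg has a fixed cost plus a per-km variable cost.  Ground variable
costs are doubled: displacing a ground ambulance over long distances
strains the EMS system beyond fuel and salary, whereas long-distance
displacement is the purpose of the air system, so the air variable cost
is not doubled.  Air ambulances never land on scene, so both the
Mothership trip and the Drip-and-Ship scene leg are ground-only.

The Drip-and-Ship inter-facility transfer is needed only for confirmed
LVO patients who are EVT-eligible (a fraction alpha * Y of
screen-positives); the expected transfer cost averages the ground and
air legs by the transfer probabilities.  Costs are expectations per
screen-positive patient.
"""

from __future__ import annotations

from dataclasses import dataclass

from .air_transfer import TransferProbabilities
from .config import ScenarioConfig
from .geometry import ScenePoint


@dataclass(frozen=True)
class CostBreakdown:
    tc_ms: float               #: Mothership expected cost
    tc_ds: float               #: Drip-and-Ship expected cost
    tc_scene_psc: float        #: scene -> PSC ground leg
    tc_transfer_ground: float  #: PSC -> CSC by ground
    tc_transfer_air: float     #: airbase -> PSC -> CSC by air
    expected_transfer: float   #: probability-weighted transfer cost


def cost_mothership(d_scene_csc: float, cfg: ScenarioConfig) -> float:
    if d_scene_csc < 0:
        raise ValueError("distance must be >= 0")
    return cfg.F_G + 2.0 * cfg.V_G * d_scene_csc


def cost_scene_psc(d_scene_psc: float, cfg: ScenarioConfig) -> float:
    if d_scene_psc < 0:
        raise ValueError("distance must be >= 0")
    return cfg.F_G + 2.0 * cfg.V_G * d_scene_psc


def cost_transfer_ground(d_psc_csc: float, cfg: ScenarioConfig) -> float:
    if d_psc_csc < 0:
        raise ValueError("distance must be >= 0")
    return cfg.F_G_prime + 2.0 * cfg.V_G * d_psc_csc


def cost_transfer_air(d_airbase_psc: float, d_psc_csc: float, cfg: ScenarioConfig) -> float:
    if d_airbase_psc < 0 or d_psc_csc < 0:
        raise ValueError("distances must be >= 0")
    return cfg.F_A + cfg.V_A * (d_airbase_psc + d_psc_csc)


def cost_dripship(
    scene: ScenePoint, probs: TransferProbabilities, cfg: ScenarioConfig
) -> CostBreakdown:
    """Full cost breakdown for a scene, including the Mothership comparator.

    The transfer leg is charged for all alpha * Y patients, including
    those beyond the alteplase window — they still transfer for EVT.
    """
    scene_leg = cost_scene_psc(scene.d_scene_psc, cfg)
    tg = cost_transfer_ground(scene.d_psc_csc, cfg)
    ta = cost_transfer_air(scene.d_airbase_psc, scene.d_psc_csc, cfg)
    expected_transfer = probs.p_ground * tg + probs.p_air * ta
    tc_ds = scene_leg + cfg.alpha * cfg.y * expected_transfer
    return CostBreakdown(
        tc_ms=cost_mothership(scene.d_scene_csc, cfg),
        tc_ds=tc_ds,
        tc_scene_psc=scene_leg,
        tc_transfer_ground=tg,
        tc_transfer_air=ta,
        expected_transfer=expected_transfer,
    )
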