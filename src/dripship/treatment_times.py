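"""Onset-to-needle and onset-to-puncture time chains per strategy.

Three pathways are modelled for a screen-positive patient:

* **Mothership** — scene straight to the EVT-enabled facility (CSC);
  thrombolysis and puncture both happen there.
* **Drip-and-Ship / ground** — scene to the alteplase-only facility (PSC)
  for thrombolysis, then a ground inter-facility transfer (needle-to-
  door-out applies) and puncture at the CSC.
* **Drip-and-Ship / air** — same first leg, but the helicopter alarm is
  raised at thrombolysis time: alarm-to-wheels-up, flight airbase->PSC,
  on-ground time at the PSC, flight PSC->CSC, then puncture.

A needle time is absent (None) when the candidate onset-to-needle time
exceeds the alteplase window; such patients still transfer for EVT with
the same door-out anchor (equivalent door-in-door-out times are assumed
for patients with contraindications).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .config import ScenarioConfig
from .geometry import ScenePoint, minutes_from_km


@dataclass(frozen=True)
class TreatmentTimes:
    """Minutes from symptom onset; ``t_needle`` None means no alteplase."""

    t_needle: Optional[float]
    t_puncture: Optional[float]
    strategy: Literal["MS", "DS"]
    mode: Literal["ground", "air", "n/a"]


def _prehospital_prefix(cfg: ScenarioConfig) -> float:
    return cfg.t_onset_fmc + cfg.t_response + cfg.t_onscene


def mothership_times(scene: ScenePoint, cfg: ScenarioConfig) -> TreatmentTimes:
    arrival_csc = _prehospital_prefix(cfg) + minutes_from_km(scene.d_scene_csc, cfg.v_ground)
    needle = arrival_csc + cfg.dtn_csc
    puncture = arrival_csc + cfg.dtp_csc_direct
    return TreatmentTimes(
        t_needle=needle if needle <= cfg.tpa_window else None,
        t_puncture=puncture,
        strategy="MS",
        mode="n/a",
    )


def _psc_needle_anchor(scene: ScenePoint, cfg: ScenarioConfig) -> float:
    """Clock position of (attempted) thrombolysis at the PSC.

    Used as the door-out anchor even when the patient is beyond the
    alteplase window.
    """
    arrival_psc = _prehospital_prefix(cfg) + minutes_from_km(scene.d_scene_psc, cfg.v_ground)
    return arrival_psc + cfg.dtn_psc


def dripship_ground_times(scene: ScenePoint, cfg: ScenarioConfig) -> TreatmentTimes:
    anchor = _psc_needle_anchor(scene, cfg)
    puncture = (
        anchor
        + cfg.ntdo_psc
        + minutes_from_km(scene.d_psc_csc, cfg.v_ground)
        + cfg.dtp_csc_transfer
    )
    return TreatmentTimes(
        t_needle=anchor if anchor <= cfg.tpa_window else None,
        t_puncture=puncture,
        strategy="DS",
        mode="ground",
    )


def dripship_air_times(scene: ScenePoint, cfg: ScenarioConfig) -> TreatmentTimes:
    anchor = _psc_needle_anchor(scene, cfg)
    puncture = (
        anchor
        + cfg.t_alarm_wheels_up
        + minutes_from_km(scene.d_airbase_psc, cfg.v_air)
        + cfg.t_onground_psc
        + minutes_from_km(scene.d_psc_csc, cfg.v_air)
        + cfg.dtp_csc_transfer
    )
    return TreatmentTimes(
        t_needle=anchor if anchor <= cfg.tpa_window else None,
        t_puncture=puncture,
        strategy="DS",
        mode="air",
    )
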