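"""Probability of inter-facility transfer by rotary-wing air ambulance.

Whether a Drip-and-Ship transfer flies depends on three independent
factors: whether air transport offers a worthwhile time advantage
(a piecewise-linear "consideration" probability in the time advantage
dT), airworthy weather, and helicopter availability.  Their product is
Pr{Air}; a transfer that cannot fly goes by ground, so
Pr{Ground} = 1 - Pr{Air}.

The time advantage dT is the ground inter-facility travel time minus the
full air pathway: alarm-to-wheels-up, flight from airbase to the
alteplase-only facility, time on the ground there, and flight on to the
EVT-enabled facility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .config import ConfigError, FacilityLayout, ScenarioConfig
from .geometry import ScenePoint, minutes_from_km


@dataclass(frozen=True)
class TransferProbabilities:
    delta_t: float          #: time advantage of air transfer (minutes)
    p_consideration: float  #: piecewise-linear consideration probability
    p_air: float            #: Pr{Air} = consideration * weather * availability
    p_ground: float         #: Pr{Ground} = 1 - Pr{Air}


def time_advantage(d_psc_csc: float, d_airbase_psc: float, cfg: ScenarioConfig) -> float:
    """Time advantage (minutes) of an air inter-facility transfer; may be negative."""
    if d_psc_csc < 0 or d_airbase_psc < 0:
        raise ValueError("distances must be >= 0")
    t_ground = minutes_from_km(d_psc_csc, cfg.v_ground)
    t_air_pathway = (
        cfg.t_alarm_wheels_up
        + minutes_from_km(d_airbase_psc, cfg.v_air)
        + cfg.t_onground_psc
        + minutes_from_km(d_psc_csc, cfg.v_air)
    )
    return t_ground - t_air_pathway


def consideration_probability(delta_t: float, dT1: float, dT2: float) -> float:
    """Piecewise-linear probability that air transfer is considered.

    0 at or below ``dT1``, 1 at or above ``dT2``, linear interpolation in
    between; continuous at both knots.
    """
    if not dT1 < dT2:
        raise ConfigError(f"dT1 must be < dT2, got dT1={dT1}, dT2={dT2}")
    if delta_t <= dT1:
        return 0.0
    if delta_t >= dT2:
        return 1.0
    return (delta_t - dT1) / (dT2 - dT1)


def transfer_probabilities(
    scene_or_layout: Union[ScenePoint, FacilityLayout], cfg: ScenarioConfig
) -> TransferProbabilities:
    """Pr{Air} / Pr{Ground} for a layout (constant across its scene grid)."""
    obj = scene_or_layout
    dt = time_advantage(obj.d_psc_csc, obj.d_airbase_psc, cfg)
    p_cons = consideration_probability(dt, cfg.dT1, cfg.dT2)
    p_air = p_cons * cfg.p_weather * cfg.p_avail
    return TransferProbabilities(
        delta_t=dt, p_consideration=p_cons, p_air=p_air, p_ground=1.0 - p_air
    )
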