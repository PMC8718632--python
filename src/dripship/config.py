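"""Scenario constants and facility layout.

All model inputs live in two frozen dataclasses: :class:`ScenarioConfig`
(times, speeds, costs, probabilities, diagnosis mixture, outcome-curve
parameters) and :class:`FacilityLayout` (planar positions of the
alteplase-only facility, the EVT-enabled facility and the helicopter
airbase).  Defaults reproduce the base-case parameterization of the model:
an inefficient alteplase-only facility (door-to-needle and
needle-to-door-out of 60 min each) and 50% EVT eligibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Tuple


class ConfigError(ValueError):
    """A scenario configuration violates a model invariant."""


@dataclass(frozen=True)
class OutcomeParams:
    """Parameters of the outcome curves (90-day mRS 0-1 probability).

    Treatment-responsive diagnoses use logistic decay in time,
    ``P(t) = 1 / (1 + exp(-(beta0 + beta1 * t)))`` with ``beta1 < 0`` so
    that the probability of an excellent outcome falls as treatment is
    delayed.  Times are minutes from symptom onset.  Transport-invariant
    diagnoses (intracerebral haemorrhage, stroke mimic) and untreated
    patients get constants.
    """

    lvo_evt_beta0: float = 0.35
    lvo_evt_beta1: float = -0.0035
    lvo_tpa_beta0: float = -0.10
    lvo_tpa_beta1: float = -0.006
    p_lvo_untreated: float = 0.10
    nonlvo_tpa_beta0: float = 1.2
    nonlvo_tpa_beta1: float = -0.0045
    p_nonlvo_untreated: float = 0.40
    p_ich: float = 0.15
    p_mimic: float = 0.90
    #: how alteplase and EVT outcomes merge for a treated LVO patient:
    #: "evt_dominates" (EVT outcome supersedes) or "max".
    combine_rule: str = "evt_dominates"
    #: optional hard onset-to-puncture cutoff (minutes) beyond which EVT
    #: is not performed; None means benefit decays via the curve only.
    evt_time_cutoff: float | None = None

    def validate(self) -> list[str]:
        errors = []
        for name in ("lvo_evt_beta1", "lvo_tpa_beta1", "nonlvo_tpa_beta1"):
            if getattr(self, name) > 0:
                errors.append(f"outcome_params.{name} must be <= 0 (non-increasing curves)")
        for name in ("p_lvo_untreated", "p_nonlvo_untreated", "p_ich", "p_mimic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"outcome_params.{name} must be in [0, 1], got {v}")
        if self.combine_rule not in ("evt_dominates", "max"):
            errors.append(
                f"outcome_params.combine_rule must be 'evt_dominates' or 'max', got {self.combine_rule!r}"
            )
        if self.evt_time_cutoff is not None and self.evt_time_cutoff < 0:
            errors.append("outcome_params.evt_time_cutoff must be >= 0 or None")
        return errors


@dataclass(frozen=True)
class ScenarioConfig:
    """All scalar constants of the transport model.

    Times are minutes, speeds km/h, costs CAD, distances km.
    """

    # prehospital time chain
    t_onset_fmc: float = 30.0      #: symptom onset to first medical contact
    t_response: float = 15.0       #: ambulance response time
    t_onscene: float = 15.0        #: on-scene time

    # facility process times
    dtn_psc: float = 60.0          #: door-to-needle at the alteplase-only facility
    ntdo_psc: float = 60.0         #: needle-to-door-out (ground transfers only)
    dtn_csc: float = 30.0          #: door-to-needle at the EVT-enabled facility
    dtp_csc_direct: float = 90.0   #: door-to-puncture for direct (Mothership) arrivals
    dtp_csc_transfer: float = 30.0 #: door-to-puncture for transferred arrivals

    # rotary-wing logistics
    t_alarm_wheels_up: float = 15.0
    t_onground_psc: float = 20.0

    # speeds
    v_ground: float = 80.0
    v_air: float = 254.0

    # air-transfer probability model
    p_weather: float = 0.904       #: probability of airworthy weather
    p_avail: float = 0.965         #: probability of air resource availability
    dT1: float = 10.0              #: minimum time advantage to consider air
    dT2: float = 40.0              #: time advantage at which air is always considered

    # transport costs
    F_G: float = 500.0             #: fixed cost, ground transport from scene
    F_G_prime: float = 400.0       #: fixed cost, inter-facility ground transfer
    F_A: float = 2500.0            #: fixed cost, air transport
    V_G: float = 5.0               #: variable ground cost per km
    V_A: float = 12.0              #: variable air cost per km

    # patient population
    alpha: float = 0.4538          #: proportion of LVO among screen-positives
    y: float = 0.5                 #: proportion of LVO patients eligible for EVT
    #: final-diagnosis mixture among screen-positives:
    #: (LVO, non-LVO ischemic, intracerebral haemorrhage, stroke mimic)
    mix: Tuple[float, float, float, float] = (0.4538, 0.1092, 0.3445, 0.0924)

    tpa_window: float = 270.0      #: alteplase onset-to-needle limit (4.5 h)

    outcome_params: OutcomeParams = field(default_factory=OutcomeParams)

    def __post_init__(self) -> None:
        errors = self._validation_errors()
        if errors:
            raise ConfigError("invalid scenario configuration: " + "; ".join(errors))

    def _validation_errors(self) -> list[str]:
        errors = []
        nonneg_times = (
            "t_onset_fmc", "t_response", "t_onscene", "dtn_psc", "ntdo_psc",
            "dtn_csc", "dtp_csc_direct", "dtp_csc_transfer",
            "t_alarm_wheels_up", "t_onground_psc", "tpa_window",
        )
        for name in nonneg_times:
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("v_ground", "v_air"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("F_G", "F_G_prime", "F_A", "V_G", "V_A"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("p_weather", "p_avail", "alpha", "y"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name} must be in [0, 1], got {v}")
        if not self.dT1 < self.dT2:
            errors.append(f"dT1 must be < dT2, got dT1={self.dT1}, dT2={self.dT2}")
        if len(self.mix) != 4:
            errors.append(f"mix must have 4 proportions, got {len(self.mix)}")
        else:
            if any(not 0.0 <= w <= 1.0 for w in self.mix):
                errors.append(f"mix proportions must be in [0, 1], got {self.mix}")
            elif not math.isclose(sum(self.mix), 1.0, abs_tol=1e-3):
                errors.append(f"mix must sum to 1 within 1e-3, got sum={sum(self.mix)}")
        errors.extend(self.outcome_params.validate())
        return errors

    @property
    def mix_normalized(self) -> Tuple[float, float, float, float]:
        """Diagnosis mixture renormalized to sum exactly to 1.

        The commonly used printed proportions total 99.99%; expectation
        formulas use the renormalized weights.
        """
        total = sum(self.mix)
        return tuple(w / total for w in self.mix)  # type: ignore[return-value]

    def with_updates(self, **kwargs) -> "ScenarioConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FacilityLayout:
    """Planar (km) positions of the facilities and the airbase.

    By default the EVT-enabled facility (CSC) is placed due south of the
    alteplase-only facility (PSC) and the airbase is co-located with the
    CSC.  The catchment is the disc of scene locations within
    ``catchment_radius_min`` minutes of ground driving from the PSC.
    """

    psc_xy: Tuple[float, float] = (0.0, 0.0)
    csc_xy: Tuple[float, float] = (0.0, -240.0)
    airbase_xy: Tuple[float, float] | None = None  #: None => co-located with CSC
    catchment_radius_min: float = 60.0

    def __post_init__(self) -> None:
        if self.psc_xy == self.csc_xy:
            raise ConfigError("psc_xy and csc_xy must differ")
        if self.catchment_radius_min <= 0:
            raise ConfigError(
                f"catchment_radius_min must be > 0, got {self.catchment_radius_min}"
            )
        if self.airbase_xy is None:
            object.__setattr__(self, "airbase_xy", self.csc_xy)

    @property
    def d_psc_csc(self) -> float:
        return math.dist(self.psc_xy, self.csc_xy)

    @property
    def d_airbase_psc(self) -> float:
        return math.dist(self.airbase_xy, self.psc_xy)

    @staticmethod
    def from_separation_km(d_psc_csc: float, catchment_radius_min: float = 60.0,
                           airbase_at_csc: bool = True) -> "FacilityLayout":
        """Layout with the PSC at the origin and the CSC ``d_psc_csc`` km due south."""
        csc = (0.0, -float(d_psc_csc))
        return FacilityLayout(
            psc_xy=(0.0, 0.0),
            csc_xy=csc,
            airbase_xy=csc if airbase_at_csc else None,
            catchment_radius_min=catchment_radius_min,
        )
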