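"""Expected probability of an excellent outcome (90-day mRS 0-1).

A patient who screens positive in the field for a large-vessel occlusion
may in fact have an LVO ischemic stroke, a non-LVO ischemic stroke, an
intracerebral haemorrhage, or a stroke mimic.  The expected outcome of a
transport strategy is a mixture over these final diagnoses, with LVO
patients split further into EVT-eligible and EVT-ineligible fractions.
For Drip-and-Ship the EVT-eligible term is additionally a mixture over
the transfer mode (ground vs. air), weighted by the transfer
probabilities.

Treatment benefit decays with time via configurable logistic curves; the
exact decay coefficients of the upstream conditional-probability
outcome model are not reproduced here, so the shipped coefficients are
documented package defaults, overridable through
``ScenarioConfig.outcome_params``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .air_transfer import transfer_probabilities
from .config import OutcomeParams, ScenarioConfig
from .geometry import ScenePoint
from .treatment_times import (
    TreatmentTimes,
    dripship_air_times,
    dripship_ground_times,
    mothership_times,
)

DIAGNOSES = ("lvo_eligible", "lvo_ineligible", "nonlvo", "ich", "mimic")


def _logistic(beta0: float, beta1: float, t: float) -> float:
    return 1.0 / (1.0 + math.exp(-(beta0 + beta1 * t)))


@dataclass(frozen=True)
class OutcomeCurves:
    """Callable outcome curves built from an :class:`OutcomeParams` block."""

    params: OutcomeParams

    def p_lvo_evt(self, t_puncture: float) -> float:
        return _logistic(self.params.lvo_evt_beta0, self.params.lvo_evt_beta1, t_puncture)

    def p_lvo_tpa(self, t_needle: float) -> float:
        return _logistic(self.params.lvo_tpa_beta0, self.params.lvo_tpa_beta1, t_needle)

    def p_nonlvo_tpa(self, t_needle: float) -> float:
        return _logistic(self.params.nonlvo_tpa_beta0, self.params.nonlvo_tpa_beta1, t_needle)

    @property
    def p_lvo_untreated(self) -> float:
        return self.params.p_lvo_untreated

    @property
    def p_nonlvo_untreated(self) -> float:
        return self.params.p_nonlvo_untreated

    @property
    def p_ich(self) -> float:
        return self.params.p_ich

    @property
    def p_mimic(self) -> float:
        return self.params.p_mimic


@dataclass(frozen=True)
class OutcomePair:
    """Expected excellent-outcome probability under each strategy."""

    p_ms: float
    p_ds: float


def curves_for(cfg: ScenarioConfig) -> OutcomeCurves:
    return OutcomeCurves(cfg.outcome_params)


def outcome_for_diagnosis(
    diagnosis: str,
    times: TreatmentTimes,
    curves: OutcomeCurves,
    cfg: ScenarioConfig,
) -> float:
    """Excellent-outcome probability for one final diagnosis and time chain."""
    p = curves.params
    if diagnosis == "ich":
        return curves.p_ich
    if diagnosis == "mimic":
        return curves.p_mimic
    if diagnosis == "nonlvo":
        if times.t_needle is not None:
            return curves.p_nonlvo_tpa(times.t_needle)
        return curves.p_nonlvo_untreated
    if diagnosis == "lvo_ineligible":
        if times.t_needle is not None:
            return curves.p_lvo_tpa(times.t_needle)
        return curves.p_lvo_untreated
    if diagnosis == "lvo_eligible":
        evt_done = times.t_puncture is not None and (
            p.evt_time_cutoff is None or times.t_puncture <= p.evt_time_cutoff
        )
        p_no_evt = (
            curves.p_lvo_tpa(times.t_needle)
            if times.t_needle is not None
            else curves.p_lvo_untreated
        )
        if not evt_done:
            return p_no_evt
        p_evt = curves.p_lvo_evt(times.t_puncture)
        if p.combine_rule == "max":
            return max(p_evt, p_no_evt)
        return p_evt  # evt_dominates
    raise ValueError(f"unknown diagnosis {diagnosis!r}")


def _mixture_weights(cfg: ScenarioConfig) -> dict[str, float]:
    w_lvo, w_nonlvo, w_ich, w_mimic = cfg.mix_normalized
    return {
        "lvo_eligible": w_lvo * cfg.y,
        "lvo_ineligible": w_lvo * (1.0 - cfg.y),
        "nonlvo": w_nonlvo,
        "ich": w_ich,
        "mimic": w_mimic,
    }


def _mixture_expectation(times_by_diag: dict[str, TreatmentTimes],
                         curves: OutcomeCurves, cfg: ScenarioConfig) -> float:
    weights = _mixture_weights(cfg)
    return sum(
        w * outcome_for_diagnosis(d, times_by_diag[d], curves, cfg)
        for d, w in weights.items()
    )


def expected_outcome_mothership(scene: ScenePoint, cfg: ScenarioConfig) -> float:
    """Diagnosis-mixture expected outcome when transported direct to the CSC."""
    curves = curves_for(cfg)
    t_ms = mothership_times(scene, cfg)
    return _mixture_expectation({d: t_ms for d in DIAGNOSES}, curves, cfg)


def expected_outcome_dripship(scene: ScenePoint, cfg: ScenarioConfig) -> float:
    """Expected outcome for Drip-and-Ship, averaged over the transfer mode.

    Only EVT-eligible LVO patients transfer; every other diagnosis is
    treated (or not) at the alteplase-only facility, so their outcome is
    mode-invariant and depends on the PSC needle time alone.
    """
    curves = curves_for(cfg)
    probs = transfer_probabilities(scene, cfg)
    t_ground = dripship_ground_times(scene, cfg)
    t_air = dripship_air_times(scene, cfg)

    def expectation(times_transfer: TreatmentTimes) -> float:
        times = {d: t_ground for d in DIAGNOSES}
        times["lvo_eligible"] = times_transfer
        return _mixture_expectation(times, curves, cfg)

    return probs.p_ground * expectation(t_ground) + probs.p_air * expectation(t_air)


def outcome_pair(scene: ScenePoint, cfg: ScenarioConfig) -> OutcomePair:
    return OutcomePair(
        p_ms=expected_outcome_mothership(scene, cfg),
        p_ds=expected_outcome_dripship(scene, cfg),
    )
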