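import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dripship import (
    FacilityLayout,
    ScenarioConfig,
    dripship_ground_times,
    expected_outcome_dripship,
    expected_outcome_mothership,
    mothership_times,
    outcome_for_diagnosis,
    scene_from_xy,
)
from dripship.config import OutcomeParams
from dripship.outcomes import curves_for

from conftest import constant_outcome_params


def test_ich_and_mimic_transport_invariant(cfg, layout_240):
    curves = curves_for(cfg)
    near = mothership_times(scene_from_xy(*layout_240.csc_xy, layout_240), cfg)
    far = dripship_ground_times(scene_from_xy(70.0, 0.0, layout_240), cfg)
    for diag, const in (("ich", cfg.outcome_params.p_ich),
                        ("mimic", cfg.outcome_params.p_mimic)):
        assert outcome_for_diagnosis(diag, near, curves, cfg) == const
        assert outcome_for_diagnosis(diag, far, curves, cfg) == const


def test_untreated_constants_when_needle_absent(cfg, layout_240):
    curves = curves_for(cfg)
    small = cfg.with_updates(tpa_window=10.0)
    times = dripship_ground_times(scene_from_xy(0.0, 0.0, layout_240), small)
    assert times.t_needle is None
    assert outcome_for_diagnosis("lvo_ineligible", times, curves, small) == \
        cfg.outcome_params.p_lvo_untreated
    assert outcome_for_diagnosis("nonlvo", times, curves, small) == \
        cfg.outcome_params.p_nonlvo_untreated


def test_unknown_diagnosis_errors(cfg, layout_240):
    times = mothership_times(scene_from_xy(0.0, 0.0, layout_240), cfg)
    with pytest.raises(ValueError):
        outcome_for_diagnosis("tia", times, curves_for(cfg), cfg)


def test_evt_dominates_with_degenerate_curves(cfg, layout_240):
    """With a time-constant EVT curve at 0.4, any eligible-LVO time chain
    yields 0.4 under the evt-dominates rule."""
    params = OutcomeParams(lvo_evt_beta0=-0.4054651081, lvo_evt_beta1=0.0)
    cfg2 = cfg.with_updates(outcome_params=params)
    curves = curves_for(cfg2)
    for scene_xy in ((0.0, 0.0), (50.0, -30.0)):
        times = dripship_ground_times(scene_from_xy(*scene_xy, layout_240), cfg2)
        assert outcome_for_diagnosis("lvo_eligible", times, curves, cfg2) == \
            pytest.approx(0.4, abs=1e-9)


def test_constant_mixture_collapses(cfg, layout_240):
    c = 0.37
    cfg2 = cfg.with_updates(outcome_params=constant_outcome_params(c))
    scene = scene_from_xy(33.0, -21.0, layout_240)
    assert expected_outcome_mothership(scene, cfg2) == pytest.approx(c)
    assert expected_outcome_dripship(scene, cfg2) == pytest.approx(c)


def test_pure_lvo_eligible_mixture(cfg, layout_240):
    params = OutcomeParams(lvo_evt_beta0=0.4054651081, lvo_evt_beta1=0.0)
    cfg2 = cfg.with_updates(mix=(1.0, 0.0, 0.0, 0.0), y=1.0, outcome_params=params)
    scene = scene_from_xy(5.0, 5.0, layout_240)
    assert expected_outcome_mothership(scene, cfg2) == pytest.approx(0.6, abs=1e-9)
    assert expected_outcome_dripship(scene, cfg2) == pytest.approx(0.6, abs=1e-9)


def test_dripship_degenerate_transfer_modes(cfg, layout_240):
    scene = scene_from_xy(12.0, -18.0, layout_240)
    ground_only = cfg.with_updates(p_weather=0.0)  # Pr{Air} = 0
    air_always = cfg.with_updates(dT1=-2e6, dT2=-1e6, p_weather=1.0, p_avail=1.0)
    p_g = expected_outcome_dripship(scene, ground_only)
    p_a = expected_outcome_dripship(scene, air_always)
    # air reaches puncture sooner here (dT + NTDO > 0), so strictly better
    assert p_a > p_g
    # with time-constant curves DS expectation is distance-invariant
    cfg_const = cfg.with_updates(outcome_params=constant_outcome_params(0.5))
    for xy in ((0.0, 0.0), (60.0, 40.0)):
        assert expected_outcome_dripship(scene_from_xy(*xy, layout_240), cfg_const) == \
            pytest.approx(0.5)


@given(shift=st.floats(0.0, 120.0))
@settings(derandomize=True, max_examples=40)
def test_expectations_bounded_and_monotone_under_time_shift(shift):
    """Delaying first medical contact can never improve either strategy."""
    cfg = ScenarioConfig()
    layout = FacilityLayout.from_separation_km(240.0)
    scene = scene_from_xy(25.0, -10.0, layout)
    base_ms = expected_outcome_mothership(scene, cfg)
    base_ds = expected_outcome_dripship(scene, cfg)
    late = cfg.with_updates(t_onset_fmc=cfg.t_onset_fmc + shift)
    for p in (base_ms, base_ds):
        assert 0.0 <= p <= 1.0
    assert expected_outcome_mothership(scene, late) <= base_ms + 1e-12
    assert expected_outcome_dripship(scene, late) <= base_ds + 1e-12


@given(y1=st.floats(0.0, 1.0), y2=st.floats(0.0, 1.0))
@settings(derandomize=True, max_examples=40)
def test_higher_eligibility_helps_when_evt_dominates(y1, y2):
    """If p_lvo_evt >= p_lvo_tpa pointwise, raising Y never lowers the
    expectation (holding times fixed)."""
    lo, hi = sorted((y1, y2))
    params = OutcomeParams(
        lvo_evt_beta0=0.5, lvo_evt_beta1=-0.001,
        lvo_tpa_beta0=-0.5, lvo_tpa_beta1=-0.001,
    )
    layout = FacilityLayout.from_separation_km(240.0)
    scene = scene_from_xy(10.0, -5.0, layout)
    p_lo = expected_outcome_mothership(scene, ScenarioConfig(y=lo, outcome_params=params))
    p_hi = expected_outcome_mothership(scene, ScenarioConfig(y=hi, outcome_params=params))
    assert p_hi >= p_lo - 1e-12


def test_strategies_coincide_for_colocated_equal_facilities():
    """With the CSC (and airbase) essentially at the PSC and facility
    constants arranged so both pathways share one clock, MS equals DS."""
    cfg = ScenarioConfig(
        dtn_psc=30.0, dtn_csc=30.0, ntdo_psc=0.0,
        dtp_csc_direct=60.0, dtp_csc_transfer=30.0,  # 30 + 0 + 30 = 60
    )
    layout = FacilityLayout(psc_xy=(0.0, 0.0), csc_xy=(0.0, -1e-9))
    for xy in ((0.0, 0.0), (30.0, 20.0), (-50.0, 10.0)):
        scene = scene_from_xy(*xy, layout)
        assert expected_outcome_mothership(scene, cfg) == pytest.approx(
            expected_outcome_dripship(scene, cfg), abs=1e-9
        )
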