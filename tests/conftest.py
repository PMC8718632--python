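import math

import pytest

from dripship import FacilityLayout, ScenarioConfig, km_from_minutes
from dripship.config import OutcomeParams


@pytest.fixture
def cfg():
    """Base-case configuration: inefficient PSC, 50% EVT eligibility."""
    return ScenarioConfig()


@pytest.fixture
def cfg_efficient(cfg):
    return cfg.with_updates(dtn_psc=30.0, ntdo_psc=20.0)


@pytest.fixture
def layout_240():
    """PSC at origin, CSC 240 km due south (180 min by ground), airbase at CSC."""
    return FacilityLayout.from_separation_km(240.0)


def layout_for_separation_min(sep_min, cfg, **kwargs):
    return FacilityLayout.from_separation_km(
        km_from_minutes(sep_min, cfg.v_ground), **kwargs
    )


def constant_outcome_params(c):
    """Outcome parameters with every curve and constant identically ``c``."""
    b0 = math.log(c / (1.0 - c))
    return OutcomeParams(
        lvo_evt_beta0=b0, lvo_evt_beta1=0.0,
        lvo_tpa_beta0=b0, lvo_tpa_beta1=0.0,
        p_lvo_untreated=c,
        nonlvo_tpa_beta0=b0, nonlvo_tpa_beta1=0.0,
        p_nonlvo_untreated=c,
        p_ich=c, p_mimic=c,
    )
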