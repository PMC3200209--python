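import numpy as np
import pandas as pd
import pytest

from pcilos import registry


def make_record(**overrides):
    """A reference-level elective record; override any field."""
    rec = {
        "age": 50.0,
        "sex": "male",
        "heart_failure": "none",
        "nyha_class_3_4": 0,
        "creatinine_gt_2_5": 0,
        "dialysis": 0,
        "ejection_fraction": 55.0,
        "mi_timing": "none",
        "peripheral_arterial_disease": 0,
        "left_main_disease": 0,
        "multivessel_disease": 0,
        "angiographic_thrombus": 0,
        "hemodynamic_state": "stable",
        "urgent_emergent": 0,
        "provider_id": 0,
        "los_days": 3,
        "complication": 0,
    }
    rec.update(overrides)
    return rec


def make_cohort(records):
    return pd.DataFrame(records)


@pytest.fixture(scope="session")
def small_cohort():
    """A 20,000-record default-config cohort shared across tests."""
    return registry.generate_cohort(registry.GeneratorConfig(n=20_000, seed=20_000))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
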