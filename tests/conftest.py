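import numpy as np
import pandas as pd
import pytest

from husphen import CohortConfig, WaveformSpec
from husphen.synthetic import generate_cohort, generate_waveform


@pytest.fixture()
def default_config() -> CohortConfig:
    return CohortConfig(seed=0)


@pytest.fixture()
def small_cohort() -> pd.DataFrame:
    """A compact cohort (imaging timepoints only) for statistics tests."""
    cfg = CohortConfig(seed=7, ages_weeks=(8, 16, 24), attrition_prob=0.0)
    return generate_cohort(cfg)


@pytest.fixture()
def clean_trace():
    return generate_waveform(WaveformSpec())


def mouse_records(bw_by_week: dict[int, float], intake_daily: float = 3.0,
                  kcal_per_g: float = 3.150, **extra) -> pd.DataFrame:
    """Minimal per-mouse longitudinal record table for metabolic tests."""
    rows = []
    for age, bw in bw_by_week.items():
        rows.append({"mouse_id": "m1", "age_weeks": age, "bw": bw,
                     "food_intake_daily": intake_daily,
                     "kcal_per_g": kcal_per_g, "fasting": False,
                     "glucose": np.nan, "insulin": np.nan,
                     "liver_weight": np.nan} | extra)
    return pd.DataFrame(rows)
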