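import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

sys.path.insert(0, str(Path(__file__).parent))

from motivmeta.simulate import SimConfig, simulate_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """One 27-study corpus (19/5/3 by level) shared across pipeline tests."""
    config = SimConfig(seed=7)
    studies, ratings, manifest = simulate_corpus(config)
    return studies, ratings, manifest, config


@pytest.fixture
def hand_studies():
    """Tiny hand-written studies table exercising the selection rules."""
    rows = [
        # two measurement tools for qol; tool B has lower attrition
        dict(study_id="T1", outcome="qol", arm="intervention", n=30, mean=5.0, sd=2.0,
             measure_name="toolA", attrition_fraction=0.2, timepoint_label="w8",
             post_intervention_order=1, followup_weeks=8.0),
        dict(study_id="T1", outcome="qol", arm="control", n=30, mean=4.0, sd=2.0,
             measure_name="toolA", attrition_fraction=0.2, timepoint_label="w8",
             post_intervention_order=1, followup_weeks=8.0),
        dict(study_id="T1", outcome="qol", arm="intervention", n=30, mean=6.0, sd=2.0,
             measure_name="toolB", attrition_fraction=0.1, timepoint_label="w8",
             post_intervention_order=1, followup_weeks=8.0),
        dict(study_id="T1", outcome="qol", arm="control", n=30, mean=4.0, sd=2.0,
             measure_name="toolB", attrition_fraction=0.1, timepoint_label="w8",
             post_intervention_order=1, followup_weeks=8.0),
    ]
    df = pd.DataFrame(rows)
    for col in ("se", "ci_low", "ci_high", "baseline_sd", "events"):
        df[col] = np.nan
    return df
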