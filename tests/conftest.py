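import numpy as np
import pandas as pd
import pytest

from pulseqc.features import FEATURE_COLUMNS, build_feature_table
from pulseqc.synth import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def mini_config():
    return SimulationConfig(n_subjects=6, duration=30.0, seed=7)


@pytest.fixture(scope="session")
def mini_cohort(mini_config):
    return generate_cohort(mini_config)


@pytest.fixture(scope="session")
def mini_features(mini_cohort):
    return build_feature_table(mini_cohort)


@pytest.fixture(scope="session")
def clean_mini_cohort():
    """Small artifact-free cohort (jitter only)."""
    config = SimulationConfig(
        n_subjects=6, duration=30.0, seed=19, clean_fraction_appropriate=1.0, lowq_fraction_higher=0.0
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def blob_features():
    """Linearly separable two-blob feature table: 8 subjects, 2 recordings each."""
    rng = np.random.default_rng(42)
    rows = []
    for s in range(8):
        subject = f"b{s + 1:02d}"
        for regime, label, center in (("appropriate", "high", 3.0), ("higher", "low", -3.0)):
            for beat in range(15):
                feats = center + rng.standard_normal(len(FEATURE_COLUMNS))
                rows.append([subject, regime, beat, label, *feats])
    return pd.DataFrame(rows, columns=["subject", "regime", "beat_index", "label"] + FEATURE_COLUMNS)
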