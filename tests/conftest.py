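import numpy as np
import pandas as pd
import pytest

from trajsmm.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def noise_free_cohort():
    """90 subjects, 3 well-separated classes, zero noise: every trajectory
    equals its class mean curve exactly."""
    cfg = CohortConfig(
        n_subjects=90, random_intercept_sd=0.0, residual_sd=0.0, seed=5
    )
    long, labels = generate_cohort(cfg)
    return cfg, long, labels


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default study-scale scenario: n=877, intercept SD 2 kg, residual SD
    1 kg, class baselines ~8.5 kg apart."""
    cfg = CohortConfig(seed=0)
    long, labels = generate_cohort(cfg)
    return cfg, long, labels


@pytest.fixture()
def tiny_long():
    """Six balanced subjects whose mean weights are 61,62,63,71,72,73."""
    rows = []
    for sid, base in enumerate([61, 62, 63, 71, 72, 73], start=1):
        for month in range(1, 10):
            rows.append({"subject_id": sid, "month": month, "weight_kg": float(base)})
    return pd.DataFrame(rows)
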