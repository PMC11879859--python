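import numpy as np
import pandas as pd
import pytest

from bsetrial import simulate
from bsetrial.datamodel import TrialDataset


def make_trial_frame(n_bse=30, n_pla=30, effect=0.0, placebo_drift=0.0,
                     change_sd=0.63, seed=0, completed_all=True):
    """Minimal valid trial table with a uniform treatment effect."""
    rng = np.random.default_rng(seed)
    n = n_bse + n_pla
    arm = np.array(["BSE"] * n_bse + ["placebo"] * n_pla)
    baseline = rng.normal(6.4, 0.2, n)
    improvement = placebo_drift + np.where(arm == "BSE", effect, 0.0) \
        + rng.normal(0, change_sd, n)
    df = pd.DataFrame({
        "participant_id": [f"P{i:04d}" for i in range(n)],
        "arm": arm,
        "completed": completed_all,
        "baseline_glucose": baseline,
        "week12_glucose": baseline - improvement,
        "baseline_bmi": rng.normal(32.0, 3.8, n),
        "baseline_insulin": rng.normal(19.0, 4.0, n).clip(1.0),
        "week12_insulin": rng.normal(19.0, 4.0, n).clip(1.0),
    })
    return df


@pytest.fixture
def small_trial():
    return TrialDataset(table=make_trial_frame(seed=42))


@pytest.fixture(scope="session")
def trial_preset():
    return simulate.load_preset("trial_table1")


@pytest.fixture(scope="session")
def medium_cohort(trial_preset):
    """10k-per-arm cohort reused by tests that only need moderate precision."""
    return simulate.generate_trial_cohort(trial_preset, seed=101,
                                          n_per_arm=(10_000, 10_000))
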