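import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import microdyn as md
from microdyn.containers import FeatureTable

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cohort():
    """20 participants, 10 per arm."""
    return md.generate_cohort(10, seed=123)


@pytest.fixture(scope="session")
def big_cohort():
    return md.generate_cohort(50, seed=321)


@pytest.fixture(scope="session")
def small_panel():
    return md.PanelSpec(
        n_gut_species=20,
        n_oral_species=10,
        n_gut_pathways=10,
        n_oral_pathways=10,
        n_metabolites=20,
        n_cytokines=5,
        missingness_rate=0.05,
        batch_count=2,
        batch_shift=0.0,
    )


@pytest.fixture(scope="session")
def small_table(cohort, small_panel):
    table, truth = md.generate_paired_features(
        cohort, small_panel, md.EffectSpec(fraction_affected=0.2), seed=7
    )
    return table, truth


def make_table(values: np.ndarray, timepoints=None, participants=None, **meta_cols):
    """Small hand-built FeatureTable for unit tests."""
    n, m = values.shape
    if participants is None:
        participants = [f"P{i // 2:03d}" for i in range(n)]
    if timepoints is None:
        timepoints = ["pre" if i % 2 == 0 else "post" for i in range(n)]
    sample_ids = [f"{p}-{t}" for p, t in zip(participants, timepoints)]
    meta = pd.DataFrame(
        {"participant_id": participants, "timepoint": timepoints, **meta_cols},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    vals = pd.DataFrame(
        values, index=meta.index, columns=[f"f{j}" for j in range(m)]
    )
    return FeatureTable(vals, meta)
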