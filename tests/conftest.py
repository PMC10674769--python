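"""Shared fixtures.

The expensive session fixtures (default 30-subject cohort and its
trained classifier) are computed once and shared by the acceptance
tests; unit tests use small bespoke inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from armfatigue.features import canonical_feature_names
from armfatigue.pipeline import cohort_feature_table, run_classification
from armfatigue.synthetic_cohort import (SyntheticParams, generate_cohort,
                                         generate_trial)

COHORT_SEED = 11


@pytest.fixture(scope="session")
def default_params() -> SyntheticParams:
    return SyntheticParams()


@pytest.fixture(scope="session")
def small_trial(default_params):
    """One default-conditions trial, reused read-only across tests."""
    return generate_trial(default_params, "S01", 42)


@pytest.fixture(scope="session")
def default_cohort(default_params):
    trials, manifest = generate_cohort(default_params, seed=COHORT_SEED)
    return trials, manifest


@pytest.fixture(scope="session")
def cohort_table(default_cohort) -> pd.DataFrame:
    trials, _ = default_cohort
    return cohort_feature_table(trials)


@pytest.fixture(scope="session")
def classification_result(cohort_table) -> dict:
    return run_classification(cohort_table, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def fake_feature_table() -> pd.DataFrame:
    """Cheap 30-subject table with all 63 columns and a learnable signal.

    Three informative columns encode the state; the rest are noise.
    Used by modeling tests that need structure, not realism.
    """
    rng = np.random.default_rng(0)
    names = canonical_feature_names()
    rows = []
    for s in range(30):
        sid = f"S{s + 1:02d}"
        n_cycles = 40
        for c in range(n_cycles):
            u = c / (n_cycles - 1)
            state = "LF" if u < 0.4 else ("MOF" if u < 0.65 else "HF")
            feats = dict(zip(names, rng.normal(0, 1, len(names))))
            feats["EMG_mean"] = 1 + 2 * u + rng.normal(0, 0.1)
            feats["FIB_tnorm"] = 1 + 0.5 * u + rng.normal(0, 0.05)
            feats["EMG_IMNF"] = 90 - 25 * u + rng.normal(0, 1)
            rows.append({"subject_id": sid, "cycle": c,
                         "borg": 10 * u, "state": state, **feats})
    return pd.DataFrame(rows)
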