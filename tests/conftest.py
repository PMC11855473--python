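"""Shared fixtures: small deterministic cohorts and fixed seeds.

All randomness is seeded; the suite is reproducible run to run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import rcmr

settings.register_profile("ci", settings(max_examples=50, derandomize=True, deadline=None))
settings.load_profile("ci")

#: global seed for the stochastic harness tests, fixed once for the suite.
SUITE_SEED = 20260928


@pytest.fixture()
def rng():
    # function-scoped so draws are independent of test execution order
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture(scope="session")
def small_cohort():
    """Forward-causal cohort small enough for per-test fits."""
    cfg = rcmr.scenario("forward-causal", n=3000, seed=11, n_variants=12)
    return rcmr.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    cfg = rcmr.scenario("null", n=3000, seed=7, n_variants=12)
    return rcmr.simulate_cohort(cfg)


@pytest.fixture()
def tiny_table():
    """8-row phenotype table with hand-checkable numbers."""
    return pd.DataFrame(
        {
            "y": [1.2, 0.7, 2.3, 1.9, 0.4, 3.1, 2.2, 1.5],
            "g": [0, 1, 2, 1, 0, 2, 1, 0],
            "age": [34.0, 51.0, 47.0, 62.0, 39.0, 55.0, 44.0, 60.0],
            "sex": [0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0],
        }
    )
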