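"""Shared fixtures: a small synthetic stimulus set and derived tables.

Statistical suites run on a scaled-down experiment (40 stimuli, schedule
40/12/10/8/6/5 with 4-item neighbourhoods, ~60 voxels) so the whole test
run stays fast; the full-size constants are asserted separately against
the configuration defaults.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nnsearch import synthetic_data as sd

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Scaled session layout used across the statistical tests.
SCALED_SCHEDULE = (40, 12, 10, 8, 6, 5)
SCALED_NN = 4


@pytest.fixture(scope="session")
def stim_small():
    return sd.generate_stimulus_set(n_categories=20, per_category=2, seed=7)


@pytest.fixture(scope="session")
def table_z(stim_small):
    return stim_small.feature_table(standardized=True)


@pytest.fixture(scope="session")
def ref_features(stim_small, table_z):
    return stim_small.referent_features(table_z)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
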