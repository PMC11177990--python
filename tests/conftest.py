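"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from gdmkin import PipelineConfig, cohort_feature_table, generate_cohort
from gdmkin.synthetic import default_profile


@pytest.fixture(scope="session")
def tiny_cohort():
    """Fast cohort for interface tests: 2+1+2 subjects, 2 half-hour days."""
    return generate_cohort(group_sizes=(2, 1, 2), seed=7, n_days=2, day_length_hours=0.5)


@pytest.fixture(scope="session")
def tiny_table(tiny_cohort):
    return cohort_feature_table(tiny_cohort, PipelineConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def healthy_profile():
    return default_profile("T000", "CTR", severity=0.0, tremor_amplitude=0.0)


@pytest.fixture()
def severe_profile():
    return default_profile("T001", "HD", severity=1.0)
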