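"""Shared fixtures: small generated cohorts and trials.

The default-scale dataset (10 subjects, 97 running trials, three estimator
variants) is session-scoped because several structural and qualitative tests
share it.
"""

from __future__ import annotations

import numpy as np
import pytest

from pose2grf import synthetic
from pose2grf.types import TrialSpec


@pytest.fixture(scope="session")
def cohort():
    return synthetic.generate_cohort(4, seed=11)


@pytest.fixture(scope="session")
def one_trial(cohort):
    """One clean running trial: (subject, keypoints, force, events)."""
    subject = cohort[0]
    kp, force, events = synthetic.generate_trial(subject, TrialSpec(), seed=42)
    return subject, kp, force, events


@pytest.fixture(scope="session")
def dataset_records():
    """Default study-scale dataset: 10 subjects, 97 trials, 3 estimators."""
    return synthetic.generate_dataset(n_subjects=10, n_trials=97, seed=1)


@pytest.fixture(scope="session")
def study_samples(dataset_records):
    from pose2grf import pipeline

    return pipeline.samples_from_records(dataset_records)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
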