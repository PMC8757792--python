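"""Shared fixtures: small synthetic cohorts and trained ensembles."""

import numpy as np
import pytest

from fogcast.classifiers import EnsembleConfig, fit_ensemble
from fogcast.stepsim import SimConfig, simulate_cohort
from fogcast.windowing import WindowingParams, pool_datasets, window_trace


@pytest.fixture(scope="session")
def small_cohort():
    """Four-subject, 60 s cohort — fast enough for unit tests."""
    cfg = SimConfig(n_subjects=4, trial_length=6000, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Nine-subject cohort at the calibrated defaults (107 s trials)."""
    return simulate_cohort(SimConfig(n_subjects=9, seed=3))


@pytest.fixture(scope="session")
def windowed_small(small_cohort):
    params = WindowingParams(IL=113, GL=0, TL=1, OL=28)
    return [window_trace(t, None, params) for t in small_cohort]


@pytest.fixture(scope="session")
def trained_ensemble(windowed_small):
    """Full three-member ensemble trained on three subjects (fourth held out).

    The NN is kept small here so the fixture stays fast; member
    behaviour at the reference topology is exercised separately.
    """
    train = pool_datasets(windowed_small[:3])
    cfg = EnsembleConfig(rf_n_estimators=30, nn_hidden_layers=2,
                         nn_hidden_units=16, nn_max_iter=200, seed=7)
    return fit_ensemble(train, cfg)


@pytest.fixture(scope="session")
def held_out_windows(windowed_small):
    return windowed_small[3]


@pytest.fixture(scope="session")
def held_out_trace(small_cohort):
    return small_cohort[3]
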