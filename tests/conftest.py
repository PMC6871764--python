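"""Shared fixtures: small synthetic cohorts and trained toy scorers.

Everything is generated programmatically at test time; heavier artifacts are
session-scoped so they are built once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

import reachscore as rs


@pytest.fixture(scope="session")
def tiny_cohort() -> rs.SyntheticCohort:
    """A miniature cohort for plumbing tests: 4 animals, 2 days, 64 features."""
    return rs.generate_cohort(rs.CohortConfig(
        n_animals=4, trials_per_day=4, days=(-1, 1), clip_len=40,
        n_features=64, informative_set_size=8, seed=7))


@pytest.fixture(scope="session")
def small_trained_scorer(tiny_cohort):
    """A cumulative-head scorer trained to convergence on the tiny cohort."""
    arch = rs.ScorerArchitecture(n_features=64, lstm_units=32, head="cumulative")
    model = rs.build_scorer(arch, seed=0)
    targets = rs.targets_for_head("cumulative", tiny_cohort.scores.df,
                                  tiny_cohort.clips)
    hyper = rs.TrainHyper(learning_rate=3e-3, batch_size=8, epochs=100,
                          weight_decay=3e-3, seed=0)
    rs.train_scorer(model, tiny_cohort.clips, targets, hyper)
    return model


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
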