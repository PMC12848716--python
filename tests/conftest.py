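"""Shared fixtures: small simulated datasets and the session-scoped study.

Everything is generated programmatically with fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from sptmotion import SimulationConfig, generate_dataset
from sptmotion.features import compute_feature_table
from sptmotion.segment import segment_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_dataset():
    """200 trajectories across all five classes (fast shared fixture)."""
    cfg = SimulationConfig(n_trajectories=200, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    """Feature table of the 200-trajectory dataset (~14k windows)."""
    return compute_feature_table(segment_dataset(small_dataset))


@pytest.fixture(scope="session")
def paper_study():
    """The full desk-scale study: accuracy ladder, tuning, importances.

    Session-scoped because it dominates the suite's runtime; every
    study-level assertion reads from this one run.
    """
    from sptmotion.study import run_reference_study

    return run_reference_study(seed=1)
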