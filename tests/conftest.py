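"""Shared fixtures: a small deterministic fixture cohort and helpers.

The fixture cohort (12 participants, 8 channels, 40 s) is generated from a
fixed seed at session start rather than stored on disk; the generator's
determinism contract makes this equivalent to shipping the files.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from bandclust import BETA, DELTA, generate_cohort
from bandclust.io import feature_table_from_metrics, metrics_to_frame
from bandclust.metrics import compute_metrics
from bandclust.pipeline import connectivity_for_recording

FIXTURE_SEED = 42


@pytest.fixture(scope="session")
def fixture_cohort():
    """Small, strongly coupled cohort built to produce stable clusters."""
    return generate_cohort(
        n_participants=12,
        subgroup_fraction=0.5,
        seed=FIXTURE_SEED,
        n_channels=12,
        duration_s=40.0,
    )


@pytest.fixture(scope="session")
def fixture_metrics(fixture_cohort):
    """Long-format metrics table for the fixture cohort (both bands)."""
    rows = []
    for pre, post in fixture_cohort.recordings:
        for rec in (pre, post):
            for w in connectivity_for_recording(rec, [DELTA, BETA]).values():
                rows.append(compute_metrics(w))
    return metrics_to_frame(rows)


@pytest.fixture(scope="session")
def fixture_features_delta(fixture_metrics):
    return feature_table_from_metrics(fixture_metrics, "delta")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
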