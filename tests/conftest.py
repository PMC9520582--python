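"""Shared fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from audioprofiles import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A small complete 3-cluster cohort plus derived/scaled features."""
    from audioprofiles import features

    spec = synthetic.CohortSpec(
        n_patients=180, n_clusters=3, separation=6.0, missing_rate=0.0, seed=5
    )
    cohort = synthetic.generate_cohort(spec)
    feats = features.derive_features(cohort)
    scaled, scaler = features.encode_and_scale(feats)
    return cohort, feats, scaled, scaler


@pytest.fixture(scope="session")
def vei_sample():
    """Well-separated VEI mixture sample with known parameters."""
    return synthetic.sample_mixture(600, 4, 3, "VEI", separation=5.0, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
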