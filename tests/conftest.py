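"""Shared fixtures.

Expensive artifacts (atlas, cohorts, trained models) are session-scoped so
the whole suite trains each network at most once.
"""

from __future__ import annotations

import numpy as np
import pytest

from strokekit import (PhantomConfig, S1Config, build_s1,
                       generate_atlas_phantom, simulate_cohort, train_s1,
                       zscore_normalize)


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig(seed=0)


@pytest.fixture(scope="session")
def atlas(phantom_config):
    return generate_atlas_phantom(phantom_config, 6)


@pytest.fixture(scope="session")
def cohort16_raw(phantom_config, atlas):
    return simulate_cohort(16, phantom_config, atlas, seed=5)


@pytest.fixture(scope="session")
def cohort16_norm(phantom_config, atlas):
    import dataclasses

    cases = simulate_cohort(16, phantom_config, atlas, seed=5)
    return [dataclasses.replace(c, volume=zscore_normalize(c.volume))
            for c in cases]


@pytest.fixture(scope="session")
def trained_s1_small(cohort16_norm):
    """A quickly trained segmenter shared across S1 tests."""
    cfg = S1Config(epochs=3, seed=1)
    return train_s1(build_s1(cfg), cohort16_norm, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
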