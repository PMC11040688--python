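"""Shared fixtures: a small synthetic study bundle and derived objects.

Session-scoped so the corpus/space are built once; tests that need
different generator settings build their own configs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from witsem import (
    SemanticSpace,
    SimulationConfig,
    build_space,
    embed_all,
    simulate_bundle,
)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=11, delta=0.5, n_statements=400, n_grams=12_000)


@pytest.fixture(scope="session")
def bundle(sim_config):
    return simulate_bundle(sim_config)


@pytest.fixture(scope="session")
def space(bundle) -> SemanticSpace:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_space(bundle.corpus, R=240, C=240, d=80)


@pytest.fixture(scope="session")
def embedded(bundle, space):
    return embed_all(bundle.statements, space)


@pytest.fixture()
def two_word_space() -> SemanticSpace:
    """Two orthogonal unit word vectors: closed-form embedding checks."""
    return SemanticSpace(["up", "right"], np.array([[1.0, 0.0], [0.0, 1.0]]))
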