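"""Shared fixtures: small synthetic window sets and tiny model configs.

Expensive generated objects are session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from imugrf.data import WindowSet
from imugrf.fixtures import FixtureConfig, make_corpus
from imugrf.model import ModelConfig


@pytest.fixture(scope="session")
def small_corpus() -> tuple[WindowSet, WindowSet]:
    """(pretrain, labeled) windows from 3 participants x 30 s of gait."""
    cfg = FixtureConfig(n_participants=3, duration_s=30.0, seed=11)
    return make_corpus(cfg)


@pytest.fixture(scope="session")
def labeled_windows(small_corpus) -> WindowSet:
    return small_corpus[1]


@pytest.fixture(scope="session")
def pretrain_windows(small_corpus) -> WindowSet:
    return small_corpus[0]


@pytest.fixture()
def tiny_config() -> ModelConfig:
    return ModelConfig.tiny()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_window_set(rng: np.random.Generator, n: int = 6, with_grf: bool = False,
                      valid_lengths=None) -> WindowSet:
    """Unstructured random windows for shape/roundtrip tests."""
    data = rng.normal(size=(n, 128, 48))
    grf = rng.normal(size=(n, 128, 3)) if with_grf else None
    vl = np.full(n, 128, dtype=int) if valid_lengths is None else np.asarray(valid_lengths)
    for i in range(n):
        data[i, vl[i]:] = 0.0
        if grf is not None:
            grf[i, vl[i]:] = 0.0
    return WindowSet(
        data=data, grf=grf,
        participant_ids=np.array([f"P{i % 3}" for i in range(n)], dtype=object),
        trial_ids=np.array([f"T{i}" for i in range(n)], dtype=object),
        starts=np.arange(n) * 64,
        valid_lengths=vl,
    )
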