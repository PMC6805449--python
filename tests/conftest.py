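"""Shared fixtures: small geometric configurations and synthetic sets."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import euclidean_dm  # noqa: E402

from psma.io import SimilarityMatrix  # noqa: E402
from psma.synth import make_fixture  # noqa: E402


@pytest.fixture
def triangle_345() -> tuple[np.ndarray, DistanceMatrix]:
    pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
    return pts, euclidean_dm(pts)


@pytest.fixture
def planar_cloud() -> tuple[np.ndarray, DistanceMatrix]:
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(50, 2))
    return pts, euclidean_dm(pts)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_set():
    return make_fixture("tiny", seed=11)


@pytest.fixture(scope="session")
def unbalanced_set():
    return make_fixture("unbalanced", seed=11)


@pytest.fixture
def small_similarity() -> SimilarityMatrix:
    values = np.array([
        [1.0, 0.8, 0.3],
        [0.8, 1.0, 0.5],
        [0.3, 0.5, 1.0],
    ])
    return SimilarityMatrix(["a", "b", "c"], values)
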