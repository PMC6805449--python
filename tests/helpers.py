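"""Test helpers shared across modules."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from psma.metricspace import DistanceMatrix


def euclidean_dm(points: np.ndarray, ids=None) -> DistanceMatrix:
    """DistanceMatrix of the Euclidean distances of a point set."""
    points = np.asarray(points, dtype=float)
    ids = ids or [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(list(ids), squareform(pdist(points)),
                          transform_tag={"method": "euclidean"})


def sorted_pairwise(coords: np.ndarray) -> np.ndarray:
    """Sorted pairwise distance vector — rotation/reflection invariant."""
    return np.sort(pdist(np.asarray(coords, dtype=float)))
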