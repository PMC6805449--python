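"""Synthetic molecule sets with known ground truth.

Latent 2D cluster coordinates are mapped back to a similarity matrix by
inverting the convex distance transform, so the full pipeline can be
exercised — and its parameter recovery measured against the latent
truth — without any external data.

Given latent distances rescaled to d in [0, 1), the similarity is

    s = (1 + k) * (1 - d) / (k + (1 - d))

the algebraic inverse of d = 1 - k*s / (1 + k - s), so running the
convex transform with the same k recovers the rescaled latent distances
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .io import ActivityTable, SimilarityMatrix
from .metricspace import DEFAULT_K

FIXTURES = ("tiny", "unbalanced", "overlap")


@dataclass
class SyntheticSet:
    ids: list[str]
    latent: np.ndarray            # (M, 2) ground-truth coordinates
    labels: np.ndarray            # binary, after label noise
    cluster: np.ndarray           # latent cluster index per molecule
    similarity: SimilarityMatrix
    params: dict = field(default_factory=dict)

    def activity_table(self) -> ActivityTable:
        return ActivityTable(list(self.ids), self.labels.copy())


def _cluster_centroids(n_clusters: int, separation: float) -> np.ndarray:
    """Centroids with nearest-neighbour distance ``separation``.

    1 or 2 clusters sit on a line, 3 form an equilateral triangle; more
    sit on a regular polygon scaled so adjacent centroids are
    ``separation`` apart (mutual equidistance is impossible in 2D
    beyond 3 clusters).
    """
    if n_clusters == 1:
        return np.zeros((1, 2))
    if n_clusters == 2:
        return np.array([[0.0, 0.0], [separation, 0.0]])
    angles = 2 * np.pi * np.arange(n_clusters) / n_clusters
    radius = separation / (2 * np.sin(np.pi / n_clusters))
    return radius * np.column_stack([np.cos(angles), np.sin(angles)])


def latent_to_similarity(latent: np.ndarray, k: float = DEFAULT_K
                         ) -> tuple[SimilarityMatrix, list[str]]:
    """Map latent coordinates to a valid similarity matrix (see module doc)."""
    latent = np.asarray(latent, dtype=float)
    ids = [f"m{i + 1:04d}" for i in range(latent.shape[0])]
    dvec = pdist(latent)
    dmax = dvec.max(initial=0.0)
    if dmax > 0:
        # strict rescale into [0, 1) keeps every similarity strictly positive
        dvec = dvec / (dmax * (1.0 + 1e-6))
    d = squareform(dvec)
    dprime = 1.0 - d
    s = (1.0 + k) * dprime / (k + dprime)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(ids, s), ids


def generate_clusters(n_pos: int, n_neg: int, n_clusters: int = 2,
                      separation: float = 10.0, noise_sd: float = 1.0,
                      label_noise: float = 0.0, k: float = DEFAULT_K,
                      seed: int = 0) -> SyntheticSet:
    """Sample clustered latent points and derive similarities + labels.

    Positives populate the first cluster, negatives the remaining ones
    (all of them when ``n_clusters`` is 1).  A fraction ``label_noise``
    of labels is flipped after assignment.
    """
    if n_pos < 2 or n_neg < 2:
        raise ValidationError("need at least 2 molecules per class")
    if separation < 0:
        raise ValidationError(f"separation must be >= 0, got {separation}")
    if not 0 <= label_noise < 0.5:
        raise ValidationError(f"label_noise must be in [0, 0.5), got {label_noise}")
    if k <= 0:
        raise ValidationError(f"k must be > 0, got {k}")
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    if n_clusters < 1:
        raise ValidationError("need at least one cluster")

    rng = np.random.default_rng(seed)
    centroids = _cluster_centroids(n_clusters, separation)
    m = n_pos + n_neg
    labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])

    cluster = np.empty(m, dtype=int)
    cluster[:n_pos] = 0
    if n_clusters == 1:
        cluster[n_pos:] = 0
    else:
        cluster[n_pos:] = 1 + rng.integers(0, n_clusters - 1, size=n_neg)

    latent = centroids[cluster] + rng.normal(0.0, noise_sd, size=(m, 2))

    n_flip = int(np.floor(label_noise * m))
    if n_flip:
        flip = rng.choice(m, size=n_flip, replace=False)
        labels[flip] = 1 - labels[flip]

    sim, ids = latent_to_similarity(latent, k=k)
    params = {"n_pos": n_pos, "n_neg": n_neg, "n_clusters": n_clusters,
              "separation": separation, "noise_sd": noise_sd,
              "label_noise": label_noise, "k": k, "seed": seed}
    return SyntheticSet(ids, latent, labels, cluster, sim, params)


def make_fixture(name: str, seed: int = 0) -> SyntheticSet:
    """Named presets for tests and demos.

    tiny       : 20 molecules, well separated, for seconds-scale runs
    unbalanced : 56 pos / 170 neg — echoes a realistic skewed Ki screen
    overlap    : cluster separation of only 2 noise SDs, the hard case
    """
    if name == "tiny":
        return generate_clusters(8, 12, separation=10.0, noise_sd=1.0, seed=seed)
    if name == "unbalanced":
        return generate_clusters(56, 170, separation=10.0, noise_sd=1.0, seed=seed)
    if name == "overlap":
        return generate_clusters(30, 70, separation=2.0, noise_sd=1.0, seed=seed)
    raise ValidationError(f"unknown fixture {name!r}; choose from {FIXTURES}")
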