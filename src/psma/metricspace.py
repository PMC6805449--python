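"""Similarity-to-distance transforms and metric-space diagnostics.

The default transform is the convex map

    d(x, y) = 1 - k * s(x, y) / (1 + k - s(x, y))

with ``k = 0.382``: it sends s=1 to d=0 and s=0 to d=1, inflates
distances among very similar molecules, and converges to ``1 - s`` as
k grows.  The resulting distances are generally *not* Euclidean, and
triangle-inequality violations are reported, never repaired.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import SimilarityMatrix

TRANSFORMS = ("one_minus", "inverse", "neglog", "convex")

DEFAULT_K = 0.382
DEFAULT_CLAMP_SIM = 1e-6


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal distance matrix with transform provenance."""

    ids: list[str]
    values: np.ndarray
    transform_tag: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"distance matrix not square: {v.shape}")
        if not np.isfinite(v).all():
            raise ValidationError("non-finite distance entry")
        if np.abs(v - v.T).max(initial=0.0) > 1e-10:
            raise ValidationError("distance matrix not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 0:
            raise ValidationError("distance diagonal not zero")
        if v.min(initial=0.0) < 0:
            raise ValidationError("negative distance entry")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def transform_values(s: np.ndarray, method: str = "convex",
                     k: float = DEFAULT_K,
                     clamp_sim: float = DEFAULT_CLAMP_SIM) -> np.ndarray:
    """Apply one similarity->distance transform element-wise.

    ``clamp_sim`` floors the similarity for the transforms that diverge
    at s=0 (``inverse``, ``neglog``), tying the clamp distance to the
    transform itself.
    """
    s = np.asarray(s, dtype=float)
    if method == "one_minus":
        return 1.0 - s
    if method == "inverse":
        return 1.0 / np.maximum(s, clamp_sim) - 1.0
    if method == "neglog":
        return -np.log(np.maximum(s, clamp_sim))
    if method == "convex":
        if k <= 0:
            raise ValidationError(f"convexity parameter k must be > 0, got {k}")
        d = 1.0 - (k * s) / (1.0 + k - s)
        return np.where(s == 1.0, 0.0, d)  # exact zero at s=1 despite rounding
    raise ValidationError(f"unknown transform {method!r}; choose from {TRANSFORMS}")


def apply_transform_tag(s: np.ndarray, tag: dict) -> np.ndarray:
    """Re-apply a stored transform tag to new similarity values."""
    return transform_values(s, method=tag.get("method", "convex"),
                            k=tag.get("k", DEFAULT_K),
                            clamp_sim=tag.get("clamp_sim", DEFAULT_CLAMP_SIM))


def similarity_to_distance(sim: SimilarityMatrix, method: str = "convex",
                           k: float = DEFAULT_K,
                           clamp_sim: float = DEFAULT_CLAMP_SIM) -> DistanceMatrix:
    """Transform a similarity matrix into a distance matrix.

    The diagonal is forced to exactly zero and the result carries a
    ``transform_tag`` so out-of-sample rows can be transformed
    identically later.
    """
    d = transform_values(sim.values, method=method, k=k, clamp_sim=clamp_sim)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    np.maximum(d, 0.0, out=d)
    tag = {"method": method, "k": k, "clamp_sim": clamp_sim}
    return DistanceMatrix(list(sim.ids), d, transform_tag=tag)


def metric_diagnostics(dist: DistanceMatrix, n_triples: int = 20000,
                       seed: int = 0) -> dict:
    """Check metric axioms; triangle inequality over sampled triples.

    Exhaustive when M <= 60, otherwise ``n_triples`` uniform samples.
    Violations are reported (count, fraction, max magnitude), never
    repaired.
    """
    m = dist.n
    if m < 3:
        raise ValidationError(f"need >=3 points for triangle checks, got {m}")
    v = dist.values
    if m <= 60:
        triples = np.array(list(itertools.combinations(range(m), 3)))
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        triples = np.empty((n_triples, 3), dtype=int)
        for row in range(n_triples):
            triples[row] = rng.choice(m, size=3, replace=False)
        exhaustive = False
    a, b, c = triples.T
    ab, ac, bc = v[a, b], v[a, c], v[b, c]
    # worst slack over the 3 inequality orientations of each triple
    slack = np.maximum.reduce([ab - ac - bc, ac - ab - bc, bc - ab - ac])
    violated = slack > 1e-12
    return {
        "n_points": m,
        "n_triples_checked": len(triples),
        "exhaustive": exhaustive,
        "n_violations": int(violated.sum()),
        "violation_fraction": float(violated.mean()),
        "max_violation": float(slack.max(initial=0.0)) if violated.any() else 0.0,
        "symmetric": bool(np.abs(v - v.T).max(initial=0.0) <= 1e-10),
        "zero_diagonal": bool(np.abs(np.diag(v)).max(initial=0.0) == 0.0),
    }


def distance_summary(dist: DistanceMatrix) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation over all M(M-1)/2 pairs."""
    if dist.n < 2:
        raise ValidationError("need >=2 points for distance summary")
    pairs = dist.upper_triangle()
    sd = float(np.std(pairs, ddof=1)) if len(pairs) > 1 else 0.0
    return float(np.mean(pairs)), sd
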