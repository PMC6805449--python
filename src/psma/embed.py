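"""Linear out-of-sample embedding into a trained 2D reference space.

If D is the training distance matrix and C the projected coordinates,
the linear map T with D @ T = C is recovered as T = pinv(D) @ C.  For
full-rank D this reproduces the training coordinates exactly; new
molecules are embedded by multiplying their distance row (to the
training molecules, in training order) with T.  The map is linear even
when the projection that produced C is not (t-SNE): near the training
support it is an adequate, not exact, extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .metricspace import DistanceMatrix, apply_transform_tag
from .projection import ProjectionResult

DEFAULT_PINV_RTOL = 1e-10


@dataclass
class EmbeddingTransform:
    """The matrix T mapping training-distance rows to 2D coordinates."""

    T: np.ndarray                        # (M, P)
    training_ids: list[str]
    transform_tag: dict = field(default_factory=dict)
    pinv_tolerance: float = DEFAULT_PINV_RTOL
    residual_inf: float = 0.0            # max |D @ T - C| at fit time

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if self.T.ndim != 2 or self.T.shape[0] != len(self.training_ids):
            raise ValidationError(
                f"T shape {self.T.shape} does not match "
                f"{len(self.training_ids)} training ids")
        if not np.isfinite(self.T).all():
            raise ValidationError("non-finite entries in embedding transform")


def compute_transform(dist: DistanceMatrix, proj: ProjectionResult,
                      pinv_rtol: float = DEFAULT_PINV_RTOL) -> EmbeddingTransform:
    """Solve D @ T = C by tolerance-truncated pseudo-inverse.

    For well-conditioned D this equals the literal inverse to numerical
    precision; for rank-deficient D (duplicate molecules) it yields the
    least-norm T, which still reproduces C within the reported residual.
    """
    if list(dist.ids) != list(proj.ids):
        raise ValidationError("distance matrix ids do not match projection ids")
    t = np.linalg.pinv(dist.values, rcond=pinv_rtol) @ proj.coords
    residual = float(np.abs(dist.values @ t - proj.coords).max())
    return EmbeddingTransform(t, list(dist.ids),
                              transform_tag=dict(dist.transform_tag),
                              pinv_tolerance=pinv_rtol, residual_inf=residual)


def embed_distances(transform: EmbeddingTransform,
                    distance_rows: np.ndarray) -> np.ndarray:
    """Embed precomputed distance rows (Q x M, training order)."""
    rows = np.atleast_2d(np.asarray(distance_rows, dtype=float))
    m = len(transform.training_ids)
    if rows.shape[1] != m:
        raise ValidationError(
            f"distance rows have {rows.shape[1]} columns, expected {m} "
            "(one per training molecule, in training order)")
    return rows @ transform.T


def embed_new(transform: EmbeddingTransform, new_similarities: np.ndarray,
              ids: Sequence[str] | None = None) -> np.ndarray:
    """Embed new molecules from their similarity rows to the training set.

    Each row holds one similarity per training molecule, ordered as
    ``transform.training_ids``.  The rows are converted to distances
    with the exact transform used at training time, then mapped by T.
    """
    if ids is not None and list(ids) != list(transform.training_ids):
        raise ValidationError("similarity columns are not in training-id order")
    sims = np.atleast_2d(np.asarray(new_similarities, dtype=float))
    m = len(transform.training_ids)
    if sims.shape[1] != m:
        raise ValidationError(
            f"similarity rows have {sims.shape[1]} columns, expected {m}")
    if sims.min(initial=0.0) < -1e-9 or sims.max(initial=0.0) > 1 + 1e-9:
        raise ValidationError("similarity values outside [0, 1]")
    dists = apply_transform_tag(np.clip(sims, 0.0, 1.0), transform.transform_tag)
    return embed_distances(transform, dists)
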