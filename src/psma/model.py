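"""The probabilistic activity surface: per-class kernel density maps
combined through Bayes' theorem into a posterior that doubles as a
spatial binary classifier.

Both class-conditional maps share bandwidths computed once from all
training coordinates pooled; priors default to the empirical class
frequencies.  The posterior at (x, y) is

    p_pos = L_pos * prior_pos / (L_pos * prior_pos + L_neg * prior_neg)

with L the exact kernel-sum likelihoods.  Where the total mixture
density vanishes (far outside the training support) queries are flagged
out-of-domain and fall back to the priors.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .density import (KernelDensityMap, default_extent, kde2d_eval, kde2d_fit,
                      silverman_bandwidth)
from .embed import EmbeddingTransform
from .errors import ValidationError
from .io import ActivityTable
from .projection import ProjectionResult

MODEL_FORMAT_VERSION = "psma-model-1"

# out-of-domain cutoff, relative to the peak mixture density at the support
EPS_RELATIVE = 1e-12


@dataclass
class PosteriorResult:
    p_pos: np.ndarray
    p_neg: np.ndarray
    density_total: np.ndarray
    in_domain: np.ndarray


@dataclass
class PSMAModel:
    kdm_pos: KernelDensityMap
    kdm_neg: KernelDensityMap
    prior_pos: float
    prior_neg: float
    transform: EmbeddingTransform | None = None
    projection_meta: dict = field(default_factory=dict)
    peak_density: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.prior_pos < 1 and 0 < self.prior_neg < 1):
            raise ValidationError("priors must lie strictly inside (0, 1)")
        if abs(self.prior_pos + self.prior_neg - 1.0) > 1e-8:
            raise ValidationError(
                f"priors must sum to 1, got {self.prior_pos + self.prior_neg}")
        if (self.kdm_pos.hx != self.kdm_neg.hx
                or self.kdm_pos.hy != self.kdm_neg.hy):
            raise ValidationError("class maps must share bandwidths")
        if self.peak_density == 0.0:
            support = np.vstack([self.kdm_pos.support, self.kdm_neg.support])
            self.peak_density = float(self._mixture(support).max())

    def _mixture(self, queries: np.ndarray) -> np.ndarray:
        return (self.prior_pos * kde2d_eval(self.kdm_pos, queries)
                + self.prior_neg * kde2d_eval(self.kdm_neg, queries))


def fit_psma(coords: ProjectionResult, labels: ActivityTable,
             transform: EmbeddingTransform | None = None,
             priors: tuple[float, float] | None = None) -> PSMAModel:
    """Fit the two class-conditional KDEs and priors on labelled coordinates.

    Bandwidths are Silverman per axis on *all* training points pooled,
    then shared by both class maps.  Priors default to empirical class
    frequencies; a user-supplied pair must sum to one.
    """
    y = labels.label_of(coords.ids)
    xy = coords.coords[:, :2]
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValidationError(
            f"each class needs >=2 molecules, got {n_pos} pos / {n_neg} neg")
    hx = silverman_bandwidth(xy[:, 0])
    hy = silverman_bandwidth(xy[:, 1])
    if priors is None:
        prior_pos = n_pos / (n_pos + n_neg)
    else:
        if abs(priors[0] + priors[1] - 1.0) > 1e-8:
            raise ValidationError(f"priors {priors} do not sum to 1")
        prior_pos = float(priors[0])
    meta = {"method": coords.method, "seed": coords.seed,
            "n_train": len(coords.ids), "stress": coords.stress}
    return PSMAModel(
        kdm_pos=kde2d_fit(xy[y == 1], hx, hy),
        kdm_neg=kde2d_fit(xy[y == 0], hx, hy),
        prior_pos=prior_pos,
        prior_neg=1.0 - prior_pos,
        transform=transform,
        projection_meta=meta,
    )


def posterior(model: PSMAModel, queries: np.ndarray) -> PosteriorResult:
    """Bayes posterior of activity at each 2D query point."""
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    l_pos = kde2d_eval(model.kdm_pos, queries)
    l_neg = kde2d_eval(model.kdm_neg, queries)
    num = l_pos * model.prior_pos
    total = num + l_neg * model.prior_neg
    eps = EPS_RELATIVE * model.peak_density
    in_domain = total > eps
    p_pos = np.where(in_domain, num / np.where(total > 0, total, 1.0),
                     model.prior_pos)
    return PosteriorResult(p_pos=p_pos, p_neg=1.0 - p_pos,
                           density_total=total, in_domain=in_domain)


def classify(model: PSMAModel, queries: np.ndarray, threshold: float = 0.5
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label queries positive iff p_pos > threshold.

    At the default threshold 0.5 this is exactly "positive iff
    P(+|x,y) > P(-|x,y)".  Out-of-domain queries score at the prior and
    are flagged.  Returns (labels, scores, in_domain).
    """
    if not 0 < threshold < 1:
        raise ValidationError(f"threshold must be in (0,1), got {threshold}")
    post = posterior(model, queries)
    return (post.p_pos > threshold).astype(int), post.p_pos, post.in_domain


def posterior_surface(model: PSMAModel, nx: int = 100, ny: int = 100,
                      extent: tuple[float, float, float, float] | None = None
                      ) -> dict:
    """Grids of p_pos and both class likelihoods over a lattice.

    Surface values at any lattice node equal ``posterior`` there exactly
    (direct kernel sums, no interpolation).
    """
    if extent is None:
        support = np.vstack([model.kdm_pos.support, model.kdm_neg.support])
        extent = default_extent(support, model.kdm_pos.hx, model.kdm_pos.hy)
    xmin, xmax, ymin, ymax = (float(v) for v in extent)
    if not (xmin < xmax and ymin < ymax) or nx < 2 or ny < 2:
        raise ValidationError(f"degenerate surface request {nx}x{ny} {extent}")
    x_axis = np.linspace(xmin, xmax, nx)
    y_axis = np.linspace(ymin, ymax, ny)
    gx, gy = np.meshgrid(x_axis, y_axis)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    post = posterior(model, pts)
    l_pos = kde2d_eval(model.kdm_pos, pts)
    l_neg = kde2d_eval(model.kdm_neg, pts)
    return {
        "x_axis": x_axis,
        "y_axis": y_axis,
        "p_pos": post.p_pos.reshape(ny, nx),
        "density_pos": l_pos.reshape(ny, nx),
        "density_neg": l_neg.reshape(ny, nx),
        "in_domain": post.in_domain.reshape(ny, nx),
        "extent": (xmin, xmax, ymin, ymax),
    }


# ---------------------------------------------------------------------------
# serialization: one JSON bundle so classify-only runs need no refit
# ---------------------------------------------------------------------------

def save_model(model: PSMAModel, path: str | os.PathLike) -> None:
    bundle = {
        "format": MODEL_FORMAT_VERSION,
        "prior_pos": model.prior_pos,
        "prior_neg": model.prior_neg,
        "bandwidths": {"hx": model.kdm_pos.hx, "hy": model.kdm_pos.hy},
        "support_pos": model.kdm_pos.support.tolist(),
        "support_neg": model.kdm_neg.support.tolist(),
        "projection_meta": model.projection_meta,
        "peak_density": model.peak_density,
    }
    if model.transform is not None:
        bundle["transform"] = {
            "T": model.transform.T.tolist(),
            "training_ids": model.transform.training_ids,
            "transform_tag": model.transform.transform_tag,
            "pinv_tolerance": model.transform.pinv_tolerance,
            "residual_inf": model.transform.residual_inf,
        }
    with open(path, "w") as fh:
        json.dump(bundle, fh)
        fh.write("\n")


def load_model(path: str | os.PathLike) -> PSMAModel:
    with open(path) as fh:
        bundle = json.load(fh)
    if bundle.get("format") != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported model bundle format {bundle.get('format')!r}")
    hx, hy = bundle["bandwidths"]["hx"], bundle["bandwidths"]["hy"]
    transform = None
    if "transform" in bundle:
        t = bundle["transform"]
        transform = EmbeddingTransform(
            np.asarray(t["T"]), list(t["training_ids"]),
            transform_tag=t["transform_tag"],
            pinv_tolerance=t["pinv_tolerance"],
            residual_inf=t["residual_inf"])
    return PSMAModel(
        kdm_pos=kde2d_fit(np.asarray(bundle["support_pos"]), hx, hy),
        kdm_neg=kde2d_fit(np.asarray(bundle["support_neg"]), hx, hy),
        prior_pos=bundle["prior_pos"],
        prior_neg=bundle["prior_neg"],
        transform=transform,
        projection_meta=bundle.get("projection_meta", {}),
        peak_density=bundle.get("peak_density", 0.0),
    )
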