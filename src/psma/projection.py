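"""Distance-preserving 2D projections and their distortion diagnostics.

Four methods operate directly on the (generally non-Euclidean) distance
matrix: principal coordinates analysis (classical metric MDS), Kruskal
non-metric MDS, Sammon mapping and t-SNE on precomputed distances.
The iterative methods start from the PCooA configuration by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .errors import NumericalError, ValidationError
from .metricspace import DistanceMatrix

log = logging.getLogger(__name__)

METHODS = ("pcooa", "kmds", "sammon", "tsne")


@dataclass
class ProjectionResult:
    """Low-dimensional coordinates plus method metadata."""

    ids: list[str]
    coords: np.ndarray                     # (M, P)
    method: str
    stress: float | None = None
    eigenvalues: np.ndarray | None = None  # pcooa only, full descending spectrum
    seed: int | None = None
    iterations_run: int | None = None
    converged: bool = True
    stress_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise NumericalError(f"{self.method}: non-finite coordinates")
        if self.coords.shape[0] != len(self.ids):
            raise ValidationError("coordinate rows do not align with ids")


@dataclass
class ShepardData:
    """Paired original/projected distance vectors and their r-squared."""

    original_d: np.ndarray
    projected_d: np.ndarray
    r2: float


# ---------------------------------------------------------------------------
# PCooA
# ---------------------------------------------------------------------------

def pcooa(dist: DistanceMatrix, dims: int = 2) -> ProjectionResult:
    """Principal coordinates analysis.

    Double-centers the squared distance matrix, eigendecomposes it, and
    scales the top eigenvectors by the square roots of their (positive)
    eigenvalues.  Negative eigenvalues — expected for non-Euclidean
    input — are reported in the spectrum but never used for
    coordinates.  Eigenvector signs are fixed so each one's
    largest-magnitude entry is positive, making the output deterministic
    across linear-algebra backends.
    """
    m = dist.n
    if m < dims + 1:
        raise ValidationError(f"need at least {dims + 1} points for {dims}D PCooA")
    d2 = dist.values ** 2
    j = np.eye(m) - np.full((m, m), 1.0 / m)
    b = -0.5 * j @ d2 @ j
    b = 0.5 * (b + b.T)
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(m, 1) * np.finfo(float).eps * max(abs(eigval[0]), 1.0)
    n_pos = int((eigval > tol).sum())
    if n_pos < dims:
        raise NumericalError(
            f"only {n_pos} positive eigenvalues, need {dims}; "
            f"spectrum head: {np.array2string(eigval[:min(m, 6)], precision=4)}")
    vecs = eigvec[:, :dims].copy()
    for col in range(dims):
        pivot = np.argmax(np.abs(vecs[:, col]))
        if vecs[pivot, col] < 0:
            vecs[:, col] = -vecs[:, col]
    coords = vecs * np.sqrt(eigval[:dims])
    pos_total = eigval[:n_pos].sum()
    log.debug("pcooa: variance represented by top %d axes: %.4f",
              dims, float(eigval[:dims].sum() / pos_total))
    return ProjectionResult(list(dist.ids), coords, "pcooa", eigenvalues=eigval)


# ---------------------------------------------------------------------------
# stress functions (pure evaluation, no optimization)
# ---------------------------------------------------------------------------

def _check_config(dist: DistanceMatrix, coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] != dist.n:
        raise ValidationError(
            f"coords shape {coords.shape} does not match {dist.n} points")
    return coords


def stress(dist: DistanceMatrix, coords: np.ndarray, kind: str = "kruskal") -> float:
    """Evaluate a configuration's stress against the original distances.

    kruskal:  sqrt( sum (d - dhat)^2 / sum d^2 )
    sammon :  (1 / sum d) * sum (d - dhat)^2 / d
    """
    coords = _check_config(dist, coords)
    d = dist.upper_triangle()
    dhat = pdist(coords)
    if kind == "kruskal":
        denom = float((d ** 2).sum())
        if denom == 0:
            raise ValidationError("all original distances are zero")
        return float(np.sqrt(((d - dhat) ** 2).sum() / denom))
    if kind == "sammon":
        pos = d > 0
        if not pos.any():
            raise ValidationError("all original distances are zero")
        return float(((d[pos] - dhat[pos]) ** 2 / d[pos]).sum() / d[pos].sum())
    raise ValidationError(f"unknown stress kind {kind!r}")


def shepard(dist: DistanceMatrix, coords: np.ndarray) -> ShepardData:
    """Original vs projected pairwise distances plus their r-squared."""
    coords = _check_config(dist, coords)
    d = dist.upper_triangle()
    dhat = pdist(coords)
    if d.std() == 0 or dhat.std() == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(d, dhat)[0, 1] ** 2)
    return ShepardData(d, dhat, r2)


# ---------------------------------------------------------------------------
# iterative methods
# ---------------------------------------------------------------------------

def _prepare_iterative(dist: DistanceMatrix, init, dims: int,
                       jitter: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Shared setup: jitter zero off-diagonal distances, resolve init."""
    d = dist.upper_triangle().copy()
    zeros = d == 0
    if zeros.any():
        warnings.warn(f"{int(zeros.sum())} zero off-diagonal distances "
                      f"jittered by {jitter:g}", stacklevel=3)
        d[zeros] = jitter
    if isinstance(init, str):
        if init != "pcooa":
            raise ValidationError(f"unknown init {init!r}")
        x0 = pcooa(dist, dims).coords
    else:
        x0 = np.asarray(init, dtype=float)
        if x0.shape != (dist.n, dims):
            raise ValidationError(f"init shape {x0.shape} != ({dist.n}, {dims})")
    return d, x0.copy()


def _nonmetric_stress1(dhat: np.ndarray, disp: np.ndarray) -> float:
    denom = float((dhat ** 2).sum())
    return float(np.sqrt(((dhat - disp) ** 2).sum() / denom)) if denom else 0.0


def kruskal_mds(dist: DistanceMatrix, init="pcooa", max_iter: int = 50,
                tol: float = 1e-3, dims: int = 2) -> ProjectionResult:
    """Kruskal non-metric MDS (stress-1 minimization).

    Each iteration fits disparities to the projected distances by
    isotonic regression on the rank order of the original distances
    (tied originals share one fitted disparity — Kruskal's primary
    approach), then moves the configuration by a Guttman transform.
    Steps are accepted only if stress-1 decreases, so the recorded
    stress trace is non-increasing.
    """
    if dist.n < 4:
        raise ValidationError(f"need >=4 points for non-metric MDS, got {dist.n}")
    d, x = _prepare_iterative(dist, init, dims)
    m = dist.n
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    def fit_disparities(dhat: np.ndarray) -> np.ndarray:
        return iso.fit_transform(d, dhat)

    dhat = pdist(x)
    disp = fit_disparities(dhat)
    current = _nonmetric_stress1(dhat, disp)
    trace = [current]
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        # Guttman transform toward the disparities
        dhat_sq = squareform(np.maximum(dhat, 1e-12))
        disp_sq = squareform(disp)
        ratio = disp_sq / np.maximum(dhat_sq, 1e-12)
        np.fill_diagonal(ratio, 0.0)
        bmat = -ratio
        np.fill_diagonal(bmat, ratio.sum(axis=1))
        x_new = bmat @ x / m
        dhat_new = pdist(x_new)
        disp_new = fit_disparities(dhat_new)
        new = _nonmetric_stress1(dhat_new, disp_new)
        if new >= current:                 # reject non-improving step
            converged = True
            break
        x, dhat, disp = x_new, dhat_new, disp_new
        improvement = current - new
        current = new
        trace.append(current)
        if current < 1e-12 or improvement < tol * max(current, 1e-12):
            converged = True
            break
    if not converged:
        warnings.warn(f"kruskal_mds: no convergence in {max_iter} iterations; "
                      "returning best configuration", stacklevel=2)
    return ProjectionResult(list(dist.ids), x, "kmds", stress=current,
                            iterations_run=iterations, converged=converged,
                            stress_trace=trace)


def _sammon_stress(d: np.ndarray, dhat: np.ndarray, c: float) -> float:
    return float(((d - dhat) ** 2 / d).sum() / c)


def sammon(dist: DistanceMatrix, init="pcooa", max_iter: int = 100,
           tol: float = 1e-4, magic: float = 0.3,
           dims: int = 2) -> ProjectionResult:
    """Sammon mapping via the classic pseudo-Newton diagonal update.

    Minimizes the error-weighted stress (residuals divided by the
    original distance, normalized by the sum of original distances)
    with step factor ``magic``.  Non-improving steps trigger step
    halving; the accepted stress trace is non-increasing.
    """
    if dist.n < 3:
        raise ValidationError(f"need >=3 points for Sammon mapping, got {dist.n}")
    d_vec, x = _prepare_iterative(dist, init, dims)
    m = dist.n
    d = squareform(d_vec)
    c = float(d_vec.sum())

    dhat_vec = pdist(x)
    current = _sammon_stress(d_vec, dhat_vec, c)
    trace = [current]
    iterations = 0
    converged = current < 1e-15
    eps = 1e-12
    for iterations in range(1, max_iter + 1):
        dhat = squareform(np.maximum(dhat_vec, eps))
        np.fill_diagonal(dhat, 1.0)        # masked out below
        dsafe = d.copy()
        np.fill_diagonal(dsafe, 1.0)
        delta = dsafe - dhat
        mask = ~np.eye(m, dtype=bool)

        w1 = np.where(mask, delta / (dsafe * dhat), 0.0)
        w2 = np.where(mask, 1.0 / (dsafe * dhat), 0.0)
        grad = np.empty_like(x)
        hess = np.empty_like(x)
        for q in range(dims):
            diff = x[:, q][:, None] - x[:, q][None, :]
            grad[:, q] = (-2.0 / c) * (w1 * diff).sum(axis=1)
            hess[:, q] = (-2.0 / c) * (w2 * (delta - (diff ** 2 / dhat)
                          * (1.0 + delta / dhat))).sum(axis=1)
        step = grad / np.maximum(np.abs(hess), eps)

        accepted = False
        factor = magic
        for _ in range(8):                 # halve until the step improves
            x_new = x - factor * step
            dhat_new = pdist(x_new)
            new = _sammon_stress(d_vec, dhat_new, c)
            if new < current:
                accepted = True
                break
            factor *= 0.5
        if not accepted:
            converged = True
            break
        improvement = (current - new) / max(current, eps)
        x, dhat_vec, current = x_new, dhat_new, new
        trace.append(current)
        if improvement < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"sammon: no convergence in {max_iter} iterations; "
                      "returning best configuration", stacklevel=2)
    return ProjectionResult(list(dist.ids), x, "sammon", stress=current,
                            iterations_run=iterations, converged=converged,
                            stress_trace=trace)


def tsne(dist: DistanceMatrix, perplexity: float = 30.0, seed: int = 0,
         max_iter: int = 1000, dims: int = 2) -> ProjectionResult:
    """t-SNE on the precomputed distance matrix; deterministic per seed."""
    from sklearn.manifold import TSNE

    m = dist.n
    bound = 3 * perplexity + 1
    if m < bound:
        raise ValidationError(
            f"perplexity {perplexity} too large for {m} points "
            f"(need M >= 3*perplexity + 1 = {bound:g})")
    model = TSNE(n_components=dims, metric="precomputed", init="random",
                 perplexity=perplexity, random_state=seed, max_iter=max_iter,
                 method="exact" if m <= 1500 else "barnes_hut")
    # copy: sklearn squares a precomputed distance matrix in place
    coords = model.fit_transform(dist.values.copy())
    return ProjectionResult(list(dist.ids), coords, "tsne", seed=seed,
                            iterations_run=int(model.n_iter_))


def project(dist: DistanceMatrix, method: str = "pcooa", *, dims: int = 2,
            seed: int = 0, perplexity: float = 30.0,
            max_iter: int | None = None) -> ProjectionResult:
    """Dispatch to one of the four projection methods with its defaults."""
    if method == "pcooa":
        return pcooa(dist, dims=dims)
    if method == "kmds":
        return kruskal_mds(dist, dims=dims, max_iter=max_iter or 50)
    if method == "sammon":
        return sammon(dist, dims=dims, max_iter=max_iter or 100)
    if method == "tsne":
        return tsne(dist, dims=dims, seed=seed, perplexity=perplexity,
                    max_iter=max_iter or 1000)
    raise ValidationError(f"unknown projection method {method!r}; "
                          f"choose from {METHODS}")
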