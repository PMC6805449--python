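"""2D Gaussian kernel density estimation with Silverman bandwidths.

The estimator is the product-kernel sum

    f(x, y) = sum_s phi((x - x_s)/hx) * phi((y - y_s)/hy) / (n hx hy)

evaluated exactly at every query — no grid interpolation — so grid
resolution affects pictures only, never classification.  Bandwidths
come from the normal-reference rule

    h = 1.06 * min(sd, IQR / 1.34) * n^(-1/5)

computed per axis.  In the intended use both class-conditional maps
share bandwidths computed once from all training points pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

# queries x support blocks are chunked to bound peak memory
_CHUNK_CELLS = 4_000_000


@dataclass
class KernelDensityMap:
    """An evaluable 2D product-Gaussian KDE (support points + bandwidths)."""

    support: np.ndarray      # (n, 2)
    hx: float
    hy: float

    def __post_init__(self) -> None:
        self.support = np.atleast_2d(np.asarray(self.support, dtype=float))
        if self.support.ndim != 2 or self.support.shape[1] != 2:
            raise ValidationError(f"support must be n x 2, got {self.support.shape}")
        if self.support.shape[0] < 1:
            raise ValidationError("need at least one support point")
        if not np.isfinite(self.support).all():
            raise ValidationError("non-finite support coordinates")
        if not (self.hx > 0 and self.hy > 0):
            raise ValidationError(f"bandwidths must be positive, got "
                                  f"hx={self.hx}, hy={self.hy}")

    @property
    def n(self) -> int:
        return self.support.shape[0]


def silverman_bandwidth(x: np.ndarray) -> float:
    """Normal-reference bandwidth 1.06 * min(sd, IQR/1.34) * n^(-1/5).

    ``sd`` is the sample (n-1) standard deviation and the IQR uses the
    standard linear-interpolation quartile convention.  A constant
    vector has zero spread and therefore no valid bandwidth.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValidationError(f"need >=2 values for a bandwidth, got {x.size}")
    sd = float(np.std(x, ddof=1))
    q1, q3 = np.percentile(x, [25.0, 75.0])
    spread = min(sd, (q3 - q1) / 1.34)
    if spread <= 0:
        raise ValidationError("zero spread (constant or degenerate vector): "
                              "bandwidth undefined")
    return 1.06 * spread * x.size ** (-0.2)


def kde2d_fit(points: np.ndarray, hx: float, hy: float) -> KernelDensityMap:
    """Build a KDE from support points and per-axis bandwidths."""
    return KernelDensityMap(points, float(hx), float(hy))


def kde2d_eval(kdm: KernelDensityMap, queries: np.ndarray) -> np.ndarray:
    """Evaluate the kernel sum exactly at each query point."""
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if queries.shape[1] != 2:
        raise ValidationError(f"queries must be Q x 2, got {queries.shape}")
    if not np.isfinite(queries).all():
        raise ValidationError("non-finite query coordinates")
    sx, sy = kdm.support[:, 0], kdm.support[:, 1]
    norm = kdm.n * kdm.hx * kdm.hy * 2.0 * np.pi
    out = np.empty(queries.shape[0])
    chunk = max(1, _CHUNK_CELLS // kdm.n)
    for start in range(0, queries.shape[0], chunk):
        q = queries[start:start + chunk]
        tx = (q[:, 0, None] - sx[None, :]) / kdm.hx
        ty = (q[:, 1, None] - sy[None, :]) / kdm.hy
        out[start:start + chunk] = np.exp(-0.5 * (tx * tx + ty * ty)).sum(axis=1) / norm
    return out


def kde2d_grid(kdm: KernelDensityMap, nx: int, ny: int,
               extent: tuple[float, float, float, float],
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the KDE on an nx-by-ny lattice over ``extent``.

    Returns ``(grid, x_axis, y_axis)`` with ``grid[iy, ix]`` the density
    at ``(x_axis[ix], y_axis[iy])``.
    """
    if nx < 2 or ny < 2:
        raise ValidationError(f"grid must be at least 2x2, got {nx}x{ny}")
    xmin, xmax, ymin, ymax = (float(v) for v in extent)
    if not (np.isfinite([xmin, xmax, ymin, ymax]).all()
            and xmin < xmax and ymin < ymax):
        raise ValidationError(f"degenerate extent {extent}")
    x_axis = np.linspace(xmin, xmax, nx)
    y_axis = np.linspace(ymin, ymax, ny)
    gx, gy = np.meshgrid(x_axis, y_axis)
    dens = kde2d_eval(kdm, np.column_stack([gx.ravel(), gy.ravel()]))
    return dens.reshape(ny, nx), x_axis, y_axis


def default_extent(points: np.ndarray, hx: float, hy: float,
                   pad: float = 3.0) -> tuple[float, float, float, float]:
    """Bounding box of ``points`` padded by ``pad`` bandwidths per axis."""
    points = np.atleast_2d(points)
    return (float(points[:, 0].min() - pad * hx),
            float(points[:, 0].max() + pad * hx),
            float(points[:, 1].min() - pad * hy),
            float(points[:, 1].max() + pad * hy))
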