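"""Parallel-beam geometry, Siddon system matrix, and matched projectors.

The system matrix ``A`` has one row per ray (view, bin) and one column
per pixel; entry ``a_ij`` is the exact intersection length of the ray's
central line with square pixel ``i``.  Forward projection is ``A x`` and
backprojection is the literal transpose ``A^T y``, so the pair is an
exact adjoint — a property the gradient interpretation of the additive
update form relies on.

Pixels the rays never touch (the corners outside the inscribed field of
view at some grids) have zero sensitivity ``s_i = sum_j a_ij``; the EM
updates freeze them at zero rather than dividing by zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .phantom import DEFAULT_CENTER


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam sampling: equally spaced views and detector bins.

    View angles are ``theta_k = k * angular_range / n_views`` degrees
    (0..357 for the default 120 views over 360); bin centers sit at
    signed offsets ``(m - (n_bins-1)/2) * bin_width`` from the rotation
    axis, symmetric about zero.
    """

    n_views: int = 120
    n_bins: int = 128
    angular_range: float = 360.0
    bin_width: float = 1.0
    center: tuple[float, float] = DEFAULT_CENTER

    def __post_init__(self) -> None:
        if self.n_views < 1 or self.n_bins < 1:
            raise ValueError("n_views and n_bins must be positive")

    @property
    def view_angles_deg(self) -> np.ndarray:
        return np.arange(self.n_views) * (self.angular_range / self.n_views)

    @property
    def bin_offsets(self) -> np.ndarray:
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0) * self.bin_width

    @property
    def n_rays(self) -> int:
        return self.n_views * self.n_bins


@dataclass
class SystemMatrix:
    """Sparse ray-pixel intersection-length operator with cached sensitivity.

    ``A`` has shape (n_rays, n_pixels); ``sensitivity`` is the
    backprojection of an all-ones sinogram, the denominator normalizer of
    the classical ML-EM update.  ``geometry``/``grid_size`` are None for
    toy operators built from a raw matrix.
    """

    A: sp.spmatrix | np.ndarray
    sensitivity: np.ndarray
    geometry: Optional[Geometry] = None
    grid_size: Optional[int] = None

    @classmethod
    def from_matrix(cls, A) -> "SystemMatrix":
        A = sp.csr_matrix(A) if sp.issparse(A) else np.asarray(A, dtype=float)
        ones = np.ones(A.shape[0])
        return cls(A=A, sensitivity=np.asarray(A.T @ ones).ravel(), geometry=None,
                   grid_size=None)

    @property
    def n_rays(self) -> int:
        return self.A.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.A.shape[1]

    @property
    def fov_mask(self) -> np.ndarray:
        """Flat boolean mask of pixels reachable by at least one ray."""
        return self.sensitivity > 0.0


def _ray_pixel_lengths(px: float, py: float, vx: float, vy: float,
                       grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Siddon trace of one line through the [-0.5, n-0.5]^2 pixel square.

    Returns (flat pixel indices, intersection lengths); empty arrays if
    the line misses the square.  (px, py) is any point on the line and
    (vx, vy) its unit direction.
    """
    n = grid_size
    lo, hi = -0.5, n - 0.5
    tmin, tmax = -np.inf, np.inf
    for p, v in ((px, vx), (py, vy)):
        if v == 0.0:
            if not (lo <= p <= hi):
                return np.empty(0, dtype=np.int64), np.empty(0)
        else:
            t0, t1 = (lo - p) / v, (hi - p) / v
            if t0 > t1:
                t0, t1 = t1, t0
            tmin, tmax = max(tmin, t0), min(tmax, t1)
    if not tmin < tmax:
        return np.empty(0, dtype=np.int64), np.empty(0)
    ts = [np.array([tmin, tmax])]
    for p, v in ((px, vx), (py, vy)):
        if v != 0.0:
            planes = lo + np.arange(1, n)  # interior grid lines
            t = (planes - p) / v
            ts.append(t[(t > tmin) & (t < tmax)])
    t = np.unique(np.concatenate(ts))
    lengths = np.diff(t)
    tm = 0.5 * (t[:-1] + t[1:])
    ix = np.clip(np.floor(px + tm * vx + 0.5).astype(np.int64), 0, n - 1)
    iy = np.clip(np.floor(py + tm * vy + 0.5).astype(np.int64), 0, n - 1)
    keep = lengths > 1e-12
    return (iy[keep] * n + ix[keep]), lengths[keep]


def build_system_matrix(geometry: Geometry, grid_size: int = 128) -> SystemMatrix:
    """Build the sparse Siddon system matrix for a grid of square pixels.

    Pixel (row iy, col ix) occupies the square
    ``[ix-0.5, ix+0.5] x [iy-0.5, iy+0.5]``; flat pixel index is
    ``iy * grid_size + ix``.  The build is deterministic: identical
    inputs give a bit-identical matrix.
    """
    cx, cy = geometry.center
    angles = np.deg2rad(geometry.view_angles_deg)
    offsets = geometry.bin_offsets
    rows, cols, vals = [], [], []
    for k, th in enumerate(angles):
        ux, uy = float(np.cos(th)), float(np.sin(th))
        vx, vy = -uy, ux
        for m, s in enumerate(offsets):
            idx, lengths = _ray_pixel_lengths(cx + s * ux, cy + s * uy, vx, vy,
                                              grid_size)
            if idx.size:
                j = k * geometry.n_bins + m
                rows.append(np.full(idx.size, j, dtype=np.int64))
                cols.append(idx)
                vals.append(lengths)
    n_pix = grid_size * grid_size
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geometry.n_rays, n_pix),
    )
    sensitivity = np.asarray(A.T @ np.ones(geometry.n_rays)).ravel()
    return SystemMatrix(A=A, sensitivity=sensitivity, geometry=geometry,
                        grid_size=grid_size)


_MATRIX_CACHE: dict[tuple, SystemMatrix] = {}


def get_system_matrix(geometry: Geometry, grid_size: int = 128) -> SystemMatrix:
    """Cached :func:`build_system_matrix` (the experiment reuses one matrix
    across hundreds of reconstructions)."""
    key = (geometry.n_views, geometry.n_bins, geometry.angular_range,
           geometry.bin_width, geometry.center, grid_size)
    if key not in _MATRIX_CACHE:
        _MATRIX_CACHE[key] = build_system_matrix(geometry, grid_size)
    return _MATRIX_CACHE[key]


def _flatten_image(sm: SystemMatrix, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x.ravel()
    if x.shape[0] != sm.n_pixels:
        raise ValueError(f"image size {x.shape} does not match {sm.n_pixels} pixels")
    return x


def forward_project(sm: SystemMatrix, x: np.ndarray) -> np.ndarray:
    """Predicted sinogram ``q = A x``.

    Accepts a flat or (n, n) image; returns an (n_views, n_bins) array
    when the operator carries a geometry, else a flat ray vector.
    """
    q = np.asarray(sm.A @ _flatten_image(sm, x)).ravel()
    if sm.geometry is not None:
        return q.reshape(sm.geometry.n_views, sm.geometry.n_bins)
    return q


def back_project(sm: SystemMatrix, y: np.ndarray) -> np.ndarray:
    """Adjoint application ``A^T y``.

    Accepts a sinogram-shaped or flat ray vector; returns an (n, n)
    image when the operator carries a grid size, else a flat vector.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != sm.n_rays:
        raise ValueError(f"sinogram size {y.shape} does not match {sm.n_rays} rays")
    x = np.asarray(sm.A.T @ y).ravel()
    if sm.grid_size is not None:
        return x.reshape(sm.grid_size, sm.grid_size)
    return x
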