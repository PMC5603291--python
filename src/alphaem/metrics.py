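"""Evaluation metrics: MSE on the phantom support, ROI noise, fidelity.

MSE is computed against the rasterized truth over the support region
(pixels whose center lies inside the background ellipse) and normalized
by ``N = n_pixels * scaling_factor``, so values are comparable across
count levels.  The ROI standard deviation measures noise alone (it
ignores bias) in a rectangle of uniform background, normalized by the
scaling factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

#: Default background rectangle: x in [98, 112], y in [58, 70] (inclusive),
#: inside the ellipse and >= 4 px clear of every disc of the default phantom.
DEFAULT_ROI_RECT = (98, 112, 58, 70)


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation setup for one count level.

    ``support`` is a flat or (n, n) boolean mask; ``n_normalizer`` is
    ``n_pixels * scale``; ``roi_rect = (x0, x1, y0, y1)`` inclusive pixel
    bounds of the uniform background rectangle; ``scale`` is the phantom
    scaling factor used to normalize the ROI standard deviation.
    """

    support: np.ndarray
    n_normalizer: float
    scale: float = 1.0
    roi_rect: tuple[int, int, int, int] = DEFAULT_ROI_RECT
    grid_size: int = 128

    def __post_init__(self) -> None:
        if self.n_normalizer <= 0:
            raise ValueError("n_normalizer must be positive")
        x0, x1, y0, y1 = self.roi_rect
        n = self.grid_size
        if not (0 <= x0 <= x1 < n and 0 <= y0 <= y1 < n):
            raise ValueError("roi_rect outside the image grid")
        object.__setattr__(self, "support",
                           np.asarray(self.support, dtype=bool).ravel())
        if not self.support.any():
            raise ValueError("support mask is empty")

    @classmethod
    def for_scale(cls, support: np.ndarray, scale: float,
                  grid_size: int = 128,
                  roi_rect: tuple[int, int, int, int] = DEFAULT_ROI_RECT
                  ) -> "EvalConfig":
        """Standard study configuration: ``N = grid_size**2 * scale``."""
        return cls(support=support, n_normalizer=grid_size * grid_size * scale,
                   scale=scale, roi_rect=roi_rect, grid_size=grid_size)


def mse(recon: np.ndarray, truth: np.ndarray, cfg: EvalConfig) -> float:
    """``(1/N) * sum over support pixels of (x_i - true_i)**2``."""
    r = np.asarray(recon, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    if r.shape != t.shape:
        raise ValueError("recon and truth shapes differ")
    d = r[cfg.support] - t[cfg.support]
    return float(np.sum(d * d) / cfg.n_normalizer)


def roi_stdev(recon: np.ndarray, cfg: EvalConfig) -> float:
    """Sample standard deviation in the background rectangle, divided by
    the phantom scaling factor."""
    n = cfg.grid_size
    img = np.asarray(recon, dtype=float).reshape(n, n)
    x0, x1, y0, y1 = cfg.roi_rect
    vals = img[y0:y1 + 1, x0:x1 + 1]
    return float(np.std(vals, ddof=1) / cfg.scale)


def data_fidelity(x: np.ndarray, p: np.ndarray, sm) -> float:
    """Data-discrepancy error ``sum_j (q_j - p_j)**2`` with ``q = A x``."""
    q = np.asarray(sm.A @ np.asarray(x, dtype=float).ravel()).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if q.shape != p.shape:
        raise ValueError("sinogram size mismatch")
    return float(np.sum((q - p) ** 2))


def central_profile(image: np.ndarray,
                    grid_size: Optional[int] = None) -> np.ndarray:
    """Central horizontal profile: mean of the two middle rows.

    For an even grid (the 128 default) the geometric center line falls
    between rows n/2 - 1 and n/2; their average is returned.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 1:
        if grid_size is None:
            grid_size = int(round(img.size ** 0.5))
        img = img.reshape(grid_size, grid_size)
    n = img.shape[0]
    if n % 2 == 0:
        return 0.5 * (img[n // 2 - 1] + img[n // 2])
    return img[n // 2].astype(float)


def central_profiles(noisy_image: np.ndarray, noiseless_rerun: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Profiles of a noisy reconstruction and its noiseless rerun.

    The rerun uses the noise-free mean sinogram with the same (alpha,
    iteration count), isolating resolution from noise in the comparison.
    """
    a = np.asarray(noisy_image)
    b = np.asarray(noiseless_rerun)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    return central_profile(a), central_profile(b)
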