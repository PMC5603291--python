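"""Seeded Poisson measurement simulation.

Noise is applied to the *analytic* mean sinogram, never to a forward
projection of a rasterized image, so the data-generation model is not
the reconstruction model (no inverse crime).  Each (scale, realization)
stream is an independent generator derived from the master seed, making
every draw exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NoiseLevel:
    """One Poisson noise condition: count scaling factor + stream identity.

    ``scale`` multiplies the mean sinogram; the study uses scales
    {0.1, 1, 10, 100, 1000}, giving expected total counts of roughly
    1e6..1e10 on the calibrated phantom.  ``seed`` is the master seed and
    ``realization_index`` (1-based) selects one of the independent noise
    realizations at this level.
    """

    scale: float
    seed: int = 0
    realization_index: int = 1

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.realization_index < 1:
            raise ValueError("realization_index is 1-based")

    def rng(self) -> np.random.Generator:
        # Distinct stream per (master seed, realization, scale); the scale
        # key uses a decimal fixed-point so 0.1 and 1 do not collide.
        scale_key = int(round(self.scale * 10))
        return np.random.default_rng(
            np.random.SeedSequence((self.seed, self.realization_index, scale_key))
        )


def poisson_measure(mean_sino: np.ndarray, level: NoiseLevel) -> np.ndarray:
    """Draw ``p_j ~ Poisson(scale * qbar_j)`` independently for every ray.

    Returns integer-valued counts as float64 (the EM arithmetic is in
    floating point).  The same :class:`NoiseLevel` always produces the
    same sinogram.
    """
    mean_sino = np.asarray(mean_sino, dtype=float)
    if np.any(mean_sino < 0):
        raise ValueError("mean sinogram must be nonnegative")
    return level.rng().poisson(level.scale * mean_sino).astype(float)


def expected_total(mean_sino: np.ndarray, scale: float) -> float:
    """Expected total count of a measurement: ``scale * sum_j qbar_j``."""
    return float(scale) * float(np.asarray(mean_sino, dtype=float).sum())
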