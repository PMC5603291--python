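"""Tiny deterministic test instances with known solutions.

These toy systems (at most 16 pixels, 24 rays) make brute-force checks
of the EM algebra — fixed points, oracle equivalence of the additive
form, count preservation — run in milliseconds, independently of the
full 128x128 study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projector import SystemMatrix

KINDS = ("identity", "random", "rank_deficient")


@dataclass(frozen=True)
class ToyInstance:
    """A small system with ground truth and exactly consistent data.

    ``p = A @ x_true`` holds exactly unless ``noisy`` was requested, in
    which case Poisson counts are drawn from that consistent sinogram.
    """

    kind: str
    operator: SystemMatrix
    x_true: np.ndarray
    p: np.ndarray
    seed: int


def make_toy(kind: str = "random", seed: int = 0, noisy: bool = False) -> ToyInstance:
    """Deterministic toy instance of the requested kind.

    * ``identity`` — 2 pixels, identity system, x_true = (3, 5): ML-EM
      solves it in a single iteration.
    * ``random`` — 4 pixels, 6 rays, strictly positive weights.
    * ``rank_deficient`` — 9 pixels, 6 rays (underdetermined): fidelity
      converges but the limit image is not unique.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown toy kind {kind!r}; pick from {KINDS}")
    rng = np.random.default_rng(np.random.SeedSequence((seed, KINDS.index(kind))))
    if kind == "identity":
        A = np.eye(2)
        x_true = np.array([3.0, 5.0])
    elif kind == "random":
        # strictly positive, with one dominant ray per pixel so the EM
        # fixed point is approached quickly
        A = rng.uniform(0.05, 0.3, size=(6, 4))
        A[np.arange(4), np.arange(4)] += 1.0
        x_true = rng.uniform(0.5, 4.0, size=4)
    else:
        A = rng.uniform(0.05, 0.3, size=(6, 9))
        A[np.arange(6), np.arange(6)] += 1.0
        x_true = rng.uniform(0.5, 4.0, size=9)
    p = A @ x_true
    if noisy:
        p = rng.poisson(p).astype(float)
    return ToyInstance(kind=kind, operator=SystemMatrix.from_matrix(A),
                       x_true=x_true, p=p, seed=seed)
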