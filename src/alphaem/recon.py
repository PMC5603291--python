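"""Classical ML-EM and the alpha-weighted EM generalization.

The classical ML-EM fixed point for Poisson emission data is

    x_i <- x_i * [sum_j a_ij p_j / q_j] / [sum_j a_ij],    q = A x.

Raising the forward projection in the ratio to a power ``alpha`` gives
the one-parameter family

    x_i <- x_i * [sum_j a_ij p_j / q_j**alpha]
               / [sum_j a_ij q_j / q_j**alpha],

which reduces to ML-EM at alpha = 1 and keeps iterates nonnegative for
every alpha > 0.  Rewriting the update additively shows it is a
variable-step gradient descent on the weighted least-squares objective
``F = sum_j W_j (q_j - p_j)**2`` with per-ray weight ``W_j = 1 /
q_j**alpha`` — i.e. alpha selects the noise model, with alpha = 1 the
nominal Poisson (variance = mean) weighting.  The additive form is
implemented only as a verification oracle; the multiplicative form is
primary because it needs no step-size clipping to stay nonnegative.

The model/results pair (:class:`AlphaEM` / :class:`AlphaEMResults`)
wraps the iteration with per-iteration diagnostics: data fidelity,
Poisson log-likelihood, the weighted objective, and — when a truth image
is supplied — MSE and region-of-interest standard deviation, enabling
MSE-optimal early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .projector import SystemMatrix
from .metrics import EvalConfig, mse as _mse, roi_stdev as _roi_stdev

_EPS_REL = 1e-12  # floor on q, relative to mean(q), guarding 0-division


def _as_flat(y: np.ndarray, n: int, what: str) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != n:
        raise ValueError(f"{what} has size {y.shape[0]}, expected {n}")
    return y


def _safe_q(q: np.ndarray, epsilon: Optional[float]) -> np.ndarray:
    if epsilon is None:
        m = q.mean()
        epsilon = _EPS_REL * m if m > 0 else _EPS_REL
    return np.maximum(q, epsilon)


def mlem_update(x: np.ndarray, p: np.ndarray, sm: SystemMatrix,
                epsilon: Optional[float] = None) -> np.ndarray:
    """One classical ML-EM iteration.

    Rays with a vanishing forward projection use a small positive floor
    (default ``1e-12 * mean(q)``) in the ratio; pixels with zero
    sensitivity stay at zero.
    """
    x = _as_flat(x, sm.n_pixels, "image")
    p = _as_flat(p, sm.n_rays, "sinogram")
    q = _safe_q(np.asarray(sm.A @ x).ravel(), epsilon)
    num = np.asarray(sm.A.T @ (p / q)).ravel()
    out = np.zeros_like(x)
    live = sm.sensitivity > 0
    out[live] = x[live] * num[live] / sm.sensitivity[live]
    return out


def alpha_em_update(x: np.ndarray, p: np.ndarray, sm: SystemMatrix,
                    alpha: float, epsilon: Optional[float] = None) -> np.ndarray:
    """One alpha-weighted EM iteration (multiplicative form).

    ``x_i <- x_i * A^T(p / q**alpha)_i / A^T(q / q**alpha)_i``.  At
    alpha = 1 this is bit-identical to :func:`mlem_update` (IEEE pow
    returns its base exactly at exponent 1, and ``A^T(q/q) = A^T 1`` is
    the stored sensitivity).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if alpha > 5:
        raise ValueError("alpha > 5 is outside the supported range")
    x = _as_flat(x, sm.n_pixels, "image")
    p = _as_flat(p, sm.n_rays, "sinogram")
    q = _safe_q(np.asarray(sm.A @ x).ravel(), epsilon)
    qa = q ** alpha
    num = np.asarray(sm.A.T @ (p / qa)).ravel()
    den = np.asarray(sm.A.T @ (q / qa)).ravel()
    out = np.zeros_like(x)
    live = den > 0
    out[live] = x[live] * num[live] / den[live]
    return out


def additive_form_update(x: np.ndarray, p: np.ndarray, sm: SystemMatrix,
                         alpha: float, epsilon: Optional[float] = None) -> np.ndarray:
    """The algebraically equivalent additive (gradient-descent) form.

    ``x_i <- x_i + [x_i / A^T(q**(1-alpha))_i] * A^T((p - q)/q**alpha)_i``.
    Kept as a numerical oracle: it must agree with
    :func:`alpha_em_update` to floating-point rounding, which the test
    suite asserts on random instances.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    x = _as_flat(x, sm.n_pixels, "image")
    p = _as_flat(p, sm.n_rays, "sinogram")
    q = _safe_q(np.asarray(sm.A @ x).ravel(), epsilon)
    qa = q ** alpha
    den = np.asarray(sm.A.T @ (q / qa)).ravel()
    grad = np.asarray(sm.A.T @ ((p - q) / qa)).ravel()
    out = x.copy()
    live = den > 0
    out[live] = x[live] + (x[live] / den[live]) * grad[live]
    return out


def step_size_field(x: np.ndarray, sm: SystemMatrix, alpha: float,
                    epsilon: Optional[float] = None) -> np.ndarray:
    """Per-pixel step size of the additive form, ``x_i / A^T(q**(1-alpha))_i``."""
    x = _as_flat(x, sm.n_pixels, "image")
    q = _safe_q(np.asarray(sm.A @ x).ravel(), epsilon)
    den = np.asarray(sm.A.T @ (q / q**alpha)).ravel()
    out = np.zeros_like(x)
    live = den > 0
    out[live] = x[live] / den[live]
    return out


def noise_weights(q: np.ndarray, alpha: float,
                  epsilon: Optional[float] = None) -> np.ndarray:
    """Implicit per-ray weights ``W_j = 1 / q_j**alpha`` at the current
    forward projection (they vary from iteration to iteration)."""
    q = _safe_q(np.asarray(q, dtype=float).ravel(), epsilon)
    return 1.0 / q**alpha


def weighted_objective(x: np.ndarray, p: np.ndarray, sm: SystemMatrix,
                       W: np.ndarray) -> float:
    """Weighted least-squares objective ``F = sum_j W_j (q_j - p_j)**2``."""
    W = np.asarray(W, dtype=float).ravel()
    if np.any(W < 0):
        raise ValueError("weights must be nonnegative")
    x = _as_flat(x, sm.n_pixels, "image")
    p = _as_flat(p, sm.n_rays, "sinogram")
    q = np.asarray(sm.A @ x).ravel()
    return float(np.sum(W * (q - p) ** 2))


def poisson_loglikelihood(x: np.ndarray, p: np.ndarray, sm: SystemMatrix,
                          epsilon: Optional[float] = None) -> float:
    """Poisson log-likelihood ``sum_j (p_j ln q_j - q_j)`` up to constants.

    Terms with ``p_j = 0`` contribute ``-q_j`` (``0 ln 0 := 0``); rays
    with ``q_j = 0`` but ``p_j > 0`` use the epsilon floor.  ML-EM must
    not decrease this quantity, which the invariant tests monitor.
    """
    x = _as_flat(x, sm.n_pixels, "image")
    p = _as_flat(p, sm.n_rays, "sinogram")
    q = _safe_q(np.asarray(sm.A @ x).ravel(), epsilon)
    ll = -q.sum()
    pos = p > 0
    ll += float(np.sum(p[pos] * np.log(q[pos])))
    return float(ll)


@dataclass(frozen=True)
class ReconConfig:
    """Iteration settings for :func:`reconstruct`.

    ``init_value`` is the uniform starting activity on in-FOV pixels;
    when None it is chosen so the initial forward projection carries the
    same total counts as the data (a scale-free start).  ``epsilon``
    floors vanishing forward-projection values; None means the relative
    default ``1e-12 * mean(q)`` recomputed each iteration.
    """

    alpha: float = 1.0
    max_iterations: int = 50
    init_value: Optional[float] = None
    epsilon: Optional[float] = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.init_value is not None and self.init_value <= 0:
            raise ValueError("init_value must be positive")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


class AlphaEM:
    """Alpha-weighted EM reconstruction model for one measured sinogram.

    Parameters
    ----------
    sinogram : array
        Measured counts ``p_j``, sinogram-shaped or flat.
    system_matrix : SystemMatrix
        Discrete projector (and its transpose) linking image and rays.
    alpha : float
        Weighting exponent; 1.0 recovers classical ML-EM.
    config : ReconConfig, optional
        Overrides alpha/iteration settings; ``alpha`` here wins if both
        are given and disagree.

    Examples
    --------
    >>> model = AlphaEM(p, sm, alpha=1.5)
    >>> res = model.fit(max_iter=50, truth=truth_img, eval_config=cfg)
    >>> res.best_iteration, res.best_mse
    """

    def __init__(self, sinogram: np.ndarray, system_matrix: SystemMatrix,
                 alpha: float = 1.0, init_value: Optional[float] = None,
                 epsilon: Optional[float] = None):
        self.sm = system_matrix
        self.p = _as_flat(sinogram, system_matrix.n_rays, "sinogram")
        if np.any(self.p < 0):
            raise ValueError("measured counts must be nonnegative")
        self.alpha = float(alpha)
        self.init_value = init_value
        self.epsilon = epsilon

    def initial_image(self) -> np.ndarray:
        """Uniform in-FOV image, scaled to match the measured total counts."""
        x0 = np.zeros(self.sm.n_pixels)
        live = self.sm.fov_mask
        if self.init_value is not None:
            x0[live] = self.init_value
            return x0
        unit = np.zeros(self.sm.n_pixels)
        unit[live] = 1.0
        denom = float(np.asarray(self.sm.A @ unit).sum())
        total = float(self.p.sum())
        x0[live] = (total / denom) if denom > 0 and total > 0 else 1.0
        return x0

    def fit(self, max_iter: int = 50, truth: Optional[np.ndarray] = None,
            eval_config: Optional[EvalConfig] = None,
            store_images: bool = False) -> "AlphaEMResults":
        """Run ``max_iter`` multiplicative updates, recording diagnostics.

        When ``truth`` and ``eval_config`` are given, the trace includes
        per-iteration MSE and ROI standard deviation and the results
        object exposes the MSE-optimal stopping point (the global argmin
        over iterations >= 1).
        """
        sm, p, alpha = self.sm, self.p, self.alpha
        truth_flat = None if truth is None else np.asarray(truth, float).ravel()
        x = self.initial_image()
        rows = []
        images: dict[int, np.ndarray] = {}

        def record(n: int, x: np.ndarray) -> None:
            q = np.asarray(sm.A @ x).ravel()
            row = {
                "iteration": n,
                "fidelity": float(np.sum((q - p) ** 2)),
                "loglik": poisson_loglikelihood(x, p, sm, self.epsilon),
                "objective": weighted_objective(
                    x, p, sm, noise_weights(q, alpha, self.epsilon)),
                "total_counts": float(q.sum()),
            }
            if truth_flat is not None and eval_config is not None:
                row["mse"] = _mse(x, truth_flat, eval_config)
                row["roi_stdev"] = _roi_stdev(x, eval_config)
            rows.append(row)
            if store_images:
                images[n] = x.copy()

        record(0, x)
        for n in range(1, max_iter + 1):
            x = alpha_em_update(x, p, sm, alpha, self.epsilon)
            record(n, x)
        trace = pd.DataFrame(rows).set_index("iteration")
        return AlphaEMResults(model=self, image=x, trace=trace, images=images)


@dataclass
class AlphaEMResults:
    """Fit output: final image, per-iteration trace, stopping diagnostics."""

    model: AlphaEM
    image: np.ndarray
    trace: pd.DataFrame
    images: dict = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return int(self.trace.index.max())

    @property
    def best_iteration(self) -> Optional[int]:
        """Iteration (>= 1) with minimal MSE, or None without a truth image."""
        if "mse" not in self.trace.columns or self.n_iterations < 1:
            return None
        return int(self.trace["mse"].iloc[1:].idxmin())

    @property
    def best_mse(self) -> Optional[float]:
        b = self.best_iteration
        return None if b is None else float(self.trace.loc[b, "mse"])

    def image_grid(self) -> np.ndarray:
        """Final image reshaped to (n, n) when a grid size is known."""
        g = self.model.sm.grid_size
        return self.image.reshape(g, g) if g else self.image

    def summary(self) -> str:
        t = self.trace
        lines = [
            "Alpha-weighted EM reconstruction",
            "=" * 46,
            f"alpha:              {self.model.alpha:g}",
            f"iterations:         {self.n_iterations}",
            f"rays / pixels:      {self.model.sm.n_rays} / {self.model.sm.n_pixels}",
            f"measured counts:    {self.model.p.sum():.6g}",
            f"final fidelity:     {t['fidelity'].iloc[-1]:.6g}",
            f"final loglik:       {t['loglik'].iloc[-1]:.6g}",
        ]
        if self.best_iteration is not None:
            b = self.best_iteration
            lines += [
                f"best iteration:     {b} (MSE-optimal early stop)",
                f"best MSE:           {t.loc[b, 'mse']:.6g}",
            ]
            if "roi_stdev" in t.columns:
                lines.append(f"ROI stdev at best:  {t.loc[b, 'roi_stdev']:.6g}")
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """MSE (if available) and data-fidelity curves vs. iteration."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.trace.iloc[1:]
        ax.semilogy(t.index, t["fidelity"], label="data fidelity")
        if "mse" in t.columns:
            ax2 = ax.twinx()
            ax2.plot(t.index, t["mse"], color="C1", label="MSE")
            ax2.set_ylabel("MSE")
        ax.set_xlabel("iteration")
        ax.set_ylabel("sum of squared residuals")
        ax.legend(loc="upper right")
        return ax


def reconstruct(p: np.ndarray, sm: SystemMatrix, cfg: ReconConfig,
                truth: Optional[np.ndarray] = None,
                eval_config: Optional[EvalConfig] = None,
                store_images: bool = False) -> AlphaEMResults:
    """Functional front end: run the alpha-EM iteration per ``cfg``."""
    model = AlphaEM(p, sm, alpha=cfg.alpha, init_value=cfg.init_value,
                    epsilon=cfg.epsilon)
    return model.fit(max_iter=cfg.max_iterations, truth=truth,
                     eval_config=eval_config, store_images=store_images)
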