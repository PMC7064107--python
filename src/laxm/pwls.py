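"""Penalized weighted least-squares (PWLS) denoising of log projections.

The estimate p minimizes

    Φ(p) = Σ_i (p̂_i − p_i)² / v_i  +  β Σ_i Σ_{j ∈ N_i} w_ij (p_i − p_j)²

where v_i is a per-pixel variance estimate of the measured log projection
p̂, N_i is the four-connectivity neighborhood, and w_ij is an
intensity-difference weight that relaxes smoothing across edges.  The
minimization is carried out by per-pixel Gauss–Seidel sweeps in raster
order with the weights frozen at the start of each sweep, so Φ (with those
weights) is non-increasing within a sweep.

Adopted closed forms (configurable):
  variance   v_i = a_i · exp(p̂_i / η)      (a_i = 0.5, η = 1 by default) —
             proportional to the delta-method variance exp(p)/N0 of a
             log-transformed Poisson transmission measurement, so only the
             relative weighting matters and the global scale is absorbed
             by β;
  weight     w_ij = exp(−(p_i − p_j)² / σ²) (σ = 2 by default).

The unit of processing is one projection image at a fixed rotation angle:
a (v, u) detector image for a full scan stack, degenerating to a 1D
detector row for a single-slice sinogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


@dataclass(frozen=True)
class PWLSConfig:
    beta: float = 1.0          # regularization relaxation parameter
    sigma: float = 2.0         # weight-control parameter of the edge kernel
    a_i: float = 0.5           # variance scale
    eta: float = 1.0           # variance shape
    n_iterations: int = 2      # Gauss-Seidel sweeps
    normalize_variance: bool = True   # divide v by its median so beta ~ 1 works

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")


def estimate_variance(p_hat: np.ndarray, config: PWLSConfig = PWLSConfig()) -> np.ndarray:
    """Per-pixel variance estimate v_i = a_i exp(p̂_i / η) of the measured
    log projection; strictly positive and monotone in p̂."""
    p_hat = np.asarray(p_hat, float)
    if not np.all(np.isfinite(p_hat)):
        raise ValueError("projections must be finite")
    return config.a_i * np.exp(p_hat / config.eta)


def neighbor_weights(p: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Edge weights over 4-neighborhood pairs of a 2D field.

    Returns (w_down, w_right): w_down[i, j] couples p[i, j] with p[i+1, j]
    and w_right[i, j] couples p[i, j] with p[i, j+1].  The symmetric full
    weight field is implied.  Values are exp(−Δp²/σ²) ∈ (0, 1].
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    p = np.asarray(p, float)
    w_down = np.exp(-((p[1:, :] - p[:-1, :]) ** 2) / sigma**2)
    w_right = np.exp(-((p[:, 1:] - p[:, :-1]) ** 2) / sigma**2)
    return w_down, w_right


def pwls_objective(
    p: np.ndarray,
    p_hat: np.ndarray,
    variance: np.ndarray,
    config: PWLSConfig,
    weights: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Value of the PWLS objective Φ(p) for one 2D projection image.

    ``weights`` may be supplied to evaluate Φ with frozen weights; otherwise
    they are computed from ``p`` itself.  Each unordered neighbor pair is
    counted twice (once from each side), matching the double sum.
    """
    p = np.asarray(p, float)
    p_hat = np.asarray(p_hat, float)
    if p.shape != p_hat.shape or p.shape != np.shape(variance):
        raise ValueError("shape mismatch between p, p_hat and variance")
    data = float(np.sum((p_hat - p) ** 2 / variance))
    w_down, w_right = weights if weights is not None else neighbor_weights(p, config.sigma)
    pen = float(np.sum(w_down * (p[1:, :] - p[:-1, :]) ** 2))
    pen += float(np.sum(w_right * (p[:, 1:] - p[:, :-1]) ** 2))
    return data + 2.0 * config.beta * pen


@njit(cache=True)
def _gs_sweep_2d(p, p_hat, inv_v, w_down, w_right, beta):  # pragma: no cover
    nrow, ncol = p.shape
    for i in range(nrow):
        for j in range(ncol):
            num = p_hat[i, j] * inv_v[i, j]
            den = inv_v[i, j]
            if i > 0:
                w = w_down[i - 1, j]
                num += 2.0 * beta * w * p[i - 1, j]
                den += 2.0 * beta * w
            if i < nrow - 1:
                w = w_down[i, j]
                num += 2.0 * beta * w * p[i + 1, j]
                den += 2.0 * beta * w
            if j > 0:
                w = w_right[i, j - 1]
                num += 2.0 * beta * w * p[i, j - 1]
                den += 2.0 * beta * w
            if j < ncol - 1:
                w = w_right[i, j]
                num += 2.0 * beta * w * p[i, j + 1]
                den += 2.0 * beta * w
            p[i, j] = num / den


def _denoise_image(p_hat: np.ndarray, config: PWLSConfig) -> np.ndarray:
    """Run PWLS on one 2D projection image (or a 1D detector row)."""
    p_hat = np.asarray(p_hat, float)
    squeeze = p_hat.ndim == 1
    if squeeze:
        p_hat = p_hat[None, :]
    v = estimate_variance(p_hat, config)
    if config.normalize_variance:
        v = v / np.median(v)
    inv_v = 1.0 / v
    p = p_hat.copy()
    for _ in range(config.n_iterations):
        w_down, w_right = neighbor_weights(p, config.sigma)
        _gs_sweep_2d(p, p_hat, inv_v, w_down, w_right, config.beta)
    return p[0] if squeeze else p


def denoise(p_hat, config: PWLSConfig = PWLSConfig()):
    """PWLS-denoise log projections.

    Accepts a single-slice ``Sinogram`` (each angle's detector row is a 1D
    unit), a 2D array treated the same way, or a 3D projection stack shaped
    (angles, v, u) where each angle's (v, u) detector image is the 2D unit.
    ``n_iterations = 0`` returns the input unchanged.
    """
    from .projection import Sinogram

    if isinstance(p_hat, Sinogram):
        values = np.stack(
            [_denoise_image(row, config)
             if config.n_iterations else row.copy()
             for row in p_hat.values]
        )
        return Sinogram(values=values, geometry=p_hat.geometry, z_index=p_hat.z_index)
    arr = np.asarray(p_hat, float)
    if config.n_iterations == 0:
        return arr.copy()
    if arr.ndim == 2:
        return np.stack([_denoise_image(row, config) for row in arr])
    if arr.ndim == 3:
        return np.stack([_denoise_image(img, config) for img in arr])
    raise ValueError("expected a 2D sinogram or a 3D projection stack")
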