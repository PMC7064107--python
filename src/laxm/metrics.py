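"""Reconstruction quality metrics: RMSE inside the field of view and SSIM.

The field of view is the disk actually covered by the detector at every
rotation angle; the bright lateral-truncation ring sits on its boundary, so
errors are only meaningful inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .phantoms import SliceImage


def _pixels(x) -> np.ndarray:
    return x.pixels if isinstance(x, SliceImage) else np.asarray(x, float)


def fov_mask(shape: tuple[int, int], fov_radius: float) -> np.ndarray:
    """Boolean disk of radius ``fov_radius`` centred on the grid."""
    ny, nx = shape
    y = np.arange(ny) - (ny - 1) / 2.0
    x = np.arange(nx) - (nx - 1) / 2.0
    xx, yy = np.meshgrid(x, y, indexing="xy")
    return xx**2 + yy**2 <= fov_radius**2


def rmse_fov(image, reference, fov_radius: float) -> float:
    """Root-mean-square error over pixels within the FOV disk, µm^-1."""
    img, ref = _pixels(image), _pixels(reference)
    if img.shape != ref.shape:
        raise ValueError(f"shape mismatch {img.shape} vs {ref.shape}")
    mask = fov_mask(img.shape, fov_radius)
    diff = (img - ref)[mask]
    return float(np.sqrt(np.mean(diff**2)))


def ssim(image, reference) -> float:
    """Structural similarity with an 11-tap Gaussian window (σ = 1.5).

    The data range is taken from the reference (max − min); a constant
    reference has no meaningful range and raises.
    """
    img, ref = _pixels(image), _pixels(reference)
    if img.shape != ref.shape:
        raise ValueError(f"shape mismatch {img.shape} vs {ref.shape}")
    data_range = float(ref.max() - ref.min())
    if data_range == 0.0:
        raise ValueError("reference has zero intensity range")
    return float(
        structural_similarity(
            img, ref,
            data_range=data_range,
            gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False,
        )
    )


@dataclass
class EvalReport:
    """Per-slice and mean metrics for one reconstruction method."""

    method: str                       # FBP | FBP_PWLS | UNet | UNet_PWLS
    rmse_per_slice: list = field(default_factory=list)
    ssim_per_slice: list = field(default_factory=list)
    fov_radius: float = 0.0

    def __post_init__(self):
        if any(r < 0 for r in self.rmse_per_slice):
            raise ValueError("RMSE must be >= 0")
        if any(not -1.0 <= s <= 1.0 for s in self.ssim_per_slice):
            raise ValueError("SSIM must lie in [-1, 1]")

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.rmse_per_slice))

    @property
    def mean_ssim(self) -> float:
        return float(np.mean(self.ssim_per_slice))

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "mean_rmse": self.mean_rmse,
            "mean_ssim": self.mean_ssim,
            "rmse_per_slice": list(map(float, self.rmse_per_slice)),
            "ssim_per_slice": list(map(float, self.ssim_per_slice)),
            "fov_radius": self.fov_radius,
        }


def evaluate_slices(
    recon_slices, reference_slices, fov_radius: float, method: str
) -> EvalReport:
    """Per-slice RMSE-in-FOV and SSIM of a reconstruction against its
    analytic reference, with per-volume means."""
    report = EvalReport(method=method, fov_radius=fov_radius)
    for rec, ref in zip(recon_slices, reference_slices, strict=True):
        if _pixels(rec).shape != _pixels(ref).shape:
            raise ValueError("reconstruction and reference grids do not align")
        report.rmse_per_slice.append(rmse_fov(rec, ref, fov_radius))
        report.ssim_per_slice.append(ssim(rec, ref))
    return report
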