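"""Parallel-beam forward model for a limited-angle TXM scan.

Each X-ray measures a line integral of the attenuation map through the
rotated sample.  Line integrals are accumulated in detector-pixel length
units, so the log-transformed projection of a map with values around
10^-2 µm^-1 across a few-hundred-pixel path is of order one — the regime in
which photon statistics at the stated incident counts (10^4 … 10^5) give
realistic transmission noise.

Conventions: the rotation axis is z; for rotation angle θ the detector
coordinate is u = x cosθ + y sinθ (signed distance from the rotation axis,
u = 0 at detector centre), and rays run along (−sinθ, cosθ).  z decouples,
so a 3D scan is a stack of independent 2D slice problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantoms import Ellipse2D, PhantomVolume, SliceImage, cross_sections


@dataclass(frozen=True)
class ScanGeometry:
    """Angle grid and detector of one tomographic scan."""

    theta_start: float = -50.0   # degrees
    theta_end: float = 50.0      # degrees
    angular_step: float = 1.0    # degrees
    detector_size: int = 512     # pixels (u)
    detector_pitch_nm: float = 21.9

    def __post_init__(self):
        if self.theta_start >= self.theta_end:
            raise ValueError("theta_start must be < theta_end")
        if self.detector_size <= 0:
            raise ValueError("detector_size must be positive")
        if self.angular_step <= 0:
            raise ValueError("angular_step must be positive")

    @property
    def angles_deg(self) -> np.ndarray:
        """Inclusive arithmetic grid of rotation angles, degrees."""
        n = int(round((self.theta_end - self.theta_start) / self.angular_step)) + 1
        return self.theta_start + self.angular_step * np.arange(n)

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @property
    def u_coords(self) -> np.ndarray:
        """Signed detector coordinates in pixels, centred on the axis."""
        n = self.detector_size
        return np.arange(n) - (n - 1) / 2.0


@dataclass(frozen=True)
class Sinogram:
    """Log-transformed projections p(θ, u) for one z-slice."""

    values: np.ndarray           # (n_angles, detector_size)
    geometry: ScanGeometry
    z_index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, float))
        expected = (self.geometry.n_angles, self.geometry.detector_size)
        if self.values.shape != expected:
            raise ValueError(
                f"sinogram shape {self.values.shape} != geometry {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")


@dataclass(frozen=True)
class NoiseModel:
    """Transmission Poisson noise at a stated incident photon count."""

    photon_count: float = 1e4    # photons per ray before attenuation
    seed: int = 0

    def __post_init__(self):
        if self.photon_count <= 0:
            raise ValueError("photon_count must be positive")


def _slab_chords(angle_rad: float, u: np.ndarray, half_width: float) -> np.ndarray:
    """Intersection lengths of rays with the square slab |x|,|y| <= W."""
    w = float(half_width)
    cos, sin = np.cos(angle_rad), np.sin(angle_rad)
    # ray: (x, y)(t) = u*(cos, sin) + t*(-sin, cos)
    t_lo = np.full_like(u, -np.inf)
    t_hi = np.full_like(u, np.inf)
    alive = np.ones_like(u, dtype=bool)
    for p0, d in ((u * cos, -sin), (u * sin, cos)):
        if abs(d) < 1e-12:
            alive &= np.abs(p0) <= w
        else:
            t1 = (-w - p0) / d
            t2 = (w - p0) / d
            t_lo = np.maximum(t_lo, np.minimum(t1, t2))
            t_hi = np.minimum(t_hi, np.maximum(t1, t2))
    chord = np.clip(t_hi - t_lo, 0.0, None)
    chord[~alive] = 0.0
    return chord


def ellipse_projection(
    ellipse: Ellipse2D, angle_rad: float, u: np.ndarray
) -> np.ndarray:
    """Closed-form chord-length integral of one ellipse along the rays.

    For the region (r-c)^T M (r-c) <= 1 with intensity ρ the projection at
    detector coordinate u is ρ · 2 sqrt(det M^-1) sqrt(s² − t²) / s² with
    s² = ω^T M^-1 ω and t = u − ω·c.
    """
    if np.linalg.det(ellipse.matrix) <= 0:
        raise ValueError("degenerate ellipse (non-positive-definite matrix)")
    omega = np.array([np.cos(angle_rad), np.sin(angle_rad)])
    Minv = np.linalg.inv(ellipse.matrix)
    s2 = omega @ Minv @ omega
    t = u - omega @ ellipse.center
    under = np.clip(s2 - t * t, 0.0, None)
    return ellipse.intensity * 2.0 * np.sqrt(np.linalg.det(Minv)) * np.sqrt(under) / s2


def analytic_sinogram(
    sections: list[Ellipse2D],
    geometry: ScanGeometry,
    background_intensity: float = 0.0,
    background_extent: float | None = None,
    z_index: int = 0,
) -> Sinogram:
    """Exact sinogram of a set of ellipse cross-sections plus a square
    background slab, linear in all intensities."""
    u = geometry.u_coords
    values = np.zeros((geometry.n_angles, geometry.detector_size))
    for ia, ang in enumerate(np.deg2rad(geometry.angles_deg)):
        row = np.zeros_like(u)
        if background_intensity and background_extent:
            row += background_intensity * _slab_chords(ang, u, background_extent)
        for sec in sections:
            row += ellipse_projection(sec, ang, u)
        values[ia] = row
    return Sinogram(values=values, geometry=geometry, z_index=z_index)


def phantom_slice_sinogram(
    phantom: PhantomVolume, z_index: int, geometry: ScanGeometry
) -> Sinogram:
    """Analytic sinogram of one horizontal phantom slice."""
    n = phantom.spec.grid_size
    if not 0 <= z_index < n:
        raise IndexError(f"z_index {z_index} outside [0, {n})")
    z = z_index - (n - 1) / 2.0
    return analytic_sinogram(
        cross_sections(phantom, z),
        geometry,
        background_intensity=phantom.spec.background_intensity,
        background_extent=phantom.spec.extent,
        z_index=z_index,
    )


def discrete_sinogram(
    image: SliceImage | np.ndarray,
    geometry: ScanGeometry,
    pixel_size: float | None = None,
) -> Sinogram:
    """Discrete projector for images with no analytic form.

    Image-rotation + column-sum scheme with linear interpolation: for each
    angle the image is resampled onto the (u, ray) frame and summed along
    the ray direction with the image's own sample spacing.  The operator is
    linear in the image.

    ``pixel_size`` is the image pixel pitch in detector-pixel units; by
    default the image spans the full detector width.
    """
    img = image.pixels if isinstance(image, SliceImage) else np.asarray(image, float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("discrete projector requires a square image")
    n = img.shape[0]
    s = geometry.detector_size / n if pixel_size is None else float(pixel_size)
    u = geometry.u_coords / s                   # detector coords, image px
    t = np.arange(n) - (n - 1) / 2.0            # ray samples, image px
    uu, tt = np.meshgrid(u, t, indexing="xy")   # rows: t, cols: u
    center = (n - 1) / 2.0
    values = np.empty((geometry.n_angles, geometry.detector_size))
    for ia, ang in enumerate(np.deg2rad(geometry.angles_deg)):
        x = uu * np.cos(ang) - tt * np.sin(ang)
        y = uu * np.sin(ang) + tt * np.cos(ang)
        # img is indexed [row=y, col=x]
        samples = ndimage.map_coordinates(
            img, [y + center, x + center], order=1, mode="constant", cval=0.0
        )
        values[ia] = samples.sum(axis=0) * s
    return Sinogram(values=values, geometry=geometry)


def corrupt(sinogram: Sinogram, noise: NoiseModel) -> Sinogram:
    """Apply transmission Poisson noise and re-take the log transform.

    Counts I ~ Poisson(N0 exp(−p)); the measured log projection is
    p̂ = ln(N0 / max(I, 1)) (zero counts clamped to one photon).
    Deterministic under the noise model's seed.
    """
    p = sinogram.values
    if np.any(p < 0):
        raise ValueError("line integrals must be non-negative before corruption")
    rng = np.random.default_rng(noise.seed)
    counts = rng.poisson(noise.photon_count * np.exp(-p))
    p_hat = np.log(noise.photon_count / np.maximum(counts, 1))
    return Sinogram(values=p_hat, geometry=sinogram.geometry, z_index=sinogram.z_index)
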