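"""Ram–Lak filtered back-projection over a limited angular window.

Each detector row is convolved with the spatial-domain Ram–Lak (ramp)
kernel and smeared back along its ray direction; the angle integral is a
Riemann sum weighted by the angular step in radians, so a full 180° scan
converges to the true attenuation map and a limited window produces the
characteristic missing-wedge artifacts.

Filtering happens at native detector resolution; backprojection linearly
interpolates the filtered rows onto the (typically coarser) reconstruction
grid.  The lateral-truncation ring at the FOV boundary is deliberately not
masked here — it marks the field of view; masking is a metrics concern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from .phantoms import SliceImage
from .projection import ScanGeometry, Sinogram


@dataclass(frozen=True)
class FBPGrid:
    """Reconstruction raster for one slice."""

    out_size: int = 256          # pixels per side
    detector_size: int = 512     # native detector pixels covered by the grid
    detector_pitch_nm: float = 21.9

    def __post_init__(self):
        if self.out_size <= 0:
            raise ValueError("out_size must be positive")

    @property
    def out_pitch_nm(self) -> float:
        return self.detector_pitch_nm * self.detector_size / self.out_size

    @property
    def fov_radius(self) -> float:
        """Circular field of view, in reconstruction pixels."""
        return self.out_size / 2.0

    @property
    def coords(self) -> np.ndarray:
        """Centred pixel coordinates in native detector-pixel units."""
        step = self.detector_size / self.out_size
        return (np.arange(self.out_size) - (self.out_size - 1) / 2.0) * step


@dataclass(frozen=True)
class ReconVolume:
    """Stack of reconstructed slices along z with provenance."""

    slices: np.ndarray           # (n_z, out, out) attenuation, µm^-1
    grid: FBPGrid
    angles_deg: np.ndarray | None = None
    pwls: bool = False

    def __post_init__(self):
        object.__setattr__(self, "slices", np.asarray(self.slices))
        if self.slices.ndim != 3:
            raise ValueError("slices must be a 3D (z, y, x) array")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


def ramlak_kernel(n_taps: int, pitch: float = 1.0) -> np.ndarray:
    """Spatial-domain Ram–Lak taps h(n) for sampling distance ``pitch``.

    Centre tap 1/(4d²), odd offsets −1/(π² n² d²), even nonzero offsets 0.
    ``n_taps`` must be odd so the kernel is centred.
    """
    if n_taps % 2 == 0:
        raise ValueError("n_taps must be odd")
    half = n_taps // 2
    n = np.arange(-half, half + 1)
    taps = np.zeros(n_taps)
    taps[half] = 1.0 / (4.0 * pitch**2)
    odd = n % 2 != 0
    taps[odd] = -1.0 / (np.pi**2 * n[odd] ** 2 * pitch**2)
    return taps


def _wrapped_kernel_fft(n_detector: int, pad: int) -> np.ndarray:
    """rFFT of the Ram–Lak kernel laid out circularly on ``pad`` samples.

    With the projection occupying the first ``n_detector`` samples of the
    zero-padded row, circular convolution with this wrapped kernel equals
    exact linear convolution there (pad >= 2 * n_detector).
    """
    n = np.arange(pad)
    n = np.where(n > pad // 2, n - pad, n)   # signed lags
    h = np.zeros(pad)
    h[0] = 0.25
    odd = n % 2 != 0
    h[odd] = -1.0 / (np.pi**2 * n[odd] ** 2)
    return sp_fft.rfft(h)


def filter_sinogram(sinogram: Sinogram) -> Sinogram:
    """Convolve each detector row with the Ram–Lak kernel.

    Rows are zero-padded to the next power of two >= 2x the detector size
    to suppress circular wrap-around; the operation is linear.
    """
    values = sinogram.values
    n = values.shape[1]
    pad = 1 << int(np.ceil(np.log2(2 * n)))
    H = _wrapped_kernel_fft(n, pad)
    spectra = sp_fft.rfft(values, pad, axis=1)
    filtered = sp_fft.irfft(spectra * H, pad, axis=1)[:, :n]
    return Sinogram(
        values=filtered, geometry=sinogram.geometry, z_index=sinogram.z_index
    )


def backproject(filtered: Sinogram, grid: FBPGrid) -> SliceImage:
    """Smear filtered rows back across the reconstruction grid.

    Pixel value = Δθ(rad) · Σ_angles q_θ(u = x cosθ + y sinθ), with q
    linearly interpolated in u.  Linear in the input sinogram.
    """
    geom = filtered.geometry
    c = grid.coords
    xx, yy = np.meshgrid(c, c, indexing="xy")
    u_det = geom.u_coords
    dtheta = np.deg2rad(geom.angular_step)
    out = np.zeros_like(xx)
    for row, ang in zip(filtered.values, np.deg2rad(geom.angles_deg)):
        u = xx * np.cos(ang) + yy * np.sin(ang)
        out += np.interp(u, u_det, row, left=0.0, right=0.0)
    out *= dtheta
    return SliceImage(
        pixels=out, pixel_pitch_nm=grid.out_pitch_nm, fov_radius=grid.fov_radius
    )


def fbp_slice(sinogram: Sinogram, grid: FBPGrid) -> SliceImage:
    """Filter + backproject one sinogram."""
    return backproject(filter_sinogram(sinogram), grid)


def reconstruct_volume(
    stack: np.ndarray, geometry: ScanGeometry, grid: FBPGrid, pwls: bool = False
) -> ReconVolume:
    """Slice-wise FBP of a full projection stack shaped (angles, v, u).

    Parallel-beam geometry decouples detector rows, so each row v is
    reconstructed independently and stacked along z.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 3:
        raise ValueError("projection stack must be shaped (angles, v, u)")
    slices = np.empty((stack.shape[1], grid.out_size, grid.out_size), np.float32)
    for v in range(stack.shape[1]):
        sino = Sinogram(values=stack[:, v, :], geometry=geometry, z_index=v)
        slices[v] = fbp_slice(sino, grid).pixels
    return ReconVolume(
        slices=slices, grid=grid, angles_deg=geometry.angles_deg, pwls=pwls
    )


def reslice_sagittal(volume: ReconVolume, n_slices: int | None = None) -> ReconVolume:
    """Re-index the (z, y, x) voxel array into sagittal (x, y, z) planes.

    A pure axis permutation — no resampling — so applying it twice (with
    full width) returns the original volume voxel for voxel.  If
    ``n_slices`` is smaller than the x-width, the central planes are kept.
    """
    vol = volume.slices
    width = vol.shape[2]
    n_slices = width if n_slices is None else n_slices
    if n_slices > width:
        raise ValueError(f"n_slices {n_slices} exceeds volume width {width}")
    sag = np.transpose(vol, (2, 1, 0))
    if n_slices < width:
        lo = (width - n_slices) // 2
        sag = sag[lo : lo + n_slices]
    return ReconVolume(
        slices=sag.copy(), grid=volume.grid,
        angles_deg=volume.angles_deg, pwls=volume.pwls,
    )
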