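"""Randomized ellipsoid cell phantoms and surrogate training imagery.

The phantoms emulate a cryo-immobilized unicellular alga: two large
ellipsoids form the outer cell boundary, two middle-sized ellipsoids stand
in for the cup-shaped chloroplast, 20 small ellipsoids mimic lipid bodies,
and 50 high-intensity small ellipsoids represent gold fiducial
nanoparticles.  A constant-intensity slab models the surrounding ice; it is
wider than the detector field of view so that simulated projections are
laterally truncated, as in a real scan.

All geometry lives in voxel units on a grid centred at the origin; the
attenuation values are in inverse micrometres.  Phantoms are analytic
(collections of quadrics), never voxelized: slices and projections are
evaluated in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

CATEGORIES = ("outer", "chloroplast", "lipid", "gold")

DEFAULT_COUNTS = {"outer": 2, "chloroplast": 2, "lipid": 20, "gold": 50}

#: Additive attenuation ranges per category, µm^-1.  Chosen so that typical
#: interior values fill a [0, 0.02] µm^-1 display window; gold fiducials are
#: strictly the brightest structures.
DEFAULT_INTENSITY_RANGES = {
    "outer": (0.002, 0.005),
    "chloroplast": (0.004, 0.008),
    "lipid": (0.006, 0.012),
    "gold": (0.015, 0.020),
}

#: Semi-axis ranges as fractions of the grid size, so phantoms scale down
#: coherently for small test grids.
DEFAULT_SIZE_RANGES = {
    "outer": (0.18, 0.30),
    "chloroplast": (0.08, 0.16),
    "lipid": (0.015, 0.040),
    "gold": (0.004, 0.010),
}

DEFAULT_PIXEL_PITCH_NM = 21.9


class PlacementError(RuntimeError):
    """Rejection sampling failed to place an interior ellipsoid."""

    def __init__(self, category: str, attempts: int):
        super().__init__(
            f"could not place a '{category}' ellipsoid inside the outer "
            f"boundary after {attempts} attempts"
        )
        self.category = category


@dataclass(frozen=True)
class Ellipsoid:
    """One quadric primitive of the additive attenuation function.

    The interior is ``(r - center)^T A (r - center) <= 1`` with
    ``A = R diag(1/a^2) R^T``; points inside contribute ``intensity``.
    """

    center: np.ndarray       # (3,) voxels, grid-centred coordinates
    semi_axes: np.ndarray    # (3,) voxels, all > 0
    rotation: np.ndarray     # (3,) Euler angles (z-y-x intrinsic), radians
    intensity: float         # additive attenuation, µm^-1
    category: str

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))
        object.__setattr__(self, "semi_axes", np.asarray(self.semi_axes, float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))
        if self.center.shape != (3,) or self.semi_axes.shape != (3,):
            raise ValueError("center and semi_axes must be 3-vectors")
        if not np.all(self.semi_axes > 0):
            raise ValueError("semi_axes must be strictly positive")
        if not np.isfinite(self.intensity):
            raise ValueError("intensity must be finite")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("zyx", self.rotation).as_matrix()

    @property
    def quadric(self) -> np.ndarray:
        """3x3 matrix A with interior ``(r-c)^T A (r-c) <= 1``."""
        R = self.rotation_matrix
        return (R / self.semi_axes**2) @ R.T

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for an (..., 3) array of points."""
        w = np.asarray(points, float) - self.center
        return np.einsum("...i,ij,...j->...", w, self.quadric, w) <= 1.0

    def surface_points(self, n: int = 32) -> np.ndarray:
        """Points on the ellipsoid surface (Fibonacci sphere), (n, 3)."""
        k = np.arange(n, dtype=float)
        phi = np.arccos(1 - 2 * (k + 0.5) / n)
        theta = np.pi * (1 + 5**0.5) * k
        dirs = np.stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
            axis=1,
        )
        return self.center + (self.rotation_matrix @ (dirs * self.semi_axes).T).T


@dataclass(frozen=True)
class Ellipse2D:
    """Planar cross-section of an ellipsoid: ``(r-c)^T M (r-c) <= 1``."""

    center: np.ndarray   # (2,)
    matrix: np.ndarray   # (2, 2) symmetric positive definite
    intensity: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        w = np.asarray(points, float) - self.center
        return np.einsum("...i,ij,...j->...", w, self.matrix, w) <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one randomized cell phantom."""

    grid_size: int = 512
    counts: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    background_intensity: float = 0.002   # µm^-1, the "ice"
    background_extent: float | None = None  # half-width of the slab, voxels
    intensity_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_RANGES)
    )
    size_ranges: dict = field(default_factory=lambda: dict(DEFAULT_SIZE_RANGES))
    center_jitter: float = 0.04           # outer-centre jitter, grid fraction
    pixel_pitch_nm: float = DEFAULT_PIXEL_PITCH_NM
    max_attempts: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.grid_size <= 0:
            raise ValueError("grid_size must be positive")
        if self.background_intensity < 0:
            raise ValueError("background_intensity must be >= 0")
        for cat, (lo, hi) in self.intensity_ranges.items():
            if lo > hi:
                raise ValueError(f"intensity range for {cat} has low > high")
        for cat in self.counts:
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
            if self.counts[cat] < 0:
                raise ValueError("counts must be >= 0")

    @property
    def extent(self) -> float:
        """Background slab half-width; default 1.5x the detector half-width."""
        if self.background_extent is not None:
            return float(self.background_extent)
        return 0.75 * self.grid_size


@dataclass(frozen=True)
class SliceImage:
    """A 2D attenuation map (µm^-1) with field-of-view metadata."""

    pixels: np.ndarray
    pixel_pitch_nm: float = DEFAULT_PIXEL_PITCH_NM
    fov_radius: float | None = None   # pixels; None = no circular FOV

    def __post_init__(self):
        object.__setattr__(self, "pixels", np.asarray(self.pixels))
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.fov_radius is not None and self.fov_radius > self.pixels.shape[1] / 2:
            raise ValueError("fov_radius exceeds half the grid width")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class PhantomVolume:
    """Analytic phantom: background slab plus additive ellipsoids."""

    ellipsoids: tuple
    spec: PhantomSpec

    def __post_init__(self):
        golds = [e.intensity for e in self.ellipsoids if e.category == "gold"]
        others = [e.intensity for e in self.ellipsoids if e.category != "gold"]
        if golds and others and min(golds) <= max(others):
            raise ValueError("gold intensity must exceed every non-gold intensity")

    @property
    def voxel_pitch(self) -> float:
        return self.spec.pixel_pitch_nm

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Attenuation at arbitrary (..., 3) points, µm^-1.

        Background plus the sum of intensities of containing ellipsoids;
        zero outside the background slab (laterally, in x and y).
        """
        pts = np.asarray(points, float)
        w = self.spec.extent
        inside = (np.abs(pts[..., 0]) <= w) & (np.abs(pts[..., 1]) <= w)
        out = np.where(inside, self.spec.background_intensity, 0.0)
        for e in self.ellipsoids:
            out = out + np.where(inside & e.contains(pts), e.intensity, 0.0)
        return out


def generate_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Draw one randomized phantom from a spec (seeded, reproducible).

    Outer ellipsoids are placed near the grid centre; chloroplast, lipid and
    gold ellipsoids are placed by rejection sampling inside the union of the
    outer ellipsoids (chloroplasts by centre containment, lipid/gold by full
    surface containment).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.grid_size
    ellipsoids: list[Ellipsoid] = []

    def draw(category: str, center: np.ndarray) -> Ellipsoid:
        lo_s, hi_s = spec.size_ranges[category]
        lo_i, hi_i = spec.intensity_ranges[category]
        return Ellipsoid(
            center=center,
            semi_axes=rng.uniform(lo_s, hi_s, 3) * n,
            rotation=rng.uniform(0.0, 2 * np.pi, 3),
            intensity=float(rng.uniform(lo_i, hi_i)),
            category=category,
        )

    outers = [
        draw("outer", rng.uniform(-spec.center_jitter, spec.center_jitter, 3) * n)
        for _ in range(spec.counts.get("outer", 0))
    ]
    ellipsoids.extend(outers)

    def in_union(points: np.ndarray) -> np.ndarray:
        if not outers:
            return np.zeros(np.shape(points)[:-1], dtype=bool)
        ok = np.zeros(np.shape(points)[:-1], dtype=bool)
        for e in outers:
            ok |= e.contains(points)
        return ok

    # sample candidate centres inside the bounding box of the outer union
    if outers:
        surf = np.concatenate([e.surface_points(64) for e in outers])
        box_lo, box_hi = surf.min(axis=0), surf.max(axis=0)
    else:
        box_lo, box_hi = np.full(3, -n / 2.0), np.full(3, n / 2.0)

    for category, full_containment in (
        ("chloroplast", False),
        ("lipid", True),
        ("gold", True),
    ):
        for _ in range(spec.counts.get(category, 0)):
            for attempt in range(spec.max_attempts):
                center = rng.uniform(box_lo, box_hi)
                if not bool(in_union(center[None])[0]):
                    continue
                e = draw(category, center)
                if not full_containment or bool(np.all(in_union(e.surface_points()))):
                    ellipsoids.append(e)
                    break
            else:
                raise PlacementError(category, spec.max_attempts)

    return PhantomVolume(ellipsoids=tuple(ellipsoids), spec=spec)


def cross_sections(phantom: PhantomVolume, z: float) -> list[Ellipse2D]:
    """Exact 2D ellipse cross-sections of the phantom at height ``z``.

    ``z`` is in grid-centred voxel coordinates.  Ellipsoids the plane misses
    are dropped.
    """
    sections = []
    for e in phantom.ellipsoids:
        A = e.quadric
        w3 = z - e.center[2]
        A2 = A[:2, :2]
        b = A[:2, 2]
        m = -w3 * np.linalg.solve(A2, b)
        k = w3**2 * (A[2, 2] - b @ np.linalg.solve(A2, b))
        if 1.0 - k <= 0.0:
            continue
        sections.append(
            Ellipse2D(
                center=e.center[:2] + m,
                matrix=A2 / (1.0 - k),
                intensity=e.intensity,
            )
        )
    return sections


def grid_coords(out_size: int, grid_size: int) -> np.ndarray:
    """Centred sample coordinates of an ``out_size`` grid spanning the phantom grid."""
    step = grid_size / out_size
    return (np.arange(out_size) - (out_size - 1) / 2.0) * step


def slice_phantom(
    phantom: PhantomVolume, z_index: int, out_size: int | None = None
) -> SliceImage:
    """Analytic evaluation of the phantom on one horizontal plane.

    ``z_index`` indexes the native voxel grid; the plane is rendered on an
    ``out_size`` x ``out_size`` grid spanning the full phantom width (no
    voxel interpolation — every pixel is a point evaluation of f).
    """
    n = phantom.spec.grid_size
    if not 0 <= z_index < n:
        raise IndexError(f"z_index {z_index} outside [0, {n})")
    out_size = out_size or n
    z = z_index - (n - 1) / 2.0
    c = grid_coords(out_size, n)
    xx, yy = np.meshgrid(c, c, indexing="xy")
    w = phantom.spec.extent
    inside = (np.abs(xx) <= w) & (np.abs(yy) <= w)
    img = np.where(inside, phantom.spec.background_intensity, 0.0)
    step = n / out_size
    for sec in cross_sections(phantom, z):
        # bounding box of the ellipse: half-extents sqrt(diag(M^-1))
        Minv = np.linalg.inv(sec.matrix)
        hx, hy = np.sqrt(np.maximum(np.diag(Minv), 0.0))
        i0 = max(0, int(np.floor((sec.center[0] - hx) / step + (out_size - 1) / 2.0)))
        i1 = min(out_size, int(np.ceil((sec.center[0] + hx) / step + (out_size + 1) / 2.0)))
        j0 = max(0, int(np.floor((sec.center[1] - hy) / step + (out_size - 1) / 2.0)))
        j1 = min(out_size, int(np.ceil((sec.center[1] + hy) / step + (out_size + 1) / 2.0)))
        if i0 >= i1 or j0 >= j1:
            continue
        pts = np.stack([xx[j0:j1, i0:i1], yy[j0:j1, i0:i1]], axis=-1)
        img[j0:j1, i0:i1] += np.where(
            inside[j0:j1, i0:i1] & sec.contains(pts), sec.intensity, 0.0
        )
    return SliceImage(
        pixels=img,
        pixel_pitch_nm=phantom.spec.pixel_pitch_nm * step,
        fov_radius=out_size / 2,
    )


def uniform_slice_indices(grid_size: int, n_slices: int = 20) -> np.ndarray:
    """z-indices uniformly spaced over the central 80% of the grid."""
    lo = int(round(0.1 * grid_size))
    hi = int(round(0.9 * grid_size)) - 1
    return np.linspace(lo, hi, n_slices).round().astype(int)


def surrogate_texture_images(
    n: int,
    size: int = 512,
    seed: int = 0,
    attenuation_range: tuple[float, float] = (0.0, 0.02),
    pixel_pitch_nm: float = DEFAULT_PIXEL_PITCH_NM,
) -> list[SliceImage]:
    """Procedurally generated structured images standing in for a
    multi-category photographic/CT image collection.

    Each image mixes randomized overlapping elliptical shapes, a smooth
    large-scale gradient field and fine-grained texture, then rescales to
    the requested attenuation range.  Deterministic under ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    c = np.arange(size) - (size - 1) / 2.0
    xx, yy = np.meshgrid(c, c, indexing="xy")
    lo, hi = attenuation_range
    images = []
    for _ in range(n):
        img = gaussian_filter(rng.standard_normal((size, size)), size / 8.0)
        img = img / (np.abs(img).max() + 1e-12)
        # random linear ramp
        ang = rng.uniform(0, 2 * np.pi)
        ramp = (np.cos(ang) * xx + np.sin(ang) * yy) / size
        img = img + rng.uniform(-1, 1) * ramp
        # overlapping ellipses of varied scale and eccentricity
        for _ in range(rng.integers(6, 16)):
            cx, cy = rng.uniform(-0.45, 0.45, 2) * size
            a, b = rng.uniform(0.02, 0.3, 2) * size
            phi = rng.uniform(0, np.pi)
            u = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
            v = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
            mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            img = img + rng.uniform(-1.0, 1.0) * mask
        # fine texture
        img = img + 0.15 * gaussian_filter(rng.standard_normal((size, size)), 1.0)
        mn, mx = img.min(), img.max()
        img = lo + (hi - lo) * (img - mn) / (mx - mn + 1e-12)
        images.append(
            SliceImage(pixels=img, pixel_pitch_nm=pixel_pitch_nm, fov_radius=None)
        )
    return images


def augment_rotations(images: Sequence[SliceImage]) -> list[SliceImage]:
    """Quarter-turn augmentation: [originals, 90°, 180°, 270°].

    Each rotation is an exact pixel permutation (np.rot90); images must be
    square.
    """
    for im in images:
        if im.pixels.shape[0] != im.pixels.shape[1]:
            raise ValueError("augment_rotations requires square images")
    out = list(images)
    for k in (1, 2, 3):
        out.extend(
            replace(im, pixels=np.rot90(im.pixels, k).copy()) for im in images
        )
    return out


def load_user_images(
    paths: Sequence[str],
    attenuation_range: tuple[float, float] = (0.0, 0.02),
    pixel_pitch_nm: float = DEFAULT_PIXEL_PITCH_NM,
) -> list[SliceImage]:
    """Load user-supplied grayscale images (TIFF/PNG) as attenuation maps.

    Color images are averaged to gray; every image is rescaled to the given
    attenuation range so external collections can fill the multi-category
    role of the training corpus.
    """
    import imageio.v3 as iio

    lo, hi = attenuation_range
    images = []
    for p in paths:
        arr = np.asarray(iio.imread(p), float)
        if arr.ndim == 3:
            arr = arr[..., :3].mean(axis=-1)
        mn, mx = arr.min(), arr.max()
        arr = lo + (hi - lo) * (arr - mn) / (mx - mn + 1e-12)
        images.append(
            SliceImage(pixels=arr, pixel_pitch_nm=pixel_pitch_nm, fov_radius=None)
        )
    return images
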