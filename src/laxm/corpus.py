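"""Training-corpus assembly.

The default recipe: 10 randomized ellipsoid phantoms, 20 uniformly chosen
horizontal slices each, plus 400 procedurally generated multi-category
images — 600 base images — augmented by 90/180/270° quarter turns to 2400.
Limited-angle sinograms (−50°…50°, 1° steps) receive transmission Poisson
noise at a photon level drawn per sample from {1e4, 5e4, 1e5}.  The 600
originals and their 90° rotations are reconstructed by FBP directly from
the noisy projections; the 180° and 270° rotations are reconstructed after
two PWLS iterations — a 1200/1200 split.  Every pair stores the corrupted
reconstruction, its artifact image (reconstruction − reference) and
provenance.

Phantom-slice sinograms are analytic (quarter turns applied to the ellipse
geometry itself); surrogate-image sinograms use the discrete projector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
from skimage.transform import resize

from .fbp import FBPGrid, fbp_slice
from .phantoms import (
    Ellipse2D,
    PhantomSpec,
    SliceImage,
    cross_sections,
    generate_phantom,
    surrogate_texture_images,
    uniform_slice_indices,
)
from .projection import (
    NoiseModel,
    ScanGeometry,
    Sinogram,
    analytic_sinogram,
    corrupt,
    discrete_sinogram,
)
from .pwls import PWLSConfig, denoise

DEFAULT_PHOTON_LEVELS = (1e4, 5e4, 1e5)

_ROT90 = np.array([[0.0, -1.0], [1.0, 0.0]])  # section transform matching np.rot90


def rotate_section(sec: Ellipse2D, k: int) -> Ellipse2D:
    """Rotate an ellipse cross-section by k quarter turns, exactly matching
    what np.rot90(image, k) does to a rendered image of it."""
    S = np.linalg.matrix_power(_ROT90, k % 4)
    return Ellipse2D(
        center=np.linalg.inv(S) @ sec.center,
        matrix=S.T @ sec.matrix @ S,
        intensity=sec.intensity,
    )


@dataclass(frozen=True)
class CorpusConfig:
    n_phantoms: int = 10
    slices_per_phantom: int = 20
    n_surrogate: int = 400
    grid_size: int = 512            # phantom grid == detector size
    out_size: int = 256             # FBP reconstruction size
    geometry: ScanGeometry | None = None   # default: −50..50, 1°, grid_size
    pwls: PWLSConfig = PWLSConfig()
    photon_levels: tuple = DEFAULT_PHOTON_LEVELS
    seed: int = 0

    def scan_geometry(self) -> ScanGeometry:
        return self.geometry or ScanGeometry(detector_size=self.grid_size)


@dataclass
class CorpusManifest:
    """Provenance and arithmetic of one corpus build."""

    n_phantom_slices: int
    n_surrogate: int
    n_base: int
    n_pairs: int
    n_pwls: int
    n_non_pwls: int
    per_rotation: dict = field(default_factory=dict)
    per_photon_level: dict = field(default_factory=dict)
    seed: int = 0
    grid_size: int = 0
    out_size: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class Corpus:
    inputs: np.ndarray       # (N, out, out) float32, corrupted FBP slices
    targets: np.ndarray      # (N, out, out) float32, artifact images
    pwls_flags: np.ndarray   # (N,) bool
    rotations: np.ndarray    # (N,) int, quarter turns
    photon_levels: np.ndarray  # (N,) float
    manifest: CorpusManifest


class _PhantomSliceSource:
    """One base image backed by analytic ellipse sections."""

    def __init__(self, phantom, z_index, out_size):
        self.spec = phantom.spec
        z = z_index - (phantom.spec.grid_size - 1) / 2.0
        self.sections = cross_sections(phantom, z)
        self.reference = SliceImage(
            pixels=_render_sections(
                self.sections, phantom.spec, out_size
            ),
            fov_radius=out_size / 2,
        )

    def sinogram(self, geometry, k):
        secs = [rotate_section(s, k) for s in self.sections]
        return analytic_sinogram(
            secs, geometry,
            background_intensity=self.spec.background_intensity,
            background_extent=self.spec.extent,
        )


def _render_sections(sections, spec, out_size):
    """Analytic rendering of a slice's sections at the output grid."""
    from .phantoms import grid_coords

    n = spec.grid_size
    c = grid_coords(out_size, n)
    xx, yy = np.meshgrid(c, c, indexing="xy")
    w = spec.extent
    inside = (np.abs(xx) <= w) & (np.abs(yy) <= w)
    img = np.where(inside, spec.background_intensity, 0.0)
    pts = np.stack([xx, yy], axis=-1)
    for sec in sections:
        img += np.where(inside & sec.contains(pts), sec.intensity, 0.0)
    return img


class _ImageSource:
    """One base image backed by a pixel raster (surrogate or user image)."""

    def __init__(self, image: SliceImage, out_size):
        self.image = image.pixels
        self.reference = SliceImage(
            pixels=resize(self.image, (out_size, out_size), anti_aliasing=True),
            fov_radius=out_size / 2,
        )

    def sinogram(self, geometry, k):
        return discrete_sinogram(np.rot90(self.image, k), geometry)


def build_corpus(config: CorpusConfig = CorpusConfig(), h5_path=None) -> Corpus:
    """Assemble the training corpus; optionally persist it to HDF5.

    Ordering is rotation-major ([all originals, all 90°, all 180°, all
    270°]); originals and 90° rotations carry pwls_flag = False, 180° and
    270° rotations True.
    """
    rng = np.random.default_rng(config.seed)
    geometry = config.scan_geometry()
    grid = FBPGrid(
        out_size=config.out_size,
        detector_size=geometry.detector_size,
        detector_pitch_nm=geometry.detector_pitch_nm,
    )

    sources = []
    for i in range(config.n_phantoms):
        spec = PhantomSpec(
            grid_size=config.grid_size, seed=int(rng.integers(2**31))
        )
        phantom = generate_phantom(spec)
        for z in uniform_slice_indices(config.grid_size, config.slices_per_phantom):
            sources.append(_PhantomSliceSource(phantom, z, config.out_size))
    n_phantom_slices = len(sources)
    for im in surrogate_texture_images(
        config.n_surrogate, size=config.grid_size, seed=int(rng.integers(2**31))
    ):
        sources.append(_ImageSource(im, config.out_size))

    n_base = len(sources)
    inputs, targets, flags, rots, photons = [], [], [], [], []
    for k in range(4):
        use_pwls = k >= 2
        for src in sources:
            sino = src.sinogram(geometry, k)
            level = float(config.photon_levels[rng.integers(len(config.photon_levels))])
            noisy = corrupt(sino, NoiseModel(level, seed=int(rng.integers(2**31))))
            if use_pwls:
                noisy = denoise(noisy, config.pwls)
            recon = fbp_slice(noisy, grid)
            ref = np.rot90(src.reference.pixels, k)
            inputs.append(recon.pixels.astype(np.float32))
            targets.append((recon.pixels - ref).astype(np.float32))
            flags.append(use_pwls)
            rots.append(k)
            photons.append(level)

    inputs = np.stack(inputs)
    targets = np.stack(targets)
    flags = np.array(flags)
    rots = np.array(rots)
    photons = np.array(photons)
    manifest = CorpusManifest(
        n_phantom_slices=n_phantom_slices,
        n_surrogate=n_base - n_phantom_slices,
        n_base=n_base,
        n_pairs=len(inputs),
        n_pwls=int(flags.sum()),
        n_non_pwls=int((~flags).sum()),
        per_rotation={str(k): int((rots == k).sum()) for k in range(4)},
        per_photon_level={
            f"{lvl:g}": int((photons == lvl).sum()) for lvl in config.photon_levels
        },
        seed=config.seed,
        grid_size=config.grid_size,
        out_size=config.out_size,
    )
    corpus = Corpus(
        inputs=inputs, targets=targets, pwls_flags=flags,
        rotations=rots, photon_levels=photons, manifest=manifest,
    )
    if h5_path is not None:
        save_corpus_h5(h5_path, corpus)
    return corpus


def save_corpus_h5(path, corpus: Corpus) -> None:
    import json

    with h5py.File(path, "w") as f:
        g = f.create_group("pairs")
        g.create_dataset("input", data=corpus.inputs, compression="gzip")
        g.create_dataset("target", data=corpus.targets, compression="gzip")
        meta = g.create_group("meta")
        meta.create_dataset("pwls_flag", data=corpus.pwls_flags)
        meta.create_dataset("rotation", data=corpus.rotations)
        meta.create_dataset("photon_level", data=corpus.photon_levels)
        f.attrs["manifest"] = json.dumps(corpus.manifest.as_dict())


def load_corpus_h5(path) -> Corpus:
    import json

    with h5py.File(path, "r") as f:
        manifest = CorpusManifest(**json.loads(f.attrs["manifest"]))
        return Corpus(
            inputs=f["pairs/input"][:],
            targets=f["pairs/target"][:],
            pwls_flags=f["pairs/meta/pwls_flag"][:].astype(bool),
            rotations=f["pairs/meta/rotation"][:],
            photon_levels=f["pairs/meta/photon_level"][:],
            manifest=manifest,
        )
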