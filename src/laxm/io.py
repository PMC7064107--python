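"""File I/O: HDF5 projection stacks and corpora, TIFF images and volumes,
YAML/JSON configuration."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .phantoms import PhantomSpec, PhantomVolume, Ellipsoid, SliceImage
from .projection import ScanGeometry, Sinogram


def load_config(path) -> dict:
    """Read a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def phantom_spec_from_config(cfg: dict) -> PhantomSpec:
    return PhantomSpec(**cfg)


def save_phantom_h5(path, phantom: PhantomVolume) -> None:
    """Store phantom geometry (not a voxelization) to HDF5."""
    with h5py.File(path, "w") as f:
        g = f.create_group("ellipsoids")
        g.create_dataset("center", data=np.array([e.center for e in phantom.ellipsoids]))
        g.create_dataset(
            "semi_axes", data=np.array([e.semi_axes for e in phantom.ellipsoids])
        )
        g.create_dataset(
            "rotation", data=np.array([e.rotation for e in phantom.ellipsoids])
        )
        g.create_dataset(
            "intensity", data=np.array([e.intensity for e in phantom.ellipsoids])
        )
        g.create_dataset(
            "category",
            data=np.array([e.category for e in phantom.ellipsoids], dtype="S16"),
        )
        f.attrs["grid_size"] = phantom.spec.grid_size
        f.attrs["background_intensity"] = phantom.spec.background_intensity
        f.attrs["background_extent"] = phantom.spec.extent
        f.attrs["pixel_pitch_nm"] = phantom.spec.pixel_pitch_nm
        f.attrs["seed"] = phantom.spec.seed


def load_phantom_h5(path) -> PhantomVolume:
    with h5py.File(path, "r") as f:
        g = f["ellipsoids"]
        ells = tuple(
            Ellipsoid(
                center=c, semi_axes=a, rotation=r, intensity=float(i),
                category=cat.decode(),
            )
            for c, a, r, i, cat in zip(
                g["center"][:], g["semi_axes"][:], g["rotation"][:],
                g["intensity"][:], g["category"][:],
            )
        )
        spec = PhantomSpec(
            grid_size=int(f.attrs["grid_size"]),
            background_intensity=float(f.attrs["background_intensity"]),
            background_extent=float(f.attrs["background_extent"]),
            pixel_pitch_nm=float(f.attrs["pixel_pitch_nm"]),
            seed=int(f.attrs["seed"]),
        )
    return PhantomVolume(ellipsoids=ells, spec=spec)


def save_stack_h5(path, values: np.ndarray, geometry: ScanGeometry) -> None:
    """Projection stack or single-slice sinogram with geometry attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=values, compression="gzip")
        f.create_dataset("angles", data=geometry.angles_deg)
        f.attrs["theta_start"] = geometry.theta_start
        f.attrs["theta_end"] = geometry.theta_end
        f.attrs["angular_step"] = geometry.angular_step
        f.attrs["detector_size"] = geometry.detector_size
        f.attrs["detector_pitch_nm"] = geometry.detector_pitch_nm


def load_stack_h5(path) -> tuple[np.ndarray, ScanGeometry]:
    with h5py.File(path, "r") as f:
        values = f["values"][:]
        geometry = ScanGeometry(
            theta_start=float(f.attrs["theta_start"]),
            theta_end=float(f.attrs["theta_end"]),
            angular_step=float(f.attrs["angular_step"]),
            detector_size=int(f.attrs["detector_size"]),
            detector_pitch_nm=float(f.attrs["detector_pitch_nm"]),
        )
    return values, geometry


def save_sinogram_h5(path, sinogram: Sinogram) -> None:
    save_stack_h5(path, sinogram.values, sinogram.geometry)


def load_sinogram_h5(path) -> Sinogram:
    values, geometry = load_stack_h5(path)
    return Sinogram(values=values, geometry=geometry)


def save_tiff(path, image_or_stack, pixel_pitch_nm: float | None = None) -> None:
    """32-bit float TIFF; 2D images single page, 3D stacks multi-page
    (ordered by the leading axis)."""
    if isinstance(image_or_stack, SliceImage):
        if pixel_pitch_nm is None:
            pixel_pitch_nm = image_or_stack.pixel_pitch_nm
        arr = image_or_stack.pixels
    else:
        arr = np.asarray(image_or_stack)
    meta = {"pixel_pitch_nm": pixel_pitch_nm} if pixel_pitch_nm else None
    tifffile.imwrite(path, arr.astype(np.float32), metadata=meta)


def load_tiff(path) -> np.ndarray:
    return tifffile.imread(path)
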