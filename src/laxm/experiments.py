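"""End-to-end study drivers.

Two canonical experiments:

* :func:`fbp_phantom_rmse` — generate one seeded test phantom, simulate the
  limited-angle scan with transmission Poisson noise, reconstruct every
  horizontal slice by Ram–Lak FBP and average the RMSE inside the FOV
  against the analytic reference slices (the plain-FBP quality figure).

* :func:`desk_experiment` — a scaled-down version of the full training
  study (small grid, shallow network, short schedule) that trains the
  artifact network on a fresh corpus and evaluates FBP, FBP+PWLS, U-Net
  and U-Net+PWLS on a held-out phantom.  It exercises every stage of the
  pipeline on one CPU in minutes; docs/methods.md discusses what this
  miniature does and does not demonstrate.
"""

from __future__ import annotations

import numpy as np

from .corpus import CorpusConfig, build_corpus
from .fbp import FBPGrid, fbp_slice
from .metrics import EvalReport, rmse_fov, ssim
from .nn import TrainConfig, UNetConfig, predict_clean, train
from .phantoms import PhantomSpec, generate_phantom, slice_phantom, uniform_slice_indices
from .projection import NoiseModel, ScanGeometry, corrupt, phantom_slice_sinogram
from .pwls import PWLSConfig, denoise


def fbp_phantom_rmse(
    seed: int,
    grid_size: int = 512,
    out_size: int = 256,
    photon_count: float = 1e4,
    pwls: PWLSConfig | None = None,
    n_slices: int | None = None,
    with_ssim: bool = False,
) -> dict:
    """Mean RMSE-in-FOV of slice-wise FBP over a fresh seeded test phantom.

    The phantom follows the default recipe (2 outer + 2 chloroplast +
    20 lipid + 50 gold ellipsoids over a constant 0.002 µm^-1 slab); the
    scan covers −50°…50° in 1° steps on a ``grid_size`` detector; noise is
    Poisson at ``photon_count`` incident photons per ray.  All
    ``grid_size`` slices are reconstructed at ``out_size``² unless
    ``n_slices`` limits them (uniformly spread, for quick looks).
    """
    rng = np.random.default_rng(seed)
    phantom = generate_phantom(
        PhantomSpec(grid_size=grid_size, seed=int(rng.integers(2**31)))
    )
    geometry = ScanGeometry(detector_size=grid_size)
    grid = FBPGrid(out_size=out_size, detector_size=grid_size)
    if n_slices is None:
        z_indices = np.arange(grid_size)
    else:
        z_indices = np.unique(
            np.linspace(0, grid_size - 1, n_slices).round().astype(int)
        )
    rmse, ssims = [], []
    for z in z_indices:
        sino = phantom_slice_sinogram(phantom, int(z), geometry)
        noisy = corrupt(sino, NoiseModel(photon_count, seed=int(rng.integers(2**31))))
        if pwls is not None:
            noisy = denoise(noisy, pwls)
        recon = fbp_slice(noisy, grid)
        ref = slice_phantom(phantom, int(z), out_size)
        rmse.append(rmse_fov(recon, ref, grid.fov_radius))
        if with_ssim:
            r = ref.pixels
            ssims.append(ssim(recon, ref) if r.max() > r.min() else 1.0)
    out = {
        "mean_rmse": float(np.mean(rmse)),
        "rmse_per_slice": rmse,
        "n_slices": len(z_indices),
        "grid_size": grid_size,
        "out_size": out_size,
        "photon_count": photon_count,
        "pwls": pwls is not None,
    }
    if with_ssim:
        out["mean_ssim"] = float(np.mean(ssims))
    return out


DESK_CORPUS = dict(
    n_phantoms=2, slices_per_phantom=10, n_surrogate=30,
    grid_size=64, out_size=64,
)
DESK_NET = UNetConfig(depth=2, base_channels=8, se_reduction=4)
DESK_TRAIN = dict(
    epochs=50, lr_plateau_epochs=40, batch_size=4, val_fraction=0.05,
)


def desk_experiment(
    seed: int,
    n_eval_slices: int = 10,
    eval_photon_count: float = 1e4,
    verbose: bool = False,
) -> dict:
    """Scaled-down four-method study: train on a small fresh corpus, then
    evaluate FBP / FBP+PWLS / U-Net / U-Net+PWLS on a held-out phantom.

    Returns {"reports": {method: EvalReport}, "log": training log,
    "manifest": corpus manifest}.
    """
    corpus = build_corpus(CorpusConfig(seed=seed, **DESK_CORPUS))
    net, norm_constant, log = train(
        corpus.inputs, corpus.targets,
        net_config=DESK_NET,
        train_config=TrainConfig(seed=seed, **DESK_TRAIN),
        verbose=verbose,
    )

    rng = np.random.default_rng(seed + 1)
    grid_size = DESK_CORPUS["grid_size"]
    phantom = generate_phantom(
        PhantomSpec(grid_size=grid_size, seed=int(rng.integers(2**31)))
    )
    geometry = ScanGeometry(detector_size=grid_size)
    grid = FBPGrid(out_size=DESK_CORPUS["out_size"], detector_size=grid_size)
    pwls_cfg = PWLSConfig()

    reports = {
        m: EvalReport(method=m, fov_radius=grid.fov_radius)
        for m in ("FBP", "FBP_PWLS", "UNet", "UNet_PWLS")
    }
    for z in uniform_slice_indices(grid_size, n_eval_slices):
        sino = phantom_slice_sinogram(phantom, int(z), geometry)
        noisy = corrupt(
            sino, NoiseModel(eval_photon_count, seed=int(rng.integers(2**31)))
        )
        ref = slice_phantom(phantom, int(z), grid.out_size)
        if ref.pixels.max() == ref.pixels.min():
            continue   # slice misses the cell: SSIM undefined on a constant
        variants = {
            "FBP": fbp_slice(noisy, grid),
            "FBP_PWLS": fbp_slice(denoise(noisy, pwls_cfg), grid),
        }
        variants["UNet"] = predict_clean(variants["FBP"], net, norm_constant)
        variants["UNet_PWLS"] = predict_clean(variants["FBP_PWLS"], net, norm_constant)
        for m, img in variants.items():
            reports[m].rmse_per_slice.append(rmse_fov(img, ref, grid.fov_radius))
            reports[m].ssim_per_slice.append(ssim(img, ref))
    return {"reports": reports, "log": log, "manifest": corpus.manifest}
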