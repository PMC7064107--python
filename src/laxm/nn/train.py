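"""Training and inference for the artifact-prediction network.

The network regresses the artifact image (corrupted reconstruction minus
reference) from the corrupted reconstruction; at inference the predicted
artifact is subtracted from the input.  All images are scaled into [-1, 1]
by one shared constant — the maximum absolute intensity over the training
inputs — which is stored with the model.

Optimization is Adam on a mean-squared-error loss with L2 weight
regularization on convolution weights.  The learning rate holds its
starting value for a plateau of epochs and then decays geometrically to
its final value at the last epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..phantoms import SliceImage
from .layers import Adam
from .unet import ArtifactUNet, UNetConfig


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 500
    lr_start: float = 1e-3
    lr_end: float = 1e-5
    lr_plateau_epochs: int = 100
    l2_weight: float = 1e-4
    batch_size: int = 4
    seed: int = 0
    val_fraction: float = 0.05     # 0 disables the held-out validation split

    def __post_init__(self):
        if not self.lr_start >= self.lr_end > 0:
            raise ValueError("need lr_start >= lr_end > 0")
        if self.epochs < self.lr_plateau_epochs:
            raise ValueError("epochs must be >= lr_plateau_epochs")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must be in [0, 1)")


def learning_rate(epoch: int, config: TrainConfig) -> float:
    """LR at a 1-based epoch: plateau then geometric decay to lr_end."""
    if epoch <= config.lr_plateau_epochs:
        return config.lr_start
    frac = (epoch - config.lr_plateau_epochs) / (config.epochs - config.lr_plateau_epochs)
    return float(config.lr_start * (config.lr_end / config.lr_start) ** frac)


def normalize(images) -> tuple[np.ndarray, float]:
    """Scale a set of images into [-1, 1] by the set's max |intensity|.

    Returns (scaled array, norm_constant); dividing by the constant is
    exactly invertible, so denormalization is multiplication.
    """
    arr = np.stack(
        [im.pixels if isinstance(im, SliceImage) else np.asarray(im) for im in images]
    ).astype(np.float64)
    if arr.size == 0:
        raise ValueError("empty image set")
    if not np.all(np.isfinite(arr)):
        raise ValueError("images must be finite")
    c = float(np.abs(arr).max())
    if c == 0.0:
        raise ValueError("all-zero image set has no usable scale")
    return (arr / c).astype(np.float32), c


def train(
    inputs: np.ndarray,
    targets: np.ndarray,
    net_config: UNetConfig = UNetConfig(),
    train_config: TrainConfig = TrainConfig(),
    norm_constant: float | None = None,
    verbose: bool = False,
) -> tuple[ArtifactUNet, float, list[dict]]:
    """Train the artifact network on (input, artifact) image pairs.

    ``inputs`` and ``targets`` are (N, H, W) stacks in physical units; one
    shared norm_constant (computed from the inputs unless given) scales
    both.  Returns (network, norm_constant, per-epoch log).
    """
    inputs = np.asarray(inputs, np.float64)
    targets = np.asarray(targets, np.float64)
    if inputs.ndim != 3 or inputs.shape != targets.shape:
        raise ValueError("inputs and targets must be matching (N, H, W) stacks")
    if inputs.shape[0] == 0:
        raise ValueError("empty training set")
    if norm_constant is None:
        norm_constant = float(np.abs(inputs).max())
        if norm_constant == 0.0:
            raise ValueError("all-zero training inputs")
    x_all = (inputs / norm_constant).astype(np.float32)[:, None]
    y_all = (targets / norm_constant).astype(np.float32)[:, None]

    rng = np.random.default_rng(train_config.seed)
    n = x_all.shape[0]
    n_val = int(round(train_config.val_fraction * n))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("validation split leaves no training samples")

    net = ArtifactUNet(net_config, seed=train_config.seed)
    opt = Adam(net.layers(), lr=train_config.lr_start,
               weight_decay=train_config.l2_weight)
    log = []
    bs = train_config.batch_size
    for epoch in range(1, train_config.epochs + 1):
        opt.lr = learning_rate(epoch, train_config)
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), bs):
            idx = order[start : start + bs]
            xb, yb = x_all[idx], y_all[idx]
            pred = net.forward(xb, training=True)
            resid = pred - yb
            losses.append(float(np.mean(resid**2)))
            net.backward((2.0 / resid.size) * resid.astype(np.float32))
            opt.step()
        entry = {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses))}
        if n_val:
            pred = net.predict(x_all[val_idx])
            entry["val_loss"] = float(np.mean((pred - y_all[val_idx]) ** 2))
        log.append(entry)
        if verbose:
            print(f"epoch {epoch:4d}  lr {opt.lr:.2e}  loss {entry['train_loss']:.3e}")
    return net, norm_constant, log


def predict_artifact(image, net: ArtifactUNet, norm_constant: float) -> np.ndarray:
    if norm_constant <= 0:
        raise ValueError("norm_constant must be positive")
    pix = image.pixels if isinstance(image, SliceImage) else np.asarray(image)
    out = net.predict((pix / norm_constant).astype(np.float32)[None, None])
    return out[0, 0].astype(np.float64) * norm_constant


def predict_clean(image, net: ArtifactUNet, norm_constant: float):
    """Subtract the predicted artifact from a corrupted reconstruction."""
    artifact = predict_artifact(image, net, norm_constant)
    if isinstance(image, SliceImage):
        return SliceImage(
            pixels=image.pixels - artifact,
            pixel_pitch_nm=image.pixel_pitch_nm,
            fov_radius=image.fov_radius,
        )
    return np.asarray(image) - artifact
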