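"""Modified U-Net that regresses the limited-angle artifact image.

An encoder–decoder with skip concatenations where each stage is a
zero-padded 3x3 convolution -> ReLU -> batch normalization ->
squeeze-and-excitation block, down-sampling is 2x2 max pooling, and
up-sampling is bilinear x2 followed by a 2x2 convolution (a
transposed-convolution decoder is available for checkerboard-artifact
comparisons).  The final 1x1 convolution emits the one-channel artifact
image with no output activation; spatial size is preserved end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .layers import (
    Adam,
    BatchNorm2D,
    BilinearUp2,
    Conv2D,
    MaxPool2,
    ReLU,
    SEBlock,
    TransposedConv2x2,
)


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 4                 # number of down-sampling levels
    base_channels: int = 64        # channels at the first level, doubling down
    se_reduction: int = 16
    in_channels: int = 1
    upsample: str = "bilinear"     # "bilinear" | "transposed"

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.upsample not in ("bilinear", "transposed"):
            raise ValueError("upsample must be 'bilinear' or 'transposed'")


class _ConvBlock:
    """conv3x3 -> ReLU -> BN -> SE, spatial size preserved."""

    def __init__(self, in_ch, out_ch, reduction, rng):
        self.layers = [
            Conv2D(in_ch, out_ch, kernel=3, rng=rng),
            ReLU(),
            BatchNorm2D(out_ch),
            SEBlock(out_ch, reduction=reduction, rng=rng),
        ]

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class _Upsample:
    """bilinear x2 + 2x2 conv, or a single transposed 2x2 conv."""

    def __init__(self, in_ch, out_ch, mode, rng):
        if mode == "bilinear":
            self.layers = [BilinearUp2(), Conv2D(in_ch, out_ch, kernel=2, rng=rng)]
        else:
            self.layers = [TransposedConv2x2(in_ch, out_ch, rng=rng)]

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class ArtifactUNet:
    """The artifact-prediction network.

    ``forward`` maps a (B, 1, H, W) batch (H, W divisible by 2**depth) to a
    (B, 1, H, W) artifact batch.  Two instances built with the same seed
    have bitwise-identical initial parameters.
    """

    def __init__(self, config: UNetConfig = UNetConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = [config.base_channels * 2**l for l in range(config.depth + 1)]
        r = config.se_reduction
        self.enc = []
        in_ch = config.in_channels
        for l in range(config.depth):
            self.enc.append(
                [_ConvBlock(in_ch, ch[l], r, rng), _ConvBlock(ch[l], ch[l], r, rng)]
            )
            in_ch = ch[l]
        self.pools = [MaxPool2() for _ in range(config.depth)]
        self.bottleneck = [
            _ConvBlock(ch[config.depth - 1], ch[config.depth], r, rng),
            _ConvBlock(ch[config.depth], ch[config.depth], r, rng),
        ]
        self.ups = []
        self.dec = []
        for l in reversed(range(config.depth)):
            self.ups.append(_Upsample(ch[l + 1], ch[l], config.upsample, rng))
            self.dec.append(
                [_ConvBlock(2 * ch[l], ch[l], r, rng), _ConvBlock(ch[l], ch[l], r, rng)]
            )
        self.head = Conv2D(ch[0], 1, kernel=1, rng=rng)

    # -- graph orchestration ------------------------------------------------

    def _all_blocks(self):
        for level in self.enc:
            yield from level
        yield from self.bottleneck
        for up in self.ups:
            yield up
        for level in self.dec:
            yield from level

    def layers(self):
        """Flat list of parameterized layers."""
        out = []
        for block in self._all_blocks():
            out.extend(block.layers)
        out.append(self.head)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for l in self.layers() for p in l.params.values())

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        x = np.asarray(x)
        if not np.issubdtype(x.dtype, np.floating):
            x = x.astype(np.float32)
        if x.ndim != 4:
            raise ValueError("expected a (batch, channel, H, W) array")
        d = 2**self.config.depth
        if x.shape[2] % d or x.shape[3] % d:
            raise ValueError(
                f"spatial size {x.shape[2:]} not divisible by 2**depth = {d}"
            )
        skips = []
        for level, pool in zip(self.enc, self.pools):
            for block in level:
                x = block.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        for block in self.bottleneck:
            x = block.forward(x, training)
        self._skip_channels = []
        for up, level, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, training)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            for block in level:
                x = block.forward(x, training)
        return self.head.forward(x, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.head.backward(dy)
        dskips = []
        for up, level, c in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            for block in reversed(level):
                dy = block.backward(dy)
            dskips.append(dy[:, :c])
            dy = up.backward(dy[:, c:])
        for block in reversed(self.bottleneck):
            dy = block.backward(dy)
        # dskips is ordered [level 0, ..., level depth-1] (decoder runs
        # shallow-last); pair it with the encoder walked deepest-first
        for level, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            dy = pool.backward(dy) + dskip
            for block in reversed(level):
                dy = block.backward(dy)
        return dy

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode forward pass (running BN statistics, no caching
        side effects that alter results; a pure function of x)."""
        return self.forward(x, training=False)

    # -- persistence --------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, l in enumerate(self.layers()):
            for k, v in l.params.items():
                state[f"layer{i}:{k}"] = v
            if isinstance(l, BatchNorm2D):
                state[f"layer{i}:running_mean"] = l.running_mean
                state[f"layer{i}:running_var"] = l.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self.layers()):
            for k in l.params:
                l.params[k][...] = state[f"layer{i}:{k}"]
            if isinstance(l, BatchNorm2D):
                l.running_mean = np.asarray(state[f"layer{i}:running_mean"])
                l.running_var = np.asarray(state[f"layer{i}:running_var"])


def save_checkpoint(path, net: ArtifactUNet, norm_constant: float, seed: int = 0):
    """Persist network weights together with the config, the normalization
    constant needed at inference, and the training seed."""
    meta = json.dumps(
        {"config": asdict(net.config), "norm_constant": float(norm_constant),
         "seed": int(seed)}
    )
    np.savez_compressed(path, __meta__=np.array(meta), **net.state_arrays())


def load_checkpoint(path) -> tuple[ArtifactUNet, float]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        net = ArtifactUNet(UNetConfig(**meta["config"]))
        net.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return net, meta["norm_constant"]
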