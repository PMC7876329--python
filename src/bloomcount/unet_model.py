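"""Fully-convolutional encoder-decoder density regressor.

The network maps an RGB patch to a single-channel nonnegative density map
of the same spatial size. Encoder stages apply two conv-BN-ReLU blocks and
a 2x2/stride-2 max-pool each, channel widths doubling per stage; the
decoder mirrors them with 2x2 transposed-conv upsampling and skip
concatenation; a final 1x1 convolution with ReLU produces the density
channel. Being fully convolutional, trained weights accept any input whose
height and width are divisible by ``2**depth``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .nn import Adam, BatchNorm2d, Conv2d, ConvTranspose2d, MaxPool2d, ReLU


@dataclass
class ModelSpec:
    """Architecture hyperparameters of the density regressor."""

    depth: int = 4
    base_channels: int = 64
    input_channels: int = 3
    output_channels: int = 1

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.input_channels != 3:
            raise ValueError("input_channels must be 3 (RGB)")
        if self.output_channels != 1:
            raise ValueError("output_channels must be 1 (density)")


class _ConvBlock:
    """conv 3x3 -> batch norm -> ReLU."""

    def __init__(self, c_in, c_out, rng, dtype):
        self.conv = Conv2d(c_in, c_out, 3, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(c_out, dtype=dtype)
        self.relu = ReLU()

    def forward(self, x, train=False):
        return self.relu.forward(
            self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))

    def layers(self):
        return [self.conv, self.bn]


class UNet:
    """Density regressor; see module docstring for the architecture."""

    def __init__(self, spec: ModelSpec, *, seed: int = 0,
                 dtype=np.float32) -> None:
        spec.validate()
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        d, b = spec.depth, spec.base_channels

        self.enc: list[tuple[_ConvBlock, _ConvBlock]] = []
        self.pools: list[MaxPool2d] = []
        c = spec.input_channels
        for i in range(d):
            ch = b * 2 ** i
            self.enc.append((_ConvBlock(c, ch, rng, dtype),
                             _ConvBlock(ch, ch, rng, dtype)))
            self.pools.append(MaxPool2d())
            c = ch
        ch = b * 2 ** d
        self.bottleneck = (_ConvBlock(c, ch, rng, dtype),
                           _ConvBlock(ch, ch, rng, dtype))
        c = ch

        self.ups: list[ConvTranspose2d] = []
        self.dec: list[tuple[_ConvBlock, _ConvBlock]] = []
        for i in reversed(range(d)):
            ch = b * 2 ** i
            self.ups.append(ConvTranspose2d(c, ch, rng=rng, dtype=dtype))
            self.dec.append((_ConvBlock(2 * ch, ch, rng, dtype),
                             _ConvBlock(ch, ch, rng, dtype)))
            c = ch
        self.head = Conv2d(c, spec.output_channels, 1, rng=rng, dtype=dtype)
        self.head_relu = ReLU()

    # -- graph ------------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, H, W, 3) float in [0, 1] -> (N, H, W, 1) density."""
        div = 2 ** self.spec.depth
        if x.shape[1] % div or x.shape[2] % div:
            raise ValueError(
                f"input spatial dims {x.shape[1]}x{x.shape[2]} must be "
                f"divisible by {div} (2**depth)")
        skips = []
        for (blk1, blk2), pool in zip(self.enc, self.pools):
            x = blk2.forward(blk1.forward(x, train), train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck[1].forward(
            self.bottleneck[0].forward(x, train), train)
        for up, (blk1, blk2), skip in zip(self.ups, self.dec,
                                          reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=3)
            x = blk2.forward(blk1.forward(x, train), train)
        return self.head_relu.forward(self.head.forward(x, train), train)

    def backward(self, dy: np.ndarray) -> None:
        dy = self.head.backward(self.head_relu.backward(dy))
        dskips = []
        for up, (blk1, blk2) in zip(reversed(self.ups), reversed(self.dec)):
            dy = blk1.backward(blk2.backward(dy))
            ch = dy.shape[3] // 2
            dskips.append(dy[..., :ch])
            dy = up.backward(np.ascontiguousarray(dy[..., ch:]))
        dy = self.bottleneck[0].backward(self.bottleneck[1].backward(dy))
        for (blk1, blk2), pool, dskip in zip(reversed(self.enc),
                                             reversed(self.pools),
                                             reversed(dskips)):
            dy = pool.backward(dy) + dskip
            dy = blk1.backward(blk2.backward(dy))

    # -- parameters -------------------------------------------------------

    def layers(self):
        out = []
        for blk1, blk2 in self.enc:
            out += blk1.layers() + blk2.layers()
        out += self.bottleneck[0].layers() + self.bottleneck[1].layers()
        for up, (blk1, blk2) in zip(self.ups, self.dec):
            out.append(up)
            out += blk1.layers() + blk2.layers()
        out.append(self.head)
        return out

    def make_optimizer(self, lr=1e-3, beta1=0.9, beta2=0.99,
                       weight_decay=1e-5) -> Adam:
        return Adam(self.layers(), lr=lr, beta1=beta1, beta2=beta2,
                    weight_decay=weight_decay)

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, lyr in enumerate(self.layers()):
            for k, v in lyr.params().items():
                out[f"l{i}.{k}"] = v.copy()
            for k, v in lyr.state().items():
                out[f"l{i}.{k}"] = v.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, lyr in enumerate(self.layers()):
            for k, v in lyr.params().items():
                np.copyto(v, weights[f"l{i}.{k}"])
            for k in lyr.state():
                setattr(lyr, k, weights[f"l{i}.{k}"].copy())


def build_model(spec: ModelSpec, *, seed: int = 0) -> UNet:
    """Construct a freshly initialized density regressor."""
    return UNet(spec, seed=seed)


def predict_density(model: UNet, rgb_patch: np.ndarray) -> np.ndarray:
    """Run inference on one RGB patch (H, W, 3), uint8 or [0, 1] float.

    Returns the (H, W) float32 density map. Height and width must be
    divisible by ``2**depth``; normalization layers run in evaluation mode
    so the output is deterministic for fixed weights.
    """
    div = 2 ** model.spec.depth
    h, w = rgb_patch.shape[:2]
    if h % div or w % div:
        raise ValueError(
            f"patch dims {h}x{w} must be divisible by {div} (2**depth)")
    x = normalize_input(rgb_patch)[None]
    return model.forward(x, train=False)[0, :, :, 0]


def normalize_input(rgb: np.ndarray) -> np.ndarray:
    """8-bit RGB -> float32 in [0, 1]; floats pass through as float32."""
    if rgb.dtype == np.uint8:
        return rgb.astype(np.float32) / 255.0
    return rgb.astype(np.float32, copy=False)


# -- persistence ----------------------------------------------------------

def save_checkpoint(model: UNet, path, *, metadata: dict | None = None):
    """Write weights as .npz plus a YAML sidecar with spec and metadata.

    The sidecar records everything inference needs to match training:
    the architecture, input normalization, and the sigma/gamma/delta used
    when the checkpoint was produced (if given in ``metadata``).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.get_weights())
    side = {"model_spec": asdict(model.spec),
            "normalization": "rgb8_to_unit",
            **(metadata or {})}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(side))


def load_checkpoint(path) -> tuple[UNet, dict]:
    """Load a checkpoint written by :func:`save_checkpoint`."""
    path = Path(path)
    side = yaml.safe_load(path.with_suffix(".yaml").read_text())
    model = UNet(ModelSpec(**side["model_spec"]))
    with np.load(path.with_suffix(".npz")) as npz:
        model.set_weights(dict(npz))
    return model, side
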