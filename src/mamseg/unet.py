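"""The segmentation U-Net: encoder-decoder with bilinear upsampling.

The network follows the classic U-Net layout.  Each encoder scale applies
two 3x3 convolutions (ReLU) and a 2x2 max pool; filter counts start at
``base_filters`` and double per scale, e.g. [64, 128, 256, 512, 1024] for
the default depth-4 / base-64 configuration.  Each decoder scale applies
bilinear x2 upsampling, a 1x1 convolution halving the filters, channel
concatenation with the matching encoder skip, and two 3x3 convolutions.
The head is dropout -> 1x1 convolution to the class count -> per-pixel
softmax over the three classes (background, breast, pectoral muscle).

Convolutions are same-padded so the output segmentation has the input's
spatial size; arbitrary input sizes are handled by zero-padding to the next
multiple of 2**depth and cropping the prediction back.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._nn import Adam, BilinearUp2, Conv2d, Dropout, MaxPool2, ReLU
from .image_io import LabelGrid

__all__ = ["UNetConfig", "SegmentationModel", "build_unet",
           "predict_probabilities", "predict_labels", "softmax_channels"]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    depth: number of down/upsampling scales; base_filters: filters at the
    first scale (doubled per scale); classes: output channels; dropout_prob:
    dropout before the final 1x1 convolution; conv_kernel: spatial kernel of
    the double-convolution blocks.
    """

    depth: int = 4
    base_filters: int = 64
    classes: int = 3
    dropout_prob: float = 0.5
    conv_kernel: int = 3
    in_channels: int = 1

    def __post_init__(self):
        if self.depth < 1 or self.base_filters < 1 or self.classes < 2:
            raise ValueError("invalid architecture configuration")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")

    @property
    def encoder_filters(self) -> list[int]:
        """Filter counts per scale, bottleneck included."""
        return [self.base_filters * 2 ** s for s in range(self.depth + 1)]


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the channel axis of (N, C, H, W)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _DoubleConv:
    """conv(k) -> ReLU -> conv(k) -> ReLU."""

    def __init__(self, cin, cout, k, rng):
        self.c1, self.r1 = Conv2d(cin, cout, k, rng), ReLU()
        self.c2, self.r2 = Conv2d(cout, cout, k, rng), ReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x, train=True):
        x = self.r1.forward(self.c1.forward(x, train), train)
        return self.r2.forward(self.c2.forward(x, train), train)

    def backward(self, d):
        d = self.c2.backward(self.r2.backward(d))
        return self.c1.backward(self.r1.backward(d))


class SegmentationModel:
    """A built U-Net with explicit forward/backward passes."""

    def __init__(self, config: UNetConfig, rng: np.random.Generator):
        self.config = config
        f = config.encoder_filters
        k = config.conv_kernel
        self.enc = []
        cin = config.in_channels
        for s in range(config.depth):
            self.enc.append(_DoubleConv(cin, f[s], k, rng))
            cin = f[s]
        self.pools = [MaxPool2() for _ in range(config.depth)]
        self.bottleneck = _DoubleConv(cin, f[config.depth], k, rng)
        self.ups, self.reduce, self.reduce_act, self.dec = [], [], [], []
        for s in reversed(range(config.depth)):
            self.ups.append(BilinearUp2())
            self.reduce.append(Conv2d(f[s + 1], f[s], 1, rng))
            self.reduce_act.append(ReLU())
            self.dec.append(_DoubleConv(2 * f[s], f[s], k, rng))
        self.dropout = Dropout(config.dropout_prob)
        self.head = Conv2d(f[0], config.classes, 1, rng)
        self._concat_split = None

    # -- parameter plumbing -------------------------------------------------
    def params(self):
        out = []
        for blk in self.enc:
            out += blk.params()
        out += self.bottleneck.params()
        for r, blk in zip(self.reduce, self.dec):
            out += r.params() + blk.params()
        out += self.head.params()
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params())

    def make_optimizer(self, lr: float = 1e-4) -> Adam:
        return Adam(self.params(), lr=lr)

    # -- forward / backward -------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = True,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits for a (N, C, H, W) batch; H and W must be multiples of
        2**depth (use :func:`predict_probabilities` for arbitrary sizes)."""
        d = self.config.depth
        if x.shape[2] % 2 ** d or x.shape[3] % 2 ** d:
            raise ValueError(f"spatial size must be a multiple of {2 ** d}")
        x = x.astype(self.head.w.dtype, copy=False)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._concat_split = []
        for up, red, act, blk, skip in zip(self.ups, self.reduce, self.reduce_act,
                                           self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = act.forward(red.forward(x, train), train)
            self._concat_split.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x, train)
        x = self.dropout.forward(x, train, rng=rng)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        d = self.dropout.backward(self.head.backward(dlogits))
        dskips = []
        for blk, red, act, up, nskip in zip(reversed(self.dec), reversed(self.reduce),
                                            reversed(self.reduce_act), reversed(self.ups),
                                            reversed(self._concat_split)):
            d = blk.backward(d)
            dskip, d = d[:, :nskip], d[:, nskip:]
            dskips.append(dskip)
            d = up.backward(red.backward(act.backward(d)))
        d = self.bottleneck.backward(d)
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            d = pool.backward(d)
            d = blk.backward(d + dskip)

    # -- persistence ---------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p for i, (p, _) in enumerate(self.params())}

    def save(self, path: str | Path) -> None:
        """Save weights (npz) with the config embedded alongside (json)."""
        path = Path(path)
        np.savez(path, **self.state_arrays())
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationModel":
        path = Path(path)
        cfg = UNetConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(cfg, np.random.default_rng(0))
        data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        for i, (p, _) in enumerate(model.params()):
            p[:] = data[f"p{i}"]
        return model


def build_unet(config: UNetConfig = UNetConfig(), seed: int = 0) -> SegmentationModel:
    """Build a U-Net with Kaiming-uniform initialized weights."""
    return SegmentationModel(config, np.random.default_rng(seed))


def predict_probabilities(model: SegmentationModel, intensity: np.ndarray) -> np.ndarray:
    """Per-pixel class probabilities for a single 2-D intensity grid.

    The input is zero-padded to the next multiple of 2**depth, run through
    the network in inference mode (dropout off) and cropped back, so the
    output is (classes, H, W) for any input size.
    """
    x = np.asarray(intensity, dtype=np.float32)
    if x.ndim != 2:
        raise ValueError("intensity must be a 2-D grid")
    if not np.all(np.isfinite(x)):
        raise ValueError("intensity must be finite")
    h, w = x.shape
    m = 2 ** model.config.depth
    ph, pw = (-h) % m, (-w) % m
    xp = np.pad(x, ((0, ph), (0, pw)))[None, None]
    logits = model.forward_logits(xp, train=False)
    probs = softmax_channels(logits)[0, :, :h, :w]
    return probs


def predict_labels(model: SegmentationModel, intensity: np.ndarray) -> LabelGrid:
    """Argmax decode of :func:`predict_probabilities`.

    numpy's argmax takes the first maximum, which realizes the tie rule
    "lower class index wins".
    """
    probs = predict_probabilities(model, intensity)
    return LabelGrid(labels=np.argmax(probs, axis=0).astype(np.uint8))
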