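"""Compact U-Net encoder–decoder with an exposed encoder-feature hook.

The network F = D∘E maps a single-channel image to per-pixel class
probabilities; the deepest encoder stage ("bottleneck") doubles as the
latent representation h = E(x) used by the contrastive consistency term.
Each stage is two 3×3 conv → batch-norm → ReLU blocks; downsampling is 2×2
max-pooling, upsampling nearest-neighbour followed by a channel-halving
convolution, with skip connections by concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["NetworkConfig", "UNet"]


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    num_classes: int = 4
    base_width: int = 16
    depth: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_width < 4:
            raise ValueError("base_width must be >= 4")


class _ConvBNReLU:
    """3×3 convolution + batch norm + ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str):
        scale = np.sqrt(2.0 / (cin * 9))  # He initialisation
        self.w = ad.Parameter(rng.normal(0.0, scale, size=(cout, cin, 3, 3)).astype(np.float32))
        self.b = ad.Parameter(np.zeros(cout, dtype=np.float32))
        self.gamma = ad.Parameter(np.ones(cout, dtype=np.float32))
        self.beta = ad.Parameter(np.zeros(cout, dtype=np.float32))
        self.running_mean = np.zeros(cout, dtype=np.float32)
        self.running_var = np.ones(cout, dtype=np.float32)
        self.name = name

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        x = ad.conv2d(x, self.w, self.b, padding=1)
        x = ad.batch_norm2d(x, self.gamma, self.beta,
                            self.running_mean, self.running_var, training)
        return x.relu()

    def params(self) -> dict:
        return {f"{self.name}.w": self.w, f"{self.name}.b": self.b,
                f"{self.name}.gamma": self.gamma, f"{self.name}.beta": self.beta}

    def buffers(self) -> dict:
        return {f"{self.name}.running_mean": self.running_mean,
                f"{self.name}.running_var": self.running_var}

    def set_buffer(self, key: str, value: np.ndarray) -> None:
        tail = key.rsplit(".", 1)[1]
        getattr(self, tail)[...] = value


class UNet:
    """Encoder–decoder segmentation network.

    ``forward`` returns softmax probability maps (B, C, H, W) and the
    bottleneck encoder features (B, d, h', w') as autodiff tensors;
    ``predict_proba`` is the NumPy-facing evaluation-mode convenience.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w0 = config.base_width
        self.enc: list[tuple[_ConvBNReLU, _ConvBNReLU]] = []
        cin = config.in_channels
        widths = [w0 * 2 ** i for i in range(config.depth)]
        for i, cw in enumerate(widths):
            self.enc.append((
                _ConvBNReLU(cin, cw, rng, f"enc{i}a"),
                _ConvBNReLU(cw, cw, rng, f"enc{i}b"),
            ))
            cin = cw
        self.dec: list[tuple[_ConvBNReLU, _ConvBNReLU, _ConvBNReLU]] = []
        for i in range(config.depth - 2, -1, -1):
            cw = widths[i]
            self.dec.append((
                _ConvBNReLU(widths[i + 1], cw, rng, f"up{i}"),     # after upsample
                _ConvBNReLU(2 * cw, cw, rng, f"dec{i}a"),          # after skip concat
                _ConvBNReLU(cw, cw, rng, f"dec{i}b"),
            ))
        scale = np.sqrt(2.0 / widths[0])
        self.head_w = ad.Parameter(
            rng.normal(0.0, scale, size=(config.num_classes, widths[0], 1, 1)).astype(np.float32))
        self.head_b = ad.Parameter(np.zeros(config.num_classes, dtype=np.float32))

    # ---- parameter bookkeeping -----------------------------------------

    def _blocks(self):
        for pair in self.enc:
            yield from pair
        for triple in self.dec:
            yield from triple

    def parameters(self) -> dict:
        out = {}
        for blk in self._blocks():
            out.update(blk.params())
        out["head.w"] = self.head_w
        out["head.b"] = self.head_b
        return out

    def buffers(self) -> dict:
        out = {}
        for blk in self._blocks():
            out.update(blk.buffers())
        return out

    def load_arrays(self, params: dict, buffers: dict | None = None) -> None:
        own = self.parameters()
        for k, v in params.items():
            own[k].data[...] = v
        if buffers:
            blocks = {blk.name: blk for blk in self._blocks()}
            for k, v in buffers.items():
                blocks[k.rsplit(".", 1)[0]].set_buffer(k, v)

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    # ---- forward passes -------------------------------------------------

    def _check_input(self, x: np.ndarray | Tensor) -> Tensor:
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        if t.ndim == 3:  # (B, H, W) -> (B, 1, H, W)
            t = t.reshape(t.shape[0], 1, t.shape[1], t.shape[2])
        mult = 2 ** (self.config.depth - 1)
        _, _, h, w = t.shape
        if h % mult or w % mult:
            raise ValueError(
                f"spatial dims must be multiples of {mult} for depth "
                f"{self.config.depth}, got {h}x{w}")
        return t

    def encode(self, x, training: bool = True) -> Tensor:
        """Bottleneck features only (for contrastive views)."""
        t = self._check_input(x)
        for i, (a, b) in enumerate(self.enc):
            if i > 0:
                t = ad.max_pool2d(t)
            t = b(a(t, training), training)
        return t

    def forward(self, x, training: bool = True) -> tuple[Tensor, Tensor]:
        """Full pass: (probability maps (B, C, H, W), bottleneck features)."""
        t = self._check_input(x)
        skips = []
        for i, (a, b) in enumerate(self.enc):
            if i > 0:
                t = ad.max_pool2d(t)
            t = b(a(t, training), training)
            skips.append(t)
        feats = t
        for (up, da, db), skip in zip(self.dec, reversed(skips[:-1])):
            t = up(ad.upsample_nearest2x(t), training)
            t = ad.concatenate([skip, t], axis=1)
            t = db(da(t, training), training)
        logits = ad.conv2d(t, self.head_w, self.head_b, padding=0)
        probs = ad.softmax(logits, axis=1)
        return probs, feats

    def predict_proba(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Evaluation-mode forward on a (B, H, W) image stack.

        Returns probability maps (B, H, W, C) and pooled-ready encoder
        features (B, h', w', d), both plain NumPy.
        """
        with ad.no_grad():
            probs, feats = self.forward(images, training=False)
        return (probs.data.transpose(0, 2, 3, 1),
                feats.data.transpose(0, 2, 3, 1))

    # ---- checkpointing ---------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"param:{k}": v.data for k, v in self.parameters().items()}
        arrays.update({f"buffer:{k}": v for k, v in self.buffers().items()})
        arrays["config"] = np.array([
            self.config.in_channels, self.config.num_classes,
            self.config.base_width, self.config.depth, self.config.seed,
        ])
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path) -> "UNet":
        with np.load(Path(path)) as z:
            cfg = z["config"].astype(int)
            net = cls(NetworkConfig(in_channels=int(cfg[0]), num_classes=int(cfg[1]),
                                    base_width=int(cfg[2]), depth=int(cfg[3]),
                                    seed=int(cfg[4])))
            params = {k[6:]: z[k] for k in z.files if k.startswith("param:")}
            buffers = {k[7:]: z[k] for k in z.files if k.startswith("buffer:")}
        net.load_arrays(params, buffers)
        return net

    def copy(self) -> "UNet":
        twin = UNet(self.config)
        twin.load_arrays({k: v.data.copy() for k, v in self.parameters().items()},
                         {k: v.copy() for k, v in self.buffers().items()})
        return twin
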