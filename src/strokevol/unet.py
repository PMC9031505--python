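"""Symmetric encoder-decoder (U-Net) segmentation models in 2D and 3D.

Both dimensionalities share one implementation: encoder levels of
(convolution, batch normalization, ReLU) x 2 followed by 2x max pooling, a
mirrored decoder with 2x up-convolution and skip concatenation from the
matching encoder level, and a final 1x1(x1) convolution with a sigmoid that
yields a per-voxel lesion probability.  The indirect (slice-wise) model is
the 2D variant with three input channels (previous/current/next slice); the
direct model is the 3D variant applied to patches.

Public inputs and outputs are channels-first, ``(batch, channels, *spatial)``;
the spatial size of the output always equals that of the input.
"""

from __future__ import annotations


import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import BatchNorm, Conv, MaxPool2, Param, ReLU, UpConv2, sigmoid

__all__ = ["UNetConfig", "UNet", "save_checkpoint", "load_checkpoint"]


class ShapeError(ValueError):
    """Input spatial shape incompatible with the configured depth."""


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    ``depth`` counts encoder levels including the bottleneck; spatial input
    sizes must be divisible by ``2**(depth-1)``.  ``input_channels`` is 3 for
    the indirect (adjacent-slice) model and 1 for the direct 3D model.
    """

    dimensionality: int = 2
    depth: int = 3
    base_channels: int = 8
    input_channels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimensionality not in (2, 3):
            raise ValueError(f"dimensionality must be 2 or 3, got {self.dimensionality}")
        if self.depth < 2:
            raise ValueError(f"depth must be >= 2, got {self.depth}")
        if self.base_channels < 4:
            raise ValueError(f"base_channels must be >= 4, got {self.base_channels}")
        if self.input_channels < 1:
            raise ValueError("input_channels must be >= 1")


class _DoubleConv:
    """(conv 3^nd -> batch norm -> ReLU) twice."""

    def __init__(self, in_ch, out_ch, ndim, rng):
        self.layers = [
            Conv(in_ch, out_ch, ndim, rng), BatchNorm(out_ch), ReLU(),
            Conv(out_ch, out_ch, ndim, rng), BatchNorm(out_ch), ReLU(),
        ]

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class UNet:
    """Encoder-decoder segmentation network emitting per-voxel probabilities."""

    def __init__(self, config: UNetConfig):
        self.config = config
        nd = config.dimensionality
        rng = np.random.default_rng(config.seed)
        ch = [config.base_channels * 2**i for i in range(config.depth)]

        self.enc_blocks = []
        in_ch = config.input_channels
        for c in ch:
            self.enc_blocks.append(_DoubleConv(in_ch, c, nd, rng))
            in_ch = c
        self.pools = [MaxPool2(nd) for _ in range(config.depth - 1)]
        self.upconvs = []
        self.dec_blocks = []
        for i in range(config.depth - 2, -1, -1):
            self.upconvs.append(UpConv2(ch[i + 1], ch[i], nd, rng))
            self.dec_blocks.append(_DoubleConv(2 * ch[i], ch[i], nd, rng))
        self.head = Conv(ch[0], 1, nd, rng, kernel=1)
        self._cache = None

    # -- parameters -------------------------------------------------------
    def params(self) -> list[Param]:
        out = []
        for block in self.enc_blocks + self.dec_blocks:
            out.extend(block.params())
        for up in self.upconvs:
            out.extend(up.params())
        out.extend(self.head.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    # -- forward / backward ----------------------------------------------
    def _check_shape(self, x: np.ndarray) -> None:
        nd = self.config.dimensionality
        if x.ndim != nd + 2:
            raise ShapeError(
                f"expected (batch, channels, {'x'.join(['S'] * nd)}) input, got shape {x.shape}"
            )
        if x.shape[1] != self.config.input_channels:
            raise ShapeError(
                f"expected {self.config.input_channels} channels, got {x.shape[1]}"
            )
        div = 2 ** (self.config.depth - 1)
        for s in x.shape[2:]:
            if s % div:
                raise ShapeError(
                    f"spatial size {s} not divisible by 2**(depth-1)={div}"
                )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map a channels-first batch to probabilities of the same spatial shape."""
        self._check_shape(x)
        h = np.ascontiguousarray(
            np.moveaxis(x, 1, -1), dtype=np.float32
        )  # channels-last internally
        skips = []
        for i, block in enumerate(self.enc_blocks):
            h = block.forward(h, train)
            if i < len(self.pools):
                skips.append(h)
                h = self.pools[i].forward(h, train)
        for up, block in zip(self.upconvs, self.dec_blocks):
            h = up.forward(h, train)
            skip = skips.pop()
            h = np.concatenate([skip, h], axis=-1)
            h = block.forward(h, train)
        z = self.head.forward(h, train)
        p = sigmoid(z)
        if train:
            self._cache = p
        return np.moveaxis(p, -1, 1)

    def backward(self, dprobs: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dprobabilities."""
        p = self._cache
        d = np.ascontiguousarray(np.moveaxis(dprobs, 1, -1), dtype=np.float32)
        d = d * p * (1.0 - p)  # through the sigmoid
        d = self.head.backward(d)
        dskips = []  # dskips[i] is the gradient into encoder level i's skip
        for up, block in zip(self.upconvs[::-1], self.dec_blocks[::-1]):
            d = block.backward(d)
            c = d.shape[-1] // 2
            dskip, dup = d[..., :c], d[..., c:]
            dskips.append(dskip)
            d = up.backward(dup)
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            if i < len(self.pools):
                d = self.pools[i].backward(d)
                d = d + dskips[i]
            d = self.enc_blocks[i].backward(d)

    # -- (de)serialization -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        for i, layer in enumerate(self._bn_layers()):
            state[f"bn_{i}_mean"] = layer.running_mean
            state[f"bn_{i}_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            val = state[f"param_{i}"]
            if val.shape != p.value.shape:
                raise ValueError(f"checkpoint mismatch at param_{i}: {val.shape} vs {p.value.shape}")
            p.value = val.astype(np.float32)
        for i, layer in enumerate(self._bn_layers()):
            layer.running_mean = state[f"bn_{i}_mean"].astype(np.float32)
            layer.running_var = state[f"bn_{i}_var"].astype(np.float32)

    def _bn_layers(self) -> list[BatchNorm]:
        out = []
        for block in self.enc_blocks + self.dec_blocks:
            out.extend(l for l in block.layers if isinstance(l, BatchNorm))
        return out

    def load_pretrained(self, state: dict[str, np.ndarray], strict: bool = False) -> list[str]:
        """Hook for externally produced weights (transfer learning).

        Loads every array whose name and shape match the current model and
        returns the names that were skipped; with ``strict`` any mismatch
        raises.  No pretrained weights ship with the package.
        """
        own = self.state_arrays()
        skipped = []
        loadable = {}
        for name, val in state.items():
            if name in own and own[name].shape == val.shape:
                loadable[name] = val
            else:
                skipped.append(name)
        if strict and skipped:
            raise ValueError(f"pretrained state mismatch: {skipped}")
        merged = dict(own)
        merged.update(loadable)
        self.load_state_arrays(merged)
        return skipped


def save_checkpoint(path: str | Path, model: UNet, extra: dict | None = None) -> Path:
    """Single-file checkpoint: parameters plus embedded JSON metadata."""
    path = Path(path)
    meta = {"unet_config": asdict(model.config), "extra": extra or {}}
    arrays = model.state_arrays()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> tuple[UNet, dict]:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = UNet(UNetConfig(**meta["unet_config"]))
        model.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta.get("extra", {})
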