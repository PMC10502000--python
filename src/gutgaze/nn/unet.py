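"""Dual-output U-net: 4-class segmentation softmax + non-negative diameter head.

The encoder halves every spatial dimension per level while doubling the
channel count; the decoder mirrors it with nearest-neighbour upsampling and
skip concatenation between levels of equal shape.  Each block is
conv-relu-conv-relu-batchnorm-dropout plus its pooling/upsampling layer, and
the block count is twice the number of levels (14 blocks for the 2d
reference configuration with 7 levels, 10 for the 3d one with 5).  Two 1x1
heads read the full-resolution features: segmentation logits (softmax over 4
classes including background) and a softplus diameter output, which
guarantees non-negative diameters with smooth gradients.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .layers import BatchNorm, Conv, Dropout, MaxPool, Param, ReLU, Softplus, Upsample

__all__ = ["UNetConfig", "UNet", "build_unet"]

N_CLASSES = 4  # background + foregut/midgut/hindgut


@dataclass(frozen=True)
class UNetConfig:
    """Topology of the U-net.

    Reference configurations follow the full-scale design (2d: 256x256 input,
    8 base channels, 7 levels -> 14 blocks; 3d: 128x128x64, 16 base channels,
    5 levels -> 10 blocks).  ``desk()`` is a deliberately tiny preset for CPU
    experiments and tests.
    """

    dims: int = 2
    input_shape: tuple[int, ...] = (256, 256)
    base_channels: int | None = None
    n_levels: int | None = None
    dropout: float = 0.1
    growth: int = 2

    def __post_init__(self) -> None:
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if len(self.input_shape) != self.dims:
            raise ValueError("input_shape length must equal dims")
        if self.base_channels is None:
            object.__setattr__(self, "base_channels", 8 if self.dims == 2 else 16)
        if self.n_levels is None:
            object.__setattr__(self, "n_levels", 7 if self.dims == 2 else 5)
        f = 2**self.n_levels
        for s in self.input_shape:
            if s % f != 0 or s // f < 1:
                raise ValueError(
                    f"input shape {self.input_shape} not divisible by 2^{self.n_levels} per axis"
                )

    @property
    def n_blocks(self) -> int:
        return 2 * self.n_levels

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * self.growth**i for i in range(self.n_levels)]

    @classmethod
    def desk(cls, dims: int = 2) -> "UNetConfig":
        """Tiny CPU preset: 3 levels, 4 base channels, 64^dims input, no dropout."""
        return cls(
            dims=dims,
            input_shape=(64,) * dims,
            base_channels=4,
            n_levels=3,
            dropout=0.0,
        )


class _DownBlock:
    def __init__(self, in_ch, out_ch, dims, dropout, rng):
        self.conv1 = Conv(in_ch, out_ch, dims, 3, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv(out_ch, out_ch, dims, 3, rng)
        self.relu2 = ReLU()
        self.bn = BatchNorm(out_ch, dims)
        self.drop = Dropout(dropout, rng)
        self.pool = MaxPool(dims)

    def forward(self, x, training):
        h = self.relu1.forward(self.conv1.forward(x, training), training)
        h = self.relu2.forward(self.conv2.forward(h, training), training)
        h = self.drop.forward(self.bn.forward(h, training), training)
        return h, self.pool.forward(h, training)

    def backward(self, d_pooled, d_skip):
        dh = self.pool.backward(d_pooled) + d_skip
        dh = self.bn.backward(self.drop.backward(dh))
        dh = self.conv2.backward(self.relu2.backward(dh))
        return self.conv1.backward(self.relu1.backward(dh))

    def layers(self):
        return [self.conv1, self.conv2, self.bn]


class _UpBlock:
    def __init__(self, up_ch, skip_ch, out_ch, dims, dropout, rng):
        self.up = Upsample(dims)
        self.conv1 = Conv(up_ch + skip_ch, out_ch, dims, 3, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv(out_ch, out_ch, dims, 3, rng)
        self.relu2 = ReLU()
        self.bn = BatchNorm(out_ch, dims)
        self.drop = Dropout(dropout, rng)
        self.up_ch = up_ch

    def forward(self, x, skip, training):
        u = self.up.forward(x, training)
        h = np.concatenate([u, skip], axis=1)
        h = self.relu1.forward(self.conv1.forward(h, training), training)
        h = self.relu2.forward(self.conv2.forward(h, training), training)
        return self.drop.forward(self.bn.forward(h, training), training)

    def backward(self, dy):
        dh = self.bn.backward(self.drop.backward(dy))
        dh = self.conv2.backward(self.relu2.backward(dh))
        dh = self.conv1.backward(self.relu1.backward(dh))
        du, dskip = dh[:, : self.up_ch], dh[:, self.up_ch :]
        return self.up.backward(du), dskip

    def layers(self):
        return [self.conv1, self.conv2, self.bn]


class UNet:
    """The assembled dual-output U-net.  Build via :func:`build_unet`."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.channels
        L = config.n_levels
        self.down: list[_DownBlock] = []
        in_ch = 1
        for i in range(L):
            self.down.append(_DownBlock(in_ch, ch[i], config.dims, config.dropout, rng))
            in_ch = ch[i]
        self.up: list[_UpBlock] = []
        up_ch = ch[L - 1]
        for j in range(L):
            lvl = L - 1 - j
            self.up.append(_UpBlock(up_ch, ch[lvl], ch[lvl], config.dims, config.dropout, rng))
            up_ch = ch[lvl]
        self.head_seg = Conv(ch[0], N_CLASSES, config.dims, 1, rng)
        self.head_diam = Conv(ch[0], 1, config.dims, 1, rng)
        self.softplus = Softplus()

    # -- forward/backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """x: (N, 1, *spatial) -> (segmentation logits (N,4,*sp), diameters (N,1,*sp))."""
        if x.ndim != 2 + self.config.dims or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, *spatial) input, got {x.shape}")
        if tuple(x.shape[2:]) != tuple(self.config.input_shape):
            raise ValueError(
                f"input spatial shape {x.shape[2:]} != configured {self.config.input_shape}"
            )
        skips = []
        h = x
        for blk in self.down:
            skip, h = blk.forward(h, training)
            skips.append(skip)
        for j, blk in enumerate(self.up):
            h = blk.forward(h, skips[len(skips) - 1 - j], training)
        logits = self.head_seg.forward(h, training)
        diam = self.softplus.forward(self.head_diam.forward(h, training), training)
        return logits, diam

    def backward(self, dlogits: np.ndarray, ddiam: np.ndarray) -> None:
        dh = self.head_seg.backward(dlogits)
        dh = dh + self.head_diam.backward(self.softplus.backward(ddiam))
        dskips = [None] * len(self.down)
        for j in range(len(self.up) - 1, -1, -1):
            dh, dskip = self.up[j].backward(dh)
            dskips[len(self.down) - 1 - j] = dskip
        for i in range(len(self.down) - 1, -1, -1):
            dh = self.down[i].backward(dh, dskips[i])

    def predict_proba(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Inference: softmax class probabilities and diameters (eval mode)."""
        logits, diam = self.forward(x, training=False)
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True), diam

    # -- parameter plumbing ------------------------------------------------
    def _layers(self):
        out = []
        for blk in self.down + self.up:
            out.extend(blk.layers())
        out.extend([self.head_seg, self.head_diam])
        return out

    def parameters(self) -> list[Param]:
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    @property
    def n_blocks(self) -> int:
        return self.config.n_blocks

    def state(self) -> list[np.ndarray]:
        st = [p.value.copy() for p in self.parameters()]
        for layer in self._layers():
            if isinstance(layer, BatchNorm):
                st.extend([layer.running_mean.copy(), layer.running_var.copy()])
        return st

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, v in zip(params, state[: len(params)]):
            p.value[...] = v
        extra = state[len(params) :]
        i = 0
        for layer in self._layers():
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = extra[i]
                layer.running_var[...] = extra[i + 1]
                i += 2

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = self.state()
        np.savez_compressed(
            path,
            config=json.dumps(asdict(self.config)),
            n_arrays=len(state),
            **{f"arr_{i}": a for i, a in enumerate(state)},
        )

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        data = np.load(Path(path), allow_pickle=False)
        cfg = json.loads(str(data["config"]))
        cfg["input_shape"] = tuple(cfg["input_shape"])
        net = cls(UNetConfig(**cfg))
        state = [data[f"arr_{i}"] for i in range(int(data["n_arrays"]))]
        net.load_state(state)
        return net


def build_unet(config: UNetConfig, seed: int = 0) -> UNet:
    """Construct a randomly initialized dual-output U-net for this config."""
    return UNet(config, seed=seed)
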