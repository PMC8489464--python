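"""A compact CPU convolutional-network engine with manual backpropagation.

Implements exactly the pieces the landmark detector needs — 3x3/1x1
convolutions, instance normalization, ReLU, 2x2 max pooling, nearest
upsampling, channel concatenation — each as a layer object with ``forward``
/ ``backward`` methods, plus the U-Net that composes them and an Adam
optimizer.  Everything is NumPy arrays in NCHW layout; ``dtype`` is
configurable (float32 for training speed, float64 for gradient checks).

The U-Net follows the standard encoder-decoder design: per resolution level
a stack of (conv -> norm -> ReLU) blocks, downsampling halves the spatial
resolution while channels double, the decoder mirrors the encoder with skip
concatenations, and a final 1x1 convolution emits per-pixel class scores.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .core import ConfigurationError


@dataclass
class ModelConfig:
    """U-Net hyperparameters.

    ``input_size`` must be divisible by ``2**(n_levels - 1)`` so the
    encoder's pooling chain lands on integer grids.
    """

    n_levels: int = 4
    blocks_per_level: int = 3
    base_channels: int = 32
    in_channels: int = 1
    out_channels: int = 4
    input_size: tuple[int, int] = (400, 400)
    norm: str = "instance"
    activation: str = "relu"
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ConfigurationError("n_levels must be >= 2")
        if self.blocks_per_level < 1 or self.base_channels < 1:
            raise ConfigurationError("blocks_per_level and base_channels must be >= 1")
        div = 2 ** (self.n_levels - 1)
        if self.input_size[0] % div or self.input_size[1] % div:
            raise ConfigurationError(
                f"input_size {self.input_size} must be divisible by {div} for {self.n_levels} levels"
            )
        if self.norm not in ("instance", "none"):
            raise ConfigurationError("norm must be 'instance' or 'none'")
        if self.activation != "relu":
            raise ConfigurationError("only 'relu' activation is supported")

    @property
    def np_dtype(self) -> np.dtype:
        return np.dtype(self.dtype)


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Conv2D:
    """Same-padded k x k convolution (k odd), He-initialized.

    Implemented as an im2col GEMM: patches are gathered once into a
    ``(N*H*W, cin*k*k)`` matrix so both passes are single large matrix
    products (the per-shift formulation is memory-bound at narrow channel
    counts).
    """

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator, dtype):
        std = np.sqrt(2.0 / (cin * ksize * ksize))
        self.W = Param((rng.standard_normal((cout, cin, ksize, ksize)) * std).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self.k = ksize
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        N, cin, H, Wd = x.shape
        cout = self.W.value.shape[0]
        Wmat = self.W.value.reshape(cout, cin * k * k)
        if k == 1:
            xt = x.transpose(0, 2, 3, 1).reshape(-1, cin)
            y = xt @ Wmat.T + self.b.value
            self._cache = (xt, x.shape)
            return y.reshape(N, H, Wd, cout).transpose(0, 3, 1, 2)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (N, cin, H, W, k, k) -> (N, H, W, cin, k, k) -> (N*H*W, cin*k*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * H * Wd, cin * k * k
        )
        y = cols @ Wmat.T + self.b.value
        self._cache = (cols, x.shape)
        return y.reshape(N, H, Wd, cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache  # type: ignore[misc]
        k, p = self.k, self.k // 2
        N, cin, H, Wd = x_shape
        cout = self.W.value.shape[0]
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, cout)
        self.b.grad += dyt.sum(axis=0)
        dWmat = dyt.T @ cols
        self.W.grad += dWmat.reshape(self.W.value.shape)
        dcols = dyt @ self.W.value.reshape(cout, cin * k * k)
        self._cache = None
        if k == 1:
            return dcols.reshape(N, H, Wd, cin).transpose(0, 3, 1, 2)
        dcols = dcols.reshape(N, H, Wd, cin, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((N, cin, H + 2 * p, Wd + 2 * p), dtype=dy.dtype)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + H, dj : dj + Wd] += dcols[:, :, :, :, di, dj]
        return dxp[:, :, p : p + H, p : p + Wd]


class InstanceNorm:
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels: int, dtype, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.eps = eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache  # type: ignore[misc]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        self._cache = None
        return inv * (dxhat - m1 - xhat * m2)


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, dy, 0.0).astype(dy.dtype)


class MaxPool2:
    """2x2 max pooling with stride 2 (deterministic first-max tie-break)."""

    def __init__(self):
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(N, C, H // 2, W // 2, 4)
        idx = xr.argmax(axis=4)
        out = np.take_along_axis(xr, idx[..., None], axis=4)[..., 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, x_shape = self._cache  # type: ignore[misc]
        N, C, H, W = x_shape
        dxr = np.zeros((N, C, H // 2, W // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=4)
        dx = dxr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = None
        return dx.reshape(N, C, H, W)


class UpsampleNearest2:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = dy.shape
        return dy.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class Block:
    """conv(3x3) -> normalization -> ReLU."""

    def __init__(self, cin: int, cout: int, config: ModelConfig, rng: np.random.Generator):
        dtype = config.np_dtype
        self.layers: list = [Conv2D(cin, cout, 3, rng, dtype)]
        if config.norm == "instance":
            self.layers.append(InstanceNorm(cout, dtype))
        self.layers.append(ReLU())

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet:
    """Encoder-decoder network emitting per-pixel class scores."""

    CHECKPOINT_VERSION = 1

    def __init__(self, config: ModelConfig, rng: np.random.Generator | int | None = None):
        self.config = config
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        C = config.base_channels
        n = config.n_levels
        mk_blocks = lambda cin, cout: [  # noqa: E731
            Block(cin if i == 0 else cout, cout, config, rng)
            for i in range(config.blocks_per_level)
        ]
        self.enc: list[list[Block]] = []
        cin = config.in_channels
        for lvl in range(n):
            cout = C * 2**lvl
            self.enc.append(mk_blocks(cin, cout))
            cin = cout
        self.pools = [MaxPool2() for _ in range(n - 1)]
        self.ups = [UpsampleNearest2() for _ in range(n - 1)]
        self.upconvs: list[Conv2D] = []
        self.dec: list[list[Block]] = []
        for lvl in reversed(range(n - 1)):
            c_here = C * 2**lvl
            self.upconvs.append(Conv2D(c_here * 2, c_here, 3, rng, config.np_dtype))
            self.dec.append(mk_blocks(c_here * 2, c_here))  # after skip concat
        self.final = Conv2D(C, config.out_channels, 1, rng, config.np_dtype)

    # -- parameter plumbing ------------------------------------------------
    def params(self) -> list[Param]:
        out: list[Param] = []
        for blocks in self.enc:
            for b in blocks:
                out += b.params()
        for conv in self.upconvs:
            out += conv.params()
        for blocks in self.dec:
            for b in blocks:
                out += b.params()
        out += self.final.params()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list does not match the architecture")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError("weight shapes do not match the architecture")
            p.value[...] = w

    def clone(self) -> "UNet":
        other = UNet(self.config, rng=0)
        other.set_weights(self.get_weights())
        return other

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class scores, shape (N, out_channels, H, W)."""
        x = np.ascontiguousarray(x, dtype=self.config.np_dtype)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (N, {self.config.in_channels}, H, W), got {x.shape}")
        n = self.config.n_levels
        skips = []
        h = x
        for lvl in range(n - 1):
            for b in self.enc[lvl]:
                h = b.forward(h)
            skips.append(h)
            h = self.pools[lvl].forward(h)
        for b in self.enc[n - 1]:
            h = b.forward(h)
        self._skip_channels = [s.shape[1] for s in skips]
        for i, lvl in enumerate(reversed(range(n - 1))):
            h = self.ups[i].forward(h)
            h = self.upconvs[i].forward(h)
            h = np.concatenate([skips[lvl], h], axis=1)
            for b in self.dec[i]:
                h = b.forward(h)
        return self.final.forward(h)

    def backward(self, dscores: np.ndarray) -> np.ndarray:
        """Backpropagate loss gradients; accumulates parameter gradients and
        returns the gradient with respect to the input image."""
        n = self.config.n_levels
        dh = self.final.backward(dscores.astype(self.config.np_dtype))
        dskips: dict[int, np.ndarray] = {}
        for i in reversed(range(n - 1)):
            lvl = n - 2 - i
            for b in reversed(self.dec[i]):
                dh = b.backward(dh)
            c_skip = self._skip_channels[lvl]
            dskips[lvl] = dh[:, :c_skip]
            dh = dh[:, c_skip:]
            dh = self.upconvs[i].backward(dh)
            dh = self.ups[i].backward(dh)
        for b in reversed(self.enc[n - 1]):
            dh = b.backward(dh)
        for lvl in reversed(range(n - 1)):
            dh = self.pools[lvl].backward(dh)
            dh = dh + dskips[lvl]
            for b in reversed(self.enc[lvl]):
                dh = b.backward(dh)
        return dh

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        """Save weights + config to an .npz checkpoint with a version field."""
        meta = {"version": self.CHECKPOINT_VERSION, "config": asdict(self.config)}
        arrays = {f"param_{i:04d}": p.value for i, p in enumerate(self.params())}
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "UNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta.get("version") != cls.CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
            cfg_dict = meta["config"]
            cfg_dict["input_size"] = tuple(cfg_dict["input_size"])
            config = ModelConfig(**cfg_dict)
            model = cls(config, rng=0)
            keys = sorted(k for k in data.files if k.startswith("param_"))
            model.set_weights([data[k] for k in keys])
        return model


class Adam:
    """Adam optimizer over a parameter list; ``lr`` is mutable for schedules."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
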