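"""Compact numpy convolutional-network engine.

Implements exactly the pieces the wavefront regressor needs — strided 3x3
convolutions (im2col), batch normalization, per-channel PReLU activations,
residual blocks, a 1x1-convolution regression head and an Adam optimizer —
with hand-written backward passes.  Everything is float32 and fully
deterministic given a seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["ConvNet", "Adam"]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int
            ) -> tuple[np.ndarray, tuple]:
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]                # (B,C,Ho,Wo,k,k)
    ho, wo = view.shape[2], view.shape[3]
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (b, c, h, w, ho, wo)


def _col2im(dcols: np.ndarray, shape: tuple, k: int, stride: int,
            pad: int) -> np.ndarray:
    b, c, h, w, ho, wo = shape
    d = dcols.reshape(b, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    gxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] \
                += d[:, :, :, :, i, j]
    if pad:
        return gxp[:, :, pad:-pad, pad:-pad]
    return gxp


class Conv2d:
    def __init__(self, cin: int, cout: int, k: int, stride: int,
                 rng: np.random.Generator):
        fan_in = cin * k * k
        self.w = (rng.standard_normal((cout, fan_in))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.stride, self.pad = k, stride, k // 2
        self.cin, self.cout = cin, cout

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols, shape = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._shape = cols, shape
        out = cols @ self.w.T + self.b
        b, _, _, _, ho, wo = shape
        return out.reshape(b, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, cout, ho, wo = g.shape
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, cout)
        self.gw = (g2.T @ self._cols).astype(np.float32)
        self.gb = g2.sum(axis=0).astype(np.float32)
        dcols = g2 @ self.w
        return _col2im(dcols, self._shape, self.k, self.stride, self.pad)

    def params(self):
        return [("w", self), ("b", self)]


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.w = np.ones(c, dtype=np.float32)   # gamma
        self.b = np.zeros(c, dtype=np.float32)  # beta
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv, self._train = xhat, inv, train
        return self.w[None, :, None, None] * xhat + self.b[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.gw = (g * xhat).sum(axis=(0, 2, 3)).astype(np.float32)
        self.gb = g.sum(axis=(0, 2, 3)).astype(np.float32)
        gx = g * self.w[None, :, None, None]
        if not self._train:
            return gx * inv[None, :, None, None]
        m = g.shape[0] * g.shape[2] * g.shape[3]
        t1 = gx.sum(axis=(0, 2, 3)) / m
        t2 = (gx * xhat).sum(axis=(0, 2, 3)) / m
        return (gx - t1[None, :, None, None]
                - xhat * t2[None, :, None, None]) * inv[None, :, None, None]

    def params(self):
        return [("w", self), ("b", self)]


class PReLU:
    def __init__(self, c: int, init: float = 0.25):
        self.w = np.full(c, init, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._neg = x < 0
        return np.where(self._neg, x * self.w[None, :, None, None], x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        neg = self._neg
        self.gw = np.where(neg, g * self._x_neg_cache, 0.0).sum(
            axis=(0, 2, 3)).astype(np.float32)
        return np.where(neg, g * self.w[None, :, None, None], g)

    # keep the pre-activation for the slope gradient
    def forward_cached(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x_neg_cache = np.where(x < 0, x, 0.0)
        return self.forward(x, train)

    def params(self):
        return [("w", self)]


class _Stage:
    """conv -> batchnorm -> prelu."""

    def __init__(self, cin, cout, k, stride, rng):
        self.conv = Conv2d(cin, cout, k, stride, rng)
        self.bn = BatchNorm2d(cout)
        self.act = PReLU(cout)

    def forward(self, x, train):
        return self.act.forward_cached(self.bn.forward(
            self.conv.forward(x, train), train), train)

    def backward(self, g):
        return self.conv.backward(self.bn.backward(self.act.backward(g)))

    def params(self):
        return self.conv.params() + self.bn.params() + self.act.params()


class ResidualBlock:
    """Two 3x3 convolutions with batch norm and PReLU, plus identity skip."""

    def __init__(self, c, rng):
        self.stage = _Stage(c, c, 3, 1, rng)
        self.conv2 = Conv2d(c, c, 3, 1, rng)
        self.bn2 = BatchNorm2d(c)
        self.act2 = PReLU(c)

    def forward(self, x, train):
        y = self.stage.forward(x, train)
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        return self.act2.forward_cached(y + x, train)

    def backward(self, g):
        g = self.act2.backward(g)
        gy = self.conv2.backward(self.bn2.backward(g))
        return self.stage.backward(gy) + g

    def params(self):
        return (self.stage.params() + self.conv2.params()
                + self.bn2.params() + self.act2.params())


class ConvNet:
    """Residual CNN mapping biplane crops to mode-amplitude vectors.

    Stride-2 downsampling stages interleaved with residual blocks, finishing
    in a 1x1-convolution head whose output is averaged spatially to give one
    value per wavefront mode.
    """

    def __init__(self, input_size: int, n_modes: int,
                 channels: tuple[int, ...] = (8, 16, 32, 64),
                 in_channels: int = 2, seed: int = 0, res_from: int = 1):
        total_stride = 2 ** len(channels)
        if input_size % total_stride:
            raise ValueError(
                f"input size {input_size} not divisible by the total stride "
                f"{total_stride}")
        rng = np.random.default_rng(seed)
        self.arch = dict(input_size=input_size, n_modes=n_modes,
                         channels=tuple(channels), in_channels=in_channels,
                         seed=seed, res_from=res_from)
        self.layers: list = []
        c = in_channels
        for i, cout in enumerate(channels):
            self.layers.append(_Stage(c, cout, 3, 2, rng))
            if i >= res_from:
                self.layers.append(ResidualBlock(cout, rng))
            c = cout
        self.head = Conv2d(c, n_modes, 1, 1, rng)
        self.head.w[:] = 0.0   # zero-init regression head
        self.n_modes = n_modes
        self.metadata: dict = {}

    # -- inference / training ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        for layer in self.layers:
            x = layer.forward(x, train)
        y = self.head.forward(x, train)
        self._head_hw = y.shape[2:]
        return y.mean(axis=(2, 3))

    def backward(self, gout: np.ndarray) -> None:
        h, w = self._head_hw
        g = np.broadcast_to(gout[:, :, None, None].astype(np.float32),
                            (gout.shape[0], gout.shape[1], h, w)) / (h * w)
        g = self.head.backward(np.ascontiguousarray(g))
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = [self.forward(x[i:i + batch_size], train=False)
                for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs, axis=0)

    # -- parameter plumbing --------------------------------------------------
    def param_refs(self):
        refs = []
        for layer in self.layers:
            refs.extend(layer.params())
        refs.extend(self.head.params())
        return refs

    def n_parameters(self) -> int:
        return int(sum(getattr(obj, name).size
                       for name, obj in self.param_refs()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (name, obj) in enumerate(self.param_refs()):
            out[f"p{i}_{name}"] = getattr(obj, name)
        bn_idx = 0
        for layer in self._all_bn():
            out[f"bn{bn_idx}_mean"] = layer.running_mean
            out[f"bn{bn_idx}_var"] = layer.running_var
            bn_idx += 1
        return out

    def _all_bn(self):
        for layer in self.layers:
            if isinstance(layer, _Stage):
                yield layer.bn
            else:
                yield layer.stage.bn
                yield layer.bn2

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, (name, obj) in enumerate(self.param_refs()):
            setattr(obj, name, np.array(arrays[f"p{i}_{name}"], dtype=np.float32))
        for bn_idx, layer in enumerate(self._all_bn()):
            layer.running_mean = np.array(arrays[f"bn{bn_idx}_mean"], np.float32)
            layer.running_var = np.array(arrays[f"bn{bn_idx}_var"], np.float32)

    def weights_hash(self) -> str:
        import hashlib
        arrays = self.state_arrays()
        h = hashlib.sha1()
        for key in sorted(arrays):
            h.update(arrays[key].tobytes())
        return h.hexdigest()

    # -- serialization -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {"arch": {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in self.arch.items()},
                "metadata": self.metadata}
        np.savez(path, __meta__=json.dumps(meta), **self.state_arrays())

    @classmethod
    def load(cls, path: str | Path) -> "ConvNet":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            arch = meta["arch"]
            model = cls(input_size=arch["input_size"], n_modes=arch["n_modes"],
                        channels=tuple(arch["channels"]),
                        in_channels=arch["in_channels"], seed=arch["seed"],
                        res_from=arch.get("res_from", 1))
            model.load_state_arrays({k: data[k] for k in data.files
                                     if k != "__meta__"})
            model.metadata = meta.get("metadata", {})
        return model


class Adam:
    def __init__(self, model: ConvNet, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model, self.lr = model, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(obj, name))
                  for name, obj in model.param_refs()]
        self.v = [np.zeros_like(getattr(obj, name))
                  for name, obj in model.param_refs()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (name, obj) in enumerate(self.model.param_refs()):
            g = getattr(obj, "g" + name)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            setattr(obj, name, getattr(obj, name)
                    - self.lr * mhat / (np.sqrt(vhat) + self.eps))
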