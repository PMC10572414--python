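"""Neural-network layers on top of the autograd engine.

Covers exactly what the segmentation models and the policy controller need:
3x3 convolutions (im2col), 2x2 transposed convolutions for decoder
up-sampling, 2x2 max-pooling, batch/instance normalization, linear and
embedding layers, and an LSTM cell.  Parameter initialization is explicit:
every constructor takes a ``numpy.random.Generator`` so model builds are
reproducible bit for bit.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "Module", "ModuleList", "Linear", "Embedding", "Conv2d",
    "ConvTranspose2d", "MaxPool2d", "BatchNorm2d", "InstanceNorm2d",
    "LSTMCell", "Identity",
]


class Module:
    """Minimal container: tracks parameters, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def _own_params(self):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield name, val

    def named_parameters(self, prefix: str = ""):
        for name, p in self._own_params():
            yield prefix + name, p
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self._buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        bufs = dict(self._buffers())
        for name, value in state.items():
            if name in params:
                params[name].data[...] = value
            elif name in bufs:
                bufs[name][...] = value
            else:
                raise KeyError(f"unknown state entry {name!r}")

    def _buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child._buffers(prefix + cname + ".")


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self.items = list(modules)

    def append(self, m: Module):
        self.items.append(m)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __len__(self):
        return len(self.items)


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 init_range: float | None = None):
        super().__init__()
        if init_range is not None:
            self.weight = Tensor(rng.uniform(-init_range, init_range,
                                             (in_features, out_features)),
                                 requires_grad=True)
            self.bias = Tensor(rng.uniform(-init_range, init_range, (out_features,)),
                               requires_grad=True)
        else:
            self.weight = _kaiming(rng, (in_features, out_features), in_features)
            self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator,
                 init_range: float = 0.1):
        super().__init__()
        self.weight = Tensor(rng.uniform(-init_range, init_range, (num_embeddings, dim)),
                             requires_grad=True)

    def forward(self, idx) -> Tensor:
        return self.weight[np.asarray(idx, dtype=np.intp)]


class Conv2d(Module):
    """3x3 (or kxk) convolution, stride 1, 'same' zero padding by default."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int | None = None):
        super().__init__()
        k = kernel_size
        self.padding = (k // 2) if padding is None else padding
        self.kernel_size = k
        fan_in = in_channels * k * k
        self.weight = _kaiming(rng, (out_channels, in_channels, k, k), fan_in)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        k, p = self.kernel_size, self.padding
        n, c, h, wdt = x.shape
        co = w.shape[0]
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        ho, wo = h + 2 * p - k + 1, wdt + 2 * p - k + 1
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))        # n,c,ho,wo,k,k
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5))
        cols2 = cols.reshape(n * ho * wo, c * k * k)
        w2 = w.data.reshape(co, c * k * k).T
        out2 = cols2 @ w2 + b.data
        out_data = out2.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)

        def backward(g):
            g2 = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
            if w.requires_grad:
                gw = (cols2.T @ g2).T.reshape(w.shape)
                w._accum(gw)
            if b.requires_grad:
                b._accum(g2.sum(axis=0))
            if x.requires_grad:
                gcols = (g2 @ w2.T).reshape(n, ho, wo, c, k, k)
                gxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        gxp[:, :, i:i + ho, j:j + wo] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                if p:
                    gxp = gxp[:, :, p:-p, p:-p]
                x._accum(gxp)

        out = Tensor(out_data)
        if x.requires_grad or w.requires_grad or b.requires_grad:
            out.requires_grad = True
            out._parents = (x, w, b)
            out._backward = backward
        return out


class ConvTranspose2d(Module):
    """2x2 transposed convolution with stride 2 (non-overlapping up-sampling)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * 4
        self.weight = _kaiming(rng, (in_channels, out_channels, 2, 2), fan_in)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        n, c, h, wd = x.shape
        co = w.shape[1]
        out_data = np.einsum("ncij,cdab->ndiajb", x.data, w.data, optimize=True)
        out_data = out_data.reshape(n, co, 2 * h, 2 * wd) + b.data[None, :, None, None]

        def backward(g):
            g6 = g.reshape(n, co, h, 2, wd, 2)
            if w.requires_grad:
                w._accum(np.einsum("ncij,ndiajb->cdab", x.data, g6, optimize=True))
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                x._accum(np.einsum("ndiajb,cdab->ncij", g6, w.data, optimize=True))

        out = Tensor(out_data)
        if x.requires_grad or w.requires_grad or b.requires_grad:
            out.requires_grad = True
            out._parents = (x, w, b)
            out._backward = backward
        return out


class MaxPool2d(Module):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        y = x.reshape(n, c, h // 2, 2, w // 2, 2)
        return y.max_axis(axis=5).max_axis(axis=3)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3)
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) * (x - mean)).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            norm = (x - mean) / ((var + self.eps) ** 0.5)
        else:
            mean = self.running_mean[None, :, None, None]
            std = np.sqrt(self.running_var + self.eps)[None, :, None, None]
            norm = (x - mean) * (1.0 / std)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return norm * g + b


class InstanceNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        axes = (2, 3)
        mean = x.mean(axis=axes, keepdims=True)
        var = ((x - mean) * (x - mean)).mean(axis=axes, keepdims=True)
        norm = (x - mean) / ((var + self.eps) ** 0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return norm * g + b


class LSTMCell(Module):
    """Standard LSTM cell; gate order i, f, g, o."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 init_range: float = 0.1):
        super().__init__()
        self.hidden_size = hidden_size
        self.w_ih = Tensor(rng.uniform(-init_range, init_range,
                                       (input_size, 4 * hidden_size)), requires_grad=True)
        self.w_hh = Tensor(rng.uniform(-init_range, init_range,
                                       (hidden_size, 4 * hidden_size)), requires_grad=True)
        self.bias = Tensor(rng.uniform(-init_range, init_range, (4 * hidden_size,)),
                           requires_grad=True)

    def forward(self, x: Tensor, state: tuple[Tensor, Tensor]):
        h, c = state
        hs = self.hidden_size
        gates = x @ self.w_ih + h @ self.w_hh + self.bias
        i = gates[:, 0 * hs:1 * hs].sigmoid()
        f = gates[:, 1 * hs:2 * hs].sigmoid()
        g = gates[:, 2 * hs:3 * hs].tanh()
        o = gates[:, 3 * hs:4 * hs].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new
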