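"""Neural-network building blocks on top of the autodiff engine.

Layers mirror the familiar torch-style surface (``Module`` with
``parameters()``, ``train()``/``eval()``, callable forward) at the small scale
this package needs: fully connected layers, causal dilated 1-D convolutions,
batch normalization, temporal max-pooling.  All parameters are initialized
with small random values drawn from an explicitly passed
``numpy.random.Generator`` so every model build is reproducible.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, astensor

__all__ = [
    "Module", "Parameter", "Linear", "Conv1dCausal", "BatchNorm1d",
    "MaxPool1d", "ReLU", "Sequential",
]


class Parameter(Tensor):
    def __init__(self, value):
        super().__init__(value, requires_grad=True)


class Module:
    """Base class: tracks sub-modules and parameters by attribute assignment."""

    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Parameter] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for mn, m in self._modules.items():
            out.extend(m.named_parameters(prefix + mn + "."))
        return out

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for m in self._modules.values():
            out.extend(m.modules())
        return out

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.value.copy() for n, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm1d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.value = np.asarray(state[n], dtype=np.float64).reshape(p.value.shape)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm1d):
                m.running_mean = np.asarray(state[f"__bn{i}.running_mean"], dtype=np.float64)
                m.running_var = np.asarray(state[f"__bn{i}.running_var"], dtype=np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return astensor(x) @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return astensor(x).relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv1dCausal(Module):
    """1-D convolution with left zero-padding so output length equals input
    length and no tap looks into the future.  Input/output layout (N, C, L)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dilation: int = 1):
        super().__init__()
        if kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        scale = np.sqrt(2.0 / (in_channels * kernel_size))
        self.weight = Parameter(rng.normal(0.0, scale, size=(out_channels, in_channels, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels))

    @property
    def left_pad(self) -> int:
        return (self.kernel_size - 1) * self.dilation

    def forward(self, x: Tensor) -> Tensor:
        x = astensor(x)
        w, b = self.weight, self.bias
        n, c, length = x.value.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        pad = self.left_pad
        k, d = self.kernel_size, self.dilation
        xp = np.pad(x.value, ((0, 0), (0, 0), (pad, 0)))
        # tap j of output position l reads padded position l + j*d, so each
        # tap is a contiguous slice: gather/scatter reduce to K sliced copies
        cols = np.empty((n, c, length, k))
        for j in range(k):
            cols[:, :, :, j] = xp[:, :, j * d: j * d + length]
        # (N, L, C*K) @ (C*K, O): BLAS does the contraction
        cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(n, length, c * k)
        w2 = w.value.reshape(self.out_channels, c * k).T
        out = (cols2 @ w2 + b.value).transpose(0, 2, 1)  # (N, O, L)

        def backward(g):
            gt = np.ascontiguousarray(g.transpose(0, 2, 1))       # (N, L, O)
            gw = np.tensordot(cols2, gt, axes=([0, 1], [0, 1]))    # (C*K, O)
            gw = gw.T.reshape(w.value.shape)
            gb = gt.sum(axis=(0, 1))
            gcols2 = gt @ w2.T                                     # (N, L, C*K)
            gcols = gcols2.reshape(n, length, c, k).transpose(0, 2, 1, 3)
            gxp = np.zeros_like(xp)
            for j in range(k):
                gxp[:, :, j * d: j * d + length] += gcols[:, :, :, j]
            gx = gxp[:, :, pad:] if pad else gxp
            return ((x, gx), (w, gw), (b, gb))

        return Tensor._make(out, (x, w, b), backward)


class BatchNorm1d(Module):
    """Batch normalization over the batch (and temporal) axes.

    Accepts (N, F) feature batches or (N, C, L) sequence batches.  In training
    mode batch statistics are used and running statistics updated; in eval mode
    the running statistics make the layer deterministic.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        x = astensor(x)
        seq = x.value.ndim == 3
        axes = (0, 2) if seq else (0,)
        shape = (1, self.num_features, 1) if seq else (1, self.num_features)
        gamma = self.gamma.reshape(shape)
        beta = self.beta.reshape(shape)
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=axes, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.value.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.value.reshape(-1))
            xhat = (x - mean) / (var + self.eps) ** 0.5
        else:
            mean = self.running_mean.reshape(shape)
            std = np.sqrt(self.running_var.reshape(shape) + self.eps)
            xhat = (x - mean) / std
        return gamma * xhat + beta


class MaxPool1d(Module):
    """Temporal max-pooling on (N, C, L); non-overlapping windows, trailing
    remainder dropped."""

    def __init__(self, kernel_size: int = 2):
        super().__init__()
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        x = astensor(x)
        n, c, length = x.value.shape
        k = self.kernel_size
        l_out = length // k
        if l_out < 1:
            raise ValueError(f"sequence length {length} shorter than pool window {k}")
        trimmed = x[:, :, : l_out * k]
        return trimmed.reshape(n, c, l_out, k).max(axis=3)
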