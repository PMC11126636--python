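"""Layer and container abstractions over the autograd engine."""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import autograd as ag
from .autograd import Tensor

_DTYPE = np.float32

# Global generator used by parameter initialisers; reseed via `seed(...)`
# before building a model for reproducible weights.
_RNG = np.random.default_rng(0)


def seed(value: int) -> None:
    """Reseed parameter initialisation globally."""
    global _RNG
    _RNG = np.random.default_rng(int(value))


def kaiming_normal(shape, fan_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_out)
    return (_RNG.standard_normal(shape) * std).astype(_DTYPE)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=None), requires_grad=True)


class Module:
    """Minimal module tree: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self._modules: "OrderedDict[str, Module]" = OrderedDict()
        self._params: "OrderedDict[str, Parameter]" = OrderedDict()
        self._buffers: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())

    # ------------------------------------------------------------ state dict
    def state_dict(self, prefix: str = "", out=None):
        if out is None:
            out = OrderedDict()
        for name, p in self._params.items():
            out[prefix + name] = p.data
        for name, b in self._buffers.items():
            out[prefix + name] = getattr(self, name)
        for name, m in self._modules.items():
            m.state_dict(prefix + name + ".", out)
        return out

    def load_state_dict(self, state) -> None:
        own = self.state_dict()
        missing = [k for k in own if k not in state]
        if missing:
            raise KeyError(f"missing keys in state dict: {missing[:5]}")
        for name, p in self._params.items():
            p.data = np.asarray(state[name]).reshape(p.data.shape).astype(p.data.dtype)
        for name in list(self._buffers):
            val = np.asarray(state[name])
            self._buffers[name] = val
            object.__setattr__(self, name, val)
        for name, m in self._modules.items():
            sub = {k[len(name) + 1:]: v for k, v in state.items()
                   if k.startswith(name + ".")}
            m.load_state_dict(sub)

    def astype(self, dtype):
        """Cast all parameters and buffers (float64 helps oracle comparisons)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for m in self.modules():
            for name in list(m._buffers):
                arr = getattr(m, name).astype(dtype)
                m._buffers[name] = arr
                object.__setattr__(m, name, arr)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_out = out_channels * kernel_size * kernel_size
        self.weight = Parameter(kaiming_normal(
            (out_channels, in_channels, kernel_size, kernel_size), fan_out))
        self.bias = Parameter(np.zeros(out_channels, dtype=_DTYPE)) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(
            _RNG.uniform(-bound, bound, (out_features, in_features)).astype(_DTYPE))
        self.bias = Parameter(np.zeros(out_features, dtype=_DTYPE)) if bias else None

    def forward(self, x):
        out = ag.matmul(x, ag.transpose(self.weight, (1, 0)))
        if self.bias is not None:
            out = ag.add(out, self.bias)
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=_DTYPE))
        self.bias = Parameter(np.zeros(num_features, dtype=_DTYPE))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=_DTYPE))
        self.register_buffer("running_var", np.ones(num_features, dtype=_DTYPE))

    def forward(self, x):
        shape = (1, self.num_features, 1, 1)
        if self.training:
            mu = ag.tmean(x, axis=(0, 2, 3), keepdims=True)
            var = ag.tmean(ag.power(ag.add(x, ag.mul(mu, -1.0)), 2.0),
                           axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            m = self.momentum
            new_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            new_var = (1 - m) * self.running_var + m * unbiased
            self._buffers["running_mean"] = new_mean.astype(self.running_mean.dtype)
            self._buffers["running_var"] = new_var.astype(self.running_var.dtype)
            object.__setattr__(self, "running_mean", self._buffers["running_mean"])
            object.__setattr__(self, "running_var", self._buffers["running_var"])
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        inv = ag.power(ag.add(var, self.eps), -0.5)
        xhat = ag.mul(ag.add(x, ag.mul(mu, -1.0)), inv)
        return ag.add(ag.mul(xhat, ag.reshape(self.weight, shape)),
                      ag.reshape(self.bias, shape))


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ag.sigmoid(x)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]
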