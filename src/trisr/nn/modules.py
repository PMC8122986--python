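"""Layer modules with learnable parameters for the numpy autodiff backend."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: tracks sub-modules and parameters by attribute name."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, module: "Module"):
        self._modules[name] = module
        object.__setattr__(self, name, module)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- (de)serialization ---------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, arr in self._buffers().items():
            state[name] = arr.copy()
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        buffers = self._buffers()
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data[...] = arr
            elif name in buffers:
                buffers[name][...] = arr
            else:
                raise KeyError(f"unknown state entry {name}")

    def _buffers(self, prefix: str = "") -> dict:
        out = {}
        for key in getattr(self, "_buffer_names", ()):
            out[prefix + key] = getattr(self, key)
        for mname, m in self._modules.items():
            out.update(m._buffers(prefix + mname + "."))
        return out

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """2-D convolution; Kaiming-style init with optional residual down-scaling.

    ESRGAN-lineage practice initializes convolutions at 0.1x Kaiming scale and
    block-final convolutions at exactly zero so residual branches start as
    no-ops; ``zero_init=True`` reproduces that.
    """

    def __init__(self, in_ch, out_ch, kernel=3, stride=1, dilation=1,
                 padding=None, bias=True, rng=None, init_scale=0.1,
                 zero_init=False):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(0)
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        fan_in = in_ch * kh * kw
        if zero_init:
            w = np.zeros((out_ch, in_ch, kh, kw))
        else:
            std = np.sqrt(2.0 / fan_in) * init_scale
            w = rng.normal(0.0, std, size=(out_ch, in_ch, kh, kw))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride, self.dilation, self.padding = stride, dilation, padding

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         dilation=self.dilation, padding=self.padding)


class Dense(Module):
    def __init__(self, in_features, out_features, rng=None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features) * 0.1
        self.weight = Tensor(rng.normal(0.0, std, size=(in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x):
        return ag.add(ag.matmul(x, self.weight), self.bias)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps, self.momentum = eps, momentum

    def forward(self, x):
        C = x.shape[1]
        shape = (1, C, 1, 1)
        if self.training:
            mu = ag.tmean(x, axis=(0, 2, 3), keepdims=True)
            centered = ag.add(x, ag.mul(mu, -1.0))
            var = ag.tmean(ag.mul(centered, centered), axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(C)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(C)
            inv = ag.power(ag.add(var, self.eps), -0.5)
            xhat = ag.mul(centered, inv)
        else:
            mu = self.running_mean.reshape(shape)
            inv = 1.0 / np.sqrt(self.running_var.reshape(shape) + self.eps)
            xhat = ag.mul(ag.add(x, -mu), ag.Tensor(inv))
        return ag.add(ag.mul(xhat, ag.reshape(self.gamma, shape)),
                      ag.reshape(self.beta, shape))


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return ag.leaky_relu(x, self.slope)


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self.register(f"l{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
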