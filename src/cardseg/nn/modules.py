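"""Layer abstractions over the autodiff engine (Module, Conv3d, norm, ...)."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module", "Parameter", "Conv3d", "DownConv2", "UpConv2",
    "InstanceNorm3d", "PReLU", "Sequential",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: tracks sub-modules and parameters by attribute name."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise ValueError(f"state dict key mismatch: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float32).copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv3d(Module):
    """Stride-1 3D convolution with symmetric zero padding."""

    def __init__(self, in_ch, out_ch, kernel, rng, bias=True):
        super().__init__()
        self.padding = kernel // 2
        fan_in = in_ch * kernel ** 3
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x):
        return F.conv3d(x, self.weight, self.bias, padding=self.padding)


class DownConv2(Module):
    """2x2x2 stride-2 convolution: halves resolution."""

    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, 2, 2, 2), in_ch * 8))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))

    def forward(self, x):
        return F.downconv2(x, self.weight, self.bias)


class UpConv2(Module):
    """2x2x2 stride-2 transposed convolution: doubles resolution."""

    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.weight = Parameter(_he_init(rng, (in_ch, out_ch, 2, 2, 2), in_ch))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))

    def forward(self, x):
        return F.upconv2(x, self.weight, self.bias)


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over the spatial axes.

    Batch-independent, so training with batch size 2 is stable.
    """

    def __init__(self, channels, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones((1, channels, 1, 1, 1), dtype=np.float32))
        self.beta = Parameter(np.zeros((1, channels, 1, 1, 1), dtype=np.float32))

    def forward(self, x):
        mu = F.mean(x, axis=(2, 3, 4), keepdims=True)
        centered = x - mu
        var = F.mean(centered * centered, axis=(2, 3, 4), keepdims=True)
        inv = F.powc(var + self.eps, -0.5)
        return centered * inv * self.gamma + self.beta


class PReLU(Module):
    """Per-channel parametric ReLU (the VNet nonlinearity)."""

    def __init__(self, channels, init=0.25):
        super().__init__()
        self.slope = Parameter(np.full((1, channels, 1, 1, 1), init, dtype=np.float32))

    def forward(self, x):
        pos = F.relu(x)
        return pos + self.slope * (x - pos)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
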