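"""Layers and modules for the fixed convolutional architectures."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv, upsample_linear

__all__ = ["Module", "Parameter", "Conv", "Linear", "Upsample", "Sequential", "ReLU"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = np.asarray(a, dtype=np.float64).copy()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Conv(Module):
    """Stride-s n-d convolution, kernel 3, padding 1, He-initialized."""

    def __init__(self, dims, in_ch, out_ch, stride=1, kernel=3, pad=1, rng=None,
                 zero_init=False):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = pad
        shape = (out_ch, in_ch) + (kernel,) * dims
        if zero_init:
            w = np.zeros(shape)
        else:
            fan_in = in_ch * kernel**dims
            w = rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        return conv(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, in_features, out_features, rng=None, zero_init=False):
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            w = rng.standard_normal((in_features, out_features)) * np.sqrt(
                2.0 / in_features
            )
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Upsample(Module):
    def forward(self, x: Tensor) -> Tensor:
        return upsample_linear(x)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x
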