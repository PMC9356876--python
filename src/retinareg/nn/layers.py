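"""Layer objects (parameter containers) over the functional autodiff ops."""

from __future__ import annotations

import math

import numpy as np

from .tensor import (
    Tensor,
    batch_norm2d,
    conv2d,
    conv_transpose2d,
    relu,
)

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "BatchNorm2d", "ConvBnRelu"]


class Module:
    """Minimal parameter-tree container."""

    training: bool = True

    def parameters(self):
        out = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def modules(self):
        out = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.parameters())

    def state_arrays(self) -> dict:
        """Flat name -> array mapping of parameters and running stats,
        used for single-file checkpointing."""
        out = {}

        def walk(mod, prefix):
            for name, v in vars(mod).items():
                key = f"{prefix}{name}"
                if isinstance(v, Tensor) and v.requires_grad:
                    out[key] = v.data
                elif isinstance(v, np.ndarray):
                    out[key] = v
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")
        return out

    def load_state_arrays(self, state: dict) -> None:
        mine = self.state_arrays()
        if set(mine) != set(state):
            missing = set(mine) ^ set(state)
            raise ValueError(f"checkpoint does not match model: {sorted(missing)[:5]}")
        for key, arr in mine.items():
            arr[...] = state[key]


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel=3, stride=1, pad=None, bias=True, rng=None):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), (c_out, c_in, kernel, kernel))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose2d(Module):
    """Kernel-3 stride-2 transposed convolution: doubles spatial size."""

    def __init__(self, c_in, c_out, rng=None):
        rng = rng or np.random.default_rng()
        fan_in = c_in * 9
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), (c_in, c_out, 3, 3))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, 2, 1, 1)


class BatchNorm2d(Module):
    def __init__(self, c):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        return batch_norm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training,
        )


class ConvBnRelu(Module):
    """The conv(3x3) -> batch norm -> ReLU unit both networks are built from."""

    def __init__(self, c_in, c_out, kernel=3, stride=1, rng=None):
        self.conv = Conv2d(c_in, c_out, kernel, stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        return relu(self.bn(self.conv(x)))
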