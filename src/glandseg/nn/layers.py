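"""Layer modules over the autodiff core: parameter containers with He init."""

from __future__ import annotations

import numpy as np

from .tensor import (F32, Parameter, Tensor, avg_pool2, batch_norm, conv2d,
                     relu)


class Module:
    """Base class: recursive parameter/state discovery for optimizers and I/O."""

    training: bool = True

    def modules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield v
                        yield from v.modules()

    def named_parameters(self, prefix=""):
        for name, value in self.__dict__.items():
            if isinstance(value, Parameter):
                yield f"{prefix}{name}", value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield from v.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix=""):
        for name, value in self.__dict__.items():
            if isinstance(value, Module):
                yield from value.named_buffers(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield from v.named_buffers(f"{prefix}{name}.{i}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield f"{prefix}{name}", value

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": p.data for k, p in self.named_parameters()}
        state.update({f"buffer:{k}": b for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                params[name].data = np.asarray(value, dtype=F32).reshape(
                    params[name].data.shape)
            elif kind == "buffer":
                buffers[name][...] = np.asarray(value)


class Conv2d(Module):
    """Convolution with He-normal kernel init; kernels carry weight decay."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(c_out, c_in, kernel, kernel)), decay=True)
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride, self.padding = stride, padding
        self.c_in, self.c_out = c_in, c_out

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    """Batch normalization; affine parameters are excluded from weight decay."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor) -> Tensor:
        return batch_norm(x, self.gamma, self.beta, self.running_mean,
                          self.running_var, self.training, self.momentum, self.eps)


class BnReluConv(Module):
    """Pre-activation unit: BN → ReLU → conv (DenseNet convention)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, padding: int = 0,
                 rng: np.random.Generator | None = None):
        self.bn = BatchNorm2d(c_in)
        self.conv = Conv2d(c_in, c_out, kernel, padding=padding, bias=False,
                           rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(relu(self.bn(x)))


class TransitionDown(Module):
    """Encoder transition: BN-ReLU-1×1 conv (channel halving) + 2×2 avg pool."""

    def __init__(self, c_in: int, c_out: int, rng=None):
        self.unit = BnReluConv(c_in, c_out, kernel=1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return avg_pool2(self.unit(x))
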