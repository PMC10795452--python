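"""Layer/module abstractions over the autograd ops."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: recursive parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        seen = set()
        for mod in self.modules():
            for v in mod.__dict__.values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    yield v

    def named_state(self, prefix=""):
        """Flat name -> array mapping of parameters and buffers."""
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield key, v.data
            elif isinstance(v, np.ndarray):
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_state(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_state(f"{key}.{i}.")

    def state_dict(self):
        return {k: v.copy() for k, v in self.named_state()}

    def load_state_dict(self, state):
        own = dict(self.named_state())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing keys: {sorted(missing)[:5]}")
        for key, arr in own.items():
            src = np.asarray(state[key])
            if src.shape != arr.shape:
                raise ValueError(f"shape mismatch for {key}: {src.shape} vs {arr.shape}")
            arr[...] = src

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self):
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def kaiming_uniform(rng, shape, fan_in):
    bound = float(np.sqrt(6.0 / fan_in))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, rng, bias=True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(kaiming_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def __call__(self, x):
        return ag.conv2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_f, out_f, rng, bias=True):
        super().__init__()
        self.weight = Parameter(kaiming_uniform(rng, (in_f, out_f), in_f))
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def __call__(self, x):
        out = ag.matmul(x, self.weight)
        if self.bias is not None:
            out = ag.add(out, self.bias)
        return out


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x):
        return ag.batchnorm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class ConvBNReLU(Module):
    """The repeated 3x3 conv -> batch norm -> ReLU unit of every encoder/decoder block."""

    def __init__(self, in_ch, out_ch, rng, kernel=3):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, rng)
        self.bn = BatchNorm2d(out_ch)

    def __call__(self, x):
        return ag.relu(self.bn(self.conv(x)))
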