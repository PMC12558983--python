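"""Neural-network modules on top of the autodiff tensor.

Modules register parameters and sub-modules by attribute assignment; a
``ModuleList`` holds ordered children.  Weight initialization is fan-in
scaled Gaussian (He) drawn from an explicit ``numpy.random.Generator`` so
every network is reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, batch_norm, conv2d, relu

__all__ = ["Module", "ModuleList", "Sequential", "Conv2d", "Linear", "BatchNorm2d", "ReLU"]


class Module:
    def __init__(self):
        self.training = True

    # -------------------------------------------------------- traversal
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield (f"{prefix}{name}", value)
        for name, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and not value.requires_grad:
                yield (f"{prefix}{name}", value)
        for name, child in self._children():
            yield from child.named_buffers(prefix=f"{prefix}{name}.")

    def train(self, flag: bool = True):
        self.training = flag
        for _, child in self._children():
            child.train(flag)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # ----------------------------------------------------------- state
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.data.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        own.update(dict(self.named_buffers()))
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, tensor in own.items():
            arr = np.asarray(state[name], dtype=tensor.data.dtype)
            if arr.shape != tensor.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {tensor.data.shape}")
            tensor.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items = list(modules)
        for i, m in enumerate(self._items):
            setattr(self, f"_{i}", m)

    def __iter__(self):
        return iter(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def __len__(self):
        return len(self._items)


class Sequential(ModuleList):
    def forward(self, x):
        for m in self._items:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return relu(x)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        std = float(np.sqrt(2.0 / in_features))
        self.weight = Tensor(rng.normal(0.0, std, size=(in_features, out_features)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel, with running
    statistics and an optionally fused trailing ReLU."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 relu: bool = False):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.relu = relu
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=np.float32), requires_grad=True)
        self.running_mean = Tensor(np.zeros((1, channels, 1, 1), dtype=np.float32))
        self.running_var = Tensor(np.ones((1, channels, 1, 1), dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = batch_norm(x, self.gamma, self.beta, self.eps,
                                      relu=self.relu)
            m = self.momentum
            self.running_mean.data = (1 - m) * self.running_mean.data + m * mu
            self.running_var.data = (1 - m) * self.running_var.data + m * var
            return out
        inv = Tensor(1.0 / np.sqrt(self.running_var.data + self.eps))
        out = (x - self.running_mean) * inv * self.gamma + self.beta
        return relu(out) if self.relu else out
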