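"""Neural-network layer primitives on top of :mod:`marrowdet.autograd`.

Provides the ``Module`` container protocol (parameter discovery, train/eval
mode, state dicts), convolution and batch-norm layers, and a momentum-SGD
optimizer.  Weight initialization draws from an explicit RNG so that model
construction is reproducible bit-for-bit from a seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor

# Batch-norm defaults follow the detector convention (config-exposed upstream).
BN_EPS = 1e-3
BN_MOMENTUM = 0.03

_DEFAULT_RNG = np.random.default_rng(0)


def set_rng(rng: np.random.Generator) -> None:
    """Set the generator used for weight initialization."""
    global _DEFAULT_RNG
    _DEFAULT_RNG = rng


def get_rng() -> np.random.Generator:
    return _DEFAULT_RNG


class Module:
    def __init__(self):
        self.training = True

    # -- discovery -----------------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_tensors(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        """All Tensor attributes (parameters and buffers), depth-first."""
        for name, value in vars(self).items():
            if isinstance(value, Tensor):
                yield (f"{prefix}{name}", value)
        for name, child in self._children():
            yield from child.named_tensors(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_tensors() if t.requires_grad]

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, child in self._children():
            yield from child.modules()

    # -- modes ---------------------------------------------------------------
    def train(self, flag: bool = True) -> "Module":
        for m in self.modules():
            m.training = flag
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- state ---------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.named_tensors()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_tensors())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(
                f"state dict mismatch: missing={sorted(missing)[:5]} "
                f"extra={sorted(extra)[:5]}"
            )
        for name, t in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {t.data.shape}")
            t.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int | None = None, groups: int = 1,
                 bias: bool = False):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("in/out channels must be divisible by groups")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        self.groups = groups
        fan_in = (in_channels // groups) * kernel * kernel
        std = float(np.sqrt(2.0 / fan_in))  # He init
        rng = get_rng()
        self.weight = Tensor(
            rng.normal(0.0, std, (out_channels, in_channels // groups, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"Conv2d configured for {self.in_channels} input channels, got {x.shape[1]}"
            )
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = BN_EPS, momentum: float = BN_MOMENTUM):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = Tensor(np.zeros(channels))
        self.running_var = Tensor(np.ones(channels))
        self.num_batches = Tensor(np.zeros(1))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            m = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - m
            v = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            if self.num_batches.data[0] == 0:
                # warm start: the first batch defines the running statistics,
                # so eval-mode forwards are sane from the first step
                self.running_mean.data = m.data.reshape(-1).copy()
                self.running_var.data = v.data.reshape(-1).copy()
            else:
                self.running_mean.data = (
                    (1 - self.momentum) * self.running_mean.data
                    + self.momentum * m.data.reshape(-1)
                )
                self.running_var.data = (
                    (1 - self.momentum) * self.running_var.data
                    + self.momentum * v.data.reshape(-1)
                )
            self.num_batches.data = self.num_batches.data + 1
            xhat = xc * ((v + self.eps) ** -0.5)
        else:
            m = self.running_mean.data.reshape(1, -1, 1, 1)
            v = self.running_var.data.reshape(1, -1, 1, 1)
            xhat = (x - m) * Tensor((v + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(
            1, -1, 1, 1
        )


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class SGD:
    """Momentum SGD with optional per-group weight decay (detector convention:
    decay applies to convolution weights only, not BN/bias parameters)."""

    def __init__(self, param_groups, lr: float, momentum: float = 0.937):
        # param_groups: list of dicts {"params": [...], "weight_decay": float}
        if param_groups and isinstance(param_groups[0], Tensor):
            param_groups = [{"params": list(param_groups), "weight_decay": 0.0}]
        self.groups = param_groups
        self.lr = lr
        self.momentum = momentum
        self._velocity = {
            id(p): np.zeros_like(p.data)
            for grp in self.groups
            for p in grp["params"]
        }

    def zero_grad(self) -> None:
        for grp in self.groups:
            for p in grp["params"]:
                p.grad = None

    def step(self) -> None:
        for grp in self.groups:
            wd = grp.get("weight_decay", 0.0)
            for p in grp["params"]:
                if p.grad is None:
                    continue
                g = p.grad
                if wd:
                    g = g + wd * p.data
                v = self._velocity[id(p)]
                v *= self.momentum
                v += g
                p.data -= self.lr * v


def split_decay_groups(model: Module, weight_decay: float) -> list[dict]:
    decay, no_decay = [], []
    for _, t in model.named_tensors():
        if not t.requires_grad:
            continue
        (decay if t.data.ndim == 4 else no_decay).append(t)
    return [
        {"params": decay, "weight_decay": weight_decay},
        {"params": no_decay, "weight_decay": 0.0},
    ]
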