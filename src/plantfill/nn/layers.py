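"""Neural-network building blocks on top of the autograd engine.

Weight initialization is fan-in-scaled Gaussian from a seeded generator;
batch normalization keeps running statistics (momentum 0.9) for
evaluation mode.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Module", "Linear", "BatchNorm", "Conv2d", "Sequential"]


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self) -> None:
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Tensor]:
        params = [v for v in vars(self).values() if isinstance(v, Tensor) and v.requires_grad]
        for _, child in self._children():
            params.extend(child.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor):
                state[prefix + name] = value.data.copy()
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                state[prefix + name] = value.copy()
        for name, child in self._children():
            state.update(child.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in vars(self).items():
            key = prefix + name
            if isinstance(value, Tensor) and key in state:
                value.data = np.array(state[key], dtype=np.float64)
            elif isinstance(value, np.ndarray) and name.startswith("running_") and key in state:
                setattr(self, name, np.array(state[key], dtype=np.float64))
        for name, child in self._children():
            child.load_state_dict(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map on the last axis: (..., in) -> (..., out)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, 1.0 / np.sqrt(n_in), (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm(Module):
    """Normalize the trailing feature axis over all leading axes.

    Works for (B, C), (B, N, C) and, via ``axis_last=False``, for image
    tensors (B, C, H, W) where the channel axis is 1.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5,
                 axis_last: bool = True):
        super().__init__()
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self.axis_last = axis_last

    def forward(self, x: Tensor) -> Tensor:
        if self.axis_last:
            reduce_axes = tuple(range(x.ndim - 1))
            shape = (1,) * (x.ndim - 1) + (-1,)
        else:  # channels at axis 1
            reduce_axes = (0,) + tuple(range(2, x.ndim))
            shape = (1, -1) + (1,) * (x.ndim - 2)
        if self.training:
            mu = x
            for ax in sorted(reduce_axes, reverse=True):
                mu = mu.mean(axis=ax, keepdims=True)
            var = (x - mu).pow(2.0)
            for ax in sorted(reduce_axes, reverse=True):
                var = var.mean(axis=ax, keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.reshape(-1)
            self.running_var = m * self.running_var + (1 - m) * var.data.reshape(-1)
            xhat = (x - mu) * (var + self.eps).pow(-0.5)
        else:
            mu = self.running_mean.reshape(shape)
            sd = np.sqrt(self.running_var + self.eps).reshape(shape)
            xhat = (x - mu) * (1.0 / sd)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1):
        super().__init__()
        fan_in = c_in * kernel * kernel
        self.weight = Tensor(
            rng.normal(0.0, 1.0 / np.sqrt(fan_in), (c_out, c_in, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.items = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.items:
            x = m(x)
        return x
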