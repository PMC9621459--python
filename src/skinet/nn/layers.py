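"""Layer/module abstractions over the autodiff core.

Modules own parameters (weights) and buffers (batch-norm running stats),
expose ``train_mode``/``eval_mode`` and, for dropout layers, an
independent ``stochastic`` switch so that dropout can stay active at
inference for Monte-Carlo sampling while batch-norm statistics remain
frozen.
"""

from __future__ import annotations

import numpy as np

from . import core
from .core import Tensor


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def modules(self):
        yield self
        for child in self._children.values():
            yield from child.modules()

    def parameters(self) -> list[Tensor]:
        out = []
        for m in self.modules():
            out.extend(m._params.values())
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train_mode(self):
        for m in self.modules():
            m.training = True
        return self

    def eval_mode(self):
        for m in self.modules():
            m.training = False
        return self

    def set_rng(self, rng: np.random.Generator):
        for m in self.modules():
            if isinstance(m, Dropout):
                m.rng = rng
        return self

    # checkpointing -----------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {}
        for name, p in self._params.items():
            state[prefix + name] = p.data.copy()
        for name, b in self._buffers.items():
            state[prefix + name] = np.asarray(b).copy()
        for name, child in self._children.items():
            state.update(child.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, p in self._params.items():
            p.data = np.array(state[prefix + name], dtype=np.float64)
        for name in list(self._buffers):
            self._buffers[name] = np.array(state[prefix + name])
            object.__setattr__(self, name, self._buffers[name])
        for name, child in self._children.items():
            child.load_state_dict(state, prefix + name + ".")
        return self

    def __call__(self, x):
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """Stride-1 convolution; padding defaults to 'same' for odd kernels."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, padding: int | None = None):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.padding = padding
        fan_in = in_ch * kernel * kernel
        self.register_param("weight", _he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.register_param("bias", np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        return core.conv2d(x, self.weight, self.bias, self.padding)


class ConvTranspose2x2(Module):
    """2x2, stride-2 transposed convolution (exact 2x upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.register_param("weight", _he_init(rng, (in_ch, out_ch, 2, 2), in_ch * 4))
        self.register_param("bias", np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        return core.conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.register_param("gamma", np.ones(channels))
        self.register_param("beta", np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3) if x.data.ndim == 4 else (0,)
        if self.training:
            mean_ = x.data.mean(axis=axes)
            var_ = x.data.var(axis=axes)
            self.running_mean *= (1 - self.momentum)
            self.running_mean += self.momentum * mean_
            self.running_var *= (1 - self.momentum)
            self.running_var += self.momentum * var_
        else:
            mean_, var_ = self.running_mean, self.running_var
        return core.batchnorm(x, self.gamma, self.beta, mean_, var_,
                              self.training, self.eps)


class Dropout(Module):
    """Dropout whose inference behaviour is governed by ``stochastic``.

    Active when training, or when ``stochastic`` is set (Monte-Carlo
    sampling at test time). Fresh masks come from ``rng``.
    """

    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate
        self.stochastic = False
        self.rng = np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if self.rate > 0 and (self.training or self.stochastic):
            return core.dropout(x, self.rate, self.rng)
        return x


class Dense(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.register_param("weight", _he_init(rng, (in_features, out_features), in_features))
        self.register_param("bias", np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return core.matmul(x, self.weight) + self.bias


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999), the training default."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
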