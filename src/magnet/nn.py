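"""Neural-network building blocks on top of the autodiff engine.

Deliberately small: just the layers the magnifying network needs (strided
convolution, batch norm, max pooling, linear layers, a GRU) plus Adam and a
cosine-annealing schedule.  Every module takes an explicit
``numpy.random.Generator`` for weight initialisation so that runs are
reproducible end to end.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from ._tensor import Tensor, batchnorm2d, conv2d, maxpool2d

__all__ = [
    "Adam",
    "BatchNorm2d",
    "Conv2d",
    "GRU",
    "Linear",
    "MaxPool2d",
    "Module",
    "Parameter",
    "ReLU",
    "Sequential",
    "cosine_lr",
]


class Parameter(Tensor):
    """A trainable tensor (``requires_grad`` always on)."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class with recursive parameter/buffer discovery."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item
            elif isinstance(value, dict):
                for key, item in value.items():
                    if isinstance(item, Module):
                        yield f"{name}.{key}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        # deduplicate: shared submodules must not be updated twice
        seen, out = set(), []
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffers", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialisation ---------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        for name, p in own.items():
            if name not in state:
                raise KeyError(f"missing parameter {name!r} in state dict")
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name!r}")
            p.data = state[name].astype(np.float32).copy()
        for name, _ in self.named_buffers():
            if name in state:
                obj, attr = self._resolve(name)
                setattr(obj, attr, state[name].copy())

    def _resolve(self, dotted: str):
        parts = dotted.split(".")
        obj = self
        for part in parts[:-1]:
            if isinstance(obj, (list, tuple)):
                obj = obj[int(part)]
            elif isinstance(obj, dict):
                obj = obj[part]
            else:
                obj = getattr(obj, part)
        return obj, parts[-1]


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Conv2d(Module):
    """2-D convolution with He-normal weight initialisation."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 1, padding: int = 1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return maxpool2d(x, self.kernel, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._buffers = ("running_mean", "running_var")
        self.eps = eps
        self.momentum = momentum

    def forward(self, x):
        C = x.shape[1]
        if self.training:
            out, mu, var = batchnorm2d(x, self.weight, self.bias, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var
                                + m * var).astype(np.float32)
            return out
        # fold running stats into one affine map (fast inference path)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = self.weight * Tensor(inv)
        shift = self.bias - self.weight * Tensor(self.running_mean * inv)
        return x * scale.reshape(1, C, 1, 1) + shift.reshape(1, C, 1, 1)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(1.0 / in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x):
        return x @ self.weight + self.bias


class GRU(Module):
    """Single-layer gated recurrent unit over a python-list sequence.

    ``forward`` consumes a list of (B, F) tensors and returns the final
    hidden state (B, H).  Gate order follows the r/z/n convention.
    """

    def __init__(self, input_size: int, hidden_size: int, *,
                 rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        self.wr = Linear(input_size, hidden_size, rng=rng)
        self.wz = Linear(input_size, hidden_size, rng=rng)
        self.wn = Linear(input_size, hidden_size, rng=rng)
        self.ur = Linear(hidden_size, hidden_size, rng=rng)
        self.uz = Linear(hidden_size, hidden_size, rng=rng)
        self.un = Linear(hidden_size, hidden_size, rng=rng)

    def forward(self, sequence):
        if not sequence:
            raise ValueError("GRU received an empty sequence")
        batch = sequence[0].shape[0]
        h = Tensor(np.zeros((batch, self.hidden_size), dtype=np.float32))
        for x in sequence:
            r = (self.wr(x) + self.ur(h)).sigmoid()
            z = (self.wz(x) + self.uz(h)).sigmoid()
            n = (self.wn(x) + r * self.un(h)).tanh()
            h = (1.0 - z) * n + z * h
        return h


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 3e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(lr0: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from ``lr0`` at epoch 0 towards 0 at the last epoch."""
    if total_epochs <= 1:
        return lr0
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * epoch / (total_epochs - 1)))
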