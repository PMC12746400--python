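"""Layer classes over the autodiff engine, with seeded initialization."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor


class Module:
    """Base class: tracks parameters and submodules by attribute."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                out[prefix + k] = v
        for name, m in self._modules.items():
            out.update(m.buffers(prefix + name + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        sd = {k: v.data.copy() for k, v in self.named_parameters().items()}
        for k, v in self.buffers().items():
            sd["buffer." + k] = v.copy()
        return sd

    def load_state_dict(self, sd: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        bufs = self.buffers()
        for k, v in sd.items():
            if k.startswith("buffer."):
                bufs[k[len("buffer."):]][...] = v
            else:
                params[k].data[...] = v

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...],
             fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, groups: int = 1,
                 zero_init: bool = False):
        super().__init__()
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        fan_in = (in_ch // groups) * k * k
        w = np.zeros((out_ch, in_ch // groups, k, k), dtype=np.float32) \
            if zero_init else _kaiming(rng, (out_ch, in_ch // groups, k, k), fan_in)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 stride: int = 2):
        super().__init__()
        self.stride = stride
        self.weight = Tensor(_kaiming(rng, (in_ch, out_ch, k, k), in_ch * k * k),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    def __init__(self, n_ch: int):
        super().__init__()
        self.gamma = Tensor(np.ones(n_ch, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, training=self.training)


class InstanceNorm2d(Module):
    """Per-sample, per-channel spatial normalization with learned affine."""

    def __init__(self, n_ch: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(n_ch, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=(2, 3), keepdims=True)
        xhat = centered * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(1, -1, 1, 1) \
            + self.beta.reshape(1, -1, 1, 1)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, l in enumerate(layers):
            setattr(self, f"layer{i}", l)

    def forward(self, x):
        for l in self.layers:
            x = l(x) if isinstance(l, Module) else l(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class ConvGRUCell(Module):
    """Convolutional gated recurrent unit (3x3 gates, tanh candidate)."""

    def __init__(self, hidden_ch: int, input_ch: int, rng: np.random.Generator):
        super().__init__()
        self.convz = Conv2d(hidden_ch + input_ch, hidden_ch, 3, rng)
        self.convr = Conv2d(hidden_ch + input_ch, hidden_ch, 3, rng)
        self.convq = Conv2d(hidden_ch + input_ch, hidden_ch, 3, rng)

    def forward(self, h: Tensor, x: Tensor) -> Tensor:
        from .tensor import concatenate
        hx = concatenate([h, x], axis=1)
        z = self.convz(hx).sigmoid()
        r = self.convr(hx).sigmoid()
        q = concatenate([h * r, x], axis=1)
        q = self.convq(q).tanh()
        return h * (1.0 - z) + q * z
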