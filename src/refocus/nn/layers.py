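"""Neural-network modules built on :mod:`refocus.nn.autodiff`.

Initialisation draws from a caller-supplied :class:`numpy.random.Generator`
so that model construction is reproducible end to end.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module: recursive parameter discovery + train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params = []
        for mod in [self, *self.modules()]:
            for v in mod.__dict__.values():
                if isinstance(v, Parameter):
                    params.append(v)
        return params

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- flat state dict (weights + buffers) for checkpointing ---------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        self._collect_state("", out)
        return out

    def _collect_state(self, prefix: str, out: dict):
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Parameter):
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                v._collect_state(key + ".", out)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._collect_state(f"{key}.{i}.", out)

    def load_state_arrays(self, state: dict[str, np.ndarray]):
        self._load_state("", state)

    def _load_state(self, prefix: str, state: dict):
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Parameter):
                v.data = np.asarray(state[key], dtype=v.data.dtype).copy()
            elif isinstance(v, np.ndarray):
                self.__dict__[k] = np.asarray(state[key], dtype=v.dtype).copy()
            elif isinstance(v, Module):
                v._load_state(key + ".", state)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._load_state(f"{key}.{i}.", state)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(ad.DEFAULT_DTYPE)


class Conv2d(Module):
    """3x3 (or 1x1) stride-1 same-padded convolution with bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kernel, kernel),
                                         fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=ad.DEFAULT_DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias)

    __call__ = forward


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel.

    Training mode uses batch statistics (gradient flows through them);
    evaluation mode uses frozen running statistics.
    """

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(n_ch, dtype=ad.DEFAULT_DTYPE))
        self.beta = Parameter(np.zeros(n_ch, dtype=ad.DEFAULT_DTYPE))
        self.running_mean = np.zeros(n_ch, dtype=np.float64)
        self.running_var = np.ones(n_ch, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = (x - mu) / ad.sqrt(var + self.eps)
        else:
            mu = self.running_mean.astype(x.data.dtype)[None, :, None, None]
            sd = np.sqrt(self.running_var + self.eps).astype(x.data.dtype)
            xhat = (x - Tensor(mu)) / Tensor(sd[None, :, None, None])
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b

    __call__ = forward


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_he_init(rng, (in_f, out_f), in_f))
        self.bias = Parameter(np.zeros(out_f, dtype=ad.DEFAULT_DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.weight) + self.bias

    __call__ = forward


class ConvGRUCell(Module):
    """Convolutional gated recurrent unit with a single forget gate.

    One gate f interpolates between the previous hidden state and a tanh
    candidate computed from the gated previous state:

        f_t  = sigmoid(W_f * x_t + U_f * h_{t-1} + b_f)
        hhat = tanh(W_h * x_t + U_h * (f_t . h_{t-1}) + b_h)
        h_t  = (1 - f_t) . h_{t-1} + f_t . hhat

    All convolutions are 3x3, stride 1, same padding; the hidden state has
    the same channel width as the input feature map.
    """

    def __init__(self, channels: int, rng: np.random.Generator, kernel: int = 3):
        super().__init__()
        fan = channels * kernel * kernel
        self.w_f = Parameter(_he_init(rng, (channels, channels, kernel, kernel), fan))
        self.u_f = Parameter(_he_init(rng, (channels, channels, kernel, kernel), fan))
        self.b_f = Parameter(np.zeros(channels, dtype=ad.DEFAULT_DTYPE))
        self.w_h = Parameter(_he_init(rng, (channels, channels, kernel, kernel), fan))
        self.u_h = Parameter(_he_init(rng, (channels, channels, kernel, kernel), fan))
        self.b_h = Parameter(np.zeros(channels, dtype=ad.DEFAULT_DTYPE))
        self.channels = channels

    def step(self, x_t: Tensor, h_prev: Tensor) -> Tensor:
        f = ad.sigmoid(ad.conv2d(x_t, self.w_f) + ad.conv2d(h_prev, self.u_f)
                       + self.b_f.reshape(1, -1, 1, 1))
        hhat = ad.tanh(ad.conv2d(x_t, self.w_h)
                       + ad.conv2d(f * h_prev, self.u_h)
                       + self.b_h.reshape(1, -1, 1, 1))
        return (1.0 - f) * h_prev + f * hhat

    __call__ = step

    def init_state(self, batch: int, height: int, width: int) -> Tensor:
        return Tensor(np.zeros((batch, self.channels, height, width),
                               dtype=ad.DEFAULT_DTYPE))


class Adam:
    """Adam optimizer (Kingma & Ba) over a parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-5,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = (p.data.astype(np.float64)
                      - self.lr * mhat / (np.sqrt(vhat) + self.eps)
                      ).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
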