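"""Layer objects built on the autograd engine.

Weight initialization is Glorot-uniform (dense/conv) and orthogonal-free
scaled-uniform for recurrent kernels, drawn from a caller-supplied
``numpy.random.Generator`` so whole-model initialization is reproducible.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, stack
from . import functional as F

__all__ = ["Module", "Dense", "Conv1d", "Conv3d", "LSTM", "BiLSTM"]

DTYPE = np.float32


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Module:
    """Minimal parameter container with recursive collection."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self):
        return sum(p.size for p in self.parameters())

    def state_dict(self):
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state):
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"p{i}"], dtype=p.data.dtype).reshape(p.shape)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Tensor(_glorot(rng, (n_in, n_out), n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        fan_in, fan_out = c_in * kernel, c_out * kernel
        self.w = Tensor(_glorot(rng, (c_out, c_in, kernel), fan_in, fan_out), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv1d(x, self.w, self.b)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel, rng: np.random.Generator):
        if isinstance(kernel, int):
            kernel = (kernel, kernel, kernel)
        fan_in = c_in * int(np.prod(kernel))
        fan_out = c_out * int(np.prod(kernel))
        self.w = Tensor(_glorot(rng, (c_out, c_in) + tuple(kernel), fan_in, fan_out),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.w, self.b)


class LSTM(Module):
    """Single-direction LSTM over (N, T, D) input, returning (N, T, H)."""

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator):
        h = n_units
        self.n_units = h
        self.wx = Tensor(_glorot(rng, (n_in, 4 * h), n_in, 4 * h), requires_grad=True)
        self.wh = Tensor(_glorot(rng, (h, 4 * h), h, 4 * h), requires_grad=True)
        b = np.zeros(4 * h, dtype=DTYPE)
        b[h:2 * h] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor, reverse: bool = False) -> Tensor:
        n, t, _ = x.shape
        h = self.n_units
        h_t = Tensor(np.zeros((n, h), dtype=DTYPE))
        c_t = Tensor(np.zeros((n, h), dtype=DTYPE))
        outs = []
        steps = range(t - 1, -1, -1) if reverse else range(t)
        for step in steps:
            xt = x[:, step, :]
            z = xt @ self.wx + h_t @ self.wh + self.b
            i = z[:, 0 * h:1 * h].sigmoid()
            f = z[:, 1 * h:2 * h].sigmoid()
            o = z[:, 2 * h:3 * h].sigmoid()
            g = z[:, 3 * h:4 * h].tanh()
            c_t = f * c_t + i * g
            h_t = o * c_t.tanh()
            outs.append(h_t)
        if reverse:
            outs = outs[::-1]
        return stack(outs, axis=1)


class BiLSTM(Module):
    """Bidirectional LSTM, concatenating forward/backward states -> (N,T,2H)."""

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator):
        self.fwd = LSTM(n_in, n_units, rng)
        self.bwd = LSTM(n_in, n_units, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return concat([self.fwd(x), self.bwd(x, reverse=True)], axis=2)
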