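"""Layers used by the methylation prediction networks.

Each layer owns named :class:`~cpgfill.nn.tensor.Tensor` parameters (and, for
batch normalisation, non-trained running-statistic buffers).  Layers are
initialised from an explicit ``numpy.random.Generator`` so that model
construction is reproducible.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, conv1d, maxpool1d


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: a container of named parameters and buffers."""

    def __init__(self):
        self.params: dict[str, Tensor] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.params.items()}
        out.update({f"buf::{k}": v.copy() for k, v in self.buffers.items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k.startswith("buf::"):
                name = k[5:]
                if self.buffers[name].shape != v.shape:
                    raise ValueError(f"buffer {name}: shape {v.shape} != "
                                     f"{self.buffers[name].shape}")
                self.buffers[name] = v.copy()
            else:
                if self.params[k].data.shape != v.shape:
                    raise ValueError(f"parameter {k}: shape {v.shape} != "
                                     f"{self.params[k].data.shape}")
                self.params[k].data = v.astype(np.float64).copy()


class Dense(Layer):
    def __init__(self, rng, n_in: int, n_out: int):
        super().__init__()
        self.params["w"] = Tensor(glorot(rng, n_in, n_out, (n_in, n_out)),
                                  requires_grad=True)
        self.params["b"] = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        return x @ self.params["w"] + self.params["b"]


class Conv1d(Layer):
    """Valid 1-D convolution over (batch, length, channels)."""

    def __init__(self, rng, n_in_channels: int, n_filters: int, filter_len: int):
        super().__init__()
        kc = filter_len * n_in_channels
        self.filter_len = filter_len
        self.params["w"] = Tensor(glorot(rng, kc, n_filters, (kc, n_filters)),
                                  requires_grad=True)
        self.params["b"] = Tensor(np.zeros(n_filters), requires_grad=True)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        return conv1d(x, self.params["w"], self.params["b"])


class MaxPool1d(Layer):
    def __init__(self, pool_len: int):
        super().__init__()
        self.pool_len = pool_len

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        return maxpool1d(x, self.pool_len)


class BatchNorm(Layer):
    """Normalises over every axis except the last (channel/feature) axis.

    Training passes use batch statistics and update exponential running
    statistics; inference uses the stored running statistics, so inference
    is deterministic and batch-size independent.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = Tensor(np.ones(n_features), requires_grad=True)
        self.params["beta"] = Tensor(np.zeros(n_features), requires_grad=True)
        self.buffers["running_mean"] = np.zeros(n_features)
        self.buffers["running_var"] = np.ones(n_features)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        axes = tuple(range(x.data.ndim - 1))
        if training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.buffers["running_mean"] = ((1 - m) * self.buffers["running_mean"]
                                            + m * mu.data.reshape(-1))
            self.buffers["running_var"] = ((1 - m) * self.buffers["running_var"]
                                           + m * var.data.reshape(-1))
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = self.buffers["running_mean"]
            sd = np.sqrt(self.buffers["running_var"] + self.eps)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xhat * self.params["gamma"] + self.params["beta"]


class GRU(Layer):
    """Single-direction gated recurrent unit over (batch, steps, n_in)."""

    def __init__(self, rng, n_in: int, n_hidden: int, reverse: bool = False):
        super().__init__()
        self.n_hidden = n_hidden
        self.reverse = reverse
        for gate in ("z", "r", "n"):
            self.params[f"w{gate}"] = Tensor(
                glorot(rng, n_in, n_hidden, (n_in, n_hidden)), requires_grad=True)
            self.params[f"u{gate}"] = Tensor(
                glorot(rng, n_hidden, n_hidden, (n_hidden, n_hidden)),
                requires_grad=True)
            self.params[f"b{gate}"] = Tensor(np.zeros(n_hidden),
                                             requires_grad=True)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        B, T, _ = x.data.shape
        p = self.params
        h = Tensor(np.zeros((B, self.n_hidden)))
        steps = range(T - 1, -1, -1) if self.reverse else range(T)
        for t in steps:
            xt = x[:, t, :]
            z = (xt @ p["wz"] + h @ p["uz"] + p["bz"]).sigmoid()
            r = (xt @ p["wr"] + h @ p["ur"] + p["br"]).sigmoid()
            n = (xt @ p["wn"] + (r * h) @ p["un"] + p["bn"]).tanh()
            h = (1.0 - z) * h + z * n
        return h


class BiGRU(Layer):
    """Bidirectional GRU; output is the concatenated final states (2*hidden)."""

    def __init__(self, rng, n_in: int, n_hidden: int):
        super().__init__()
        self.fwd = GRU(rng, n_in, n_hidden, reverse=False)
        self.bwd = GRU(rng, n_in, n_hidden, reverse=True)
        for k, v in self.fwd.params.items():
            self.params[f"fwd_{k}"] = v
        for k, v in self.bwd.params.items():
            self.params[f"bwd_{k}"] = v

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        return concat([self.fwd.forward(x), self.bwd.forward(x)], axis=-1)
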