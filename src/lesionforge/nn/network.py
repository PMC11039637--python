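"""Sequential container plus the Adam optimiser."""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .layers import Dropout, Layer

__all__ = ["Network", "Adam"]


class Network:
    """A plain sequential stack of :class:`~lesionforge.nn.layers.Layer`."""

    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    __call__ = forward

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def set_rng(self, rng: np.random.Generator) -> None:
        """Hand a single RNG to every stochastic layer (dropout masks)."""
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def parameters(self) -> Iterable[tuple[Layer, str]]:
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                state[f"{i}.{name}"] = value.copy()
            for name in ("running_mean", "running_var"):
                if hasattr(layer, name):
                    state[f"{i}.{name}"] = getattr(layer, name).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, value in state.items():
            idx, name = key.split(".", 1)
            layer = self.layers[int(idx)]
            if name in layer.params:
                layer.params[name] = np.asarray(value, dtype=np.float32).copy()
            else:
                setattr(layer, name, np.asarray(value, dtype=np.float32).copy())


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, network: Network, learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.network = network
        self.lr = float(learning_rate)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, name in self.network.parameters():
            grad = layer.grads.get(name)
            if grad is None:
                continue
            key = (id(layer), name)
            m = self._m.get(key)
            if m is None:
                m = np.zeros_like(layer.params[name])
                v = np.zeros_like(layer.params[name])
            else:
                v = self._v[key]
            m = b1 * m + (1 - b1) * grad
            v = b2 * v + (1 - b2) * grad * grad
            self._m[key], self._v[key] = m, v
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            layer.params[name] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
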