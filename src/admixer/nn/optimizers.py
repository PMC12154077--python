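"""First-order stochastic optimizers: Adam, Adagrad, Adamax, Nadam.

Hyperparameters beyond the learning rate use the customary defaults
(beta1 = 0.9, beta2 = 0.999, eps = 1e-7 for the Adam family; eps = 1e-7
accumulator offset for Adagrad).
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_optimizer", "Optimizer"]


class Optimizer:
    def __init__(self, lr: float):
        if lr < 0:
            raise ValueError(f"learning rate must be >= 0, got {lr}")
        self.lr = lr
        self.state: dict[int, dict] = {}
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            st = self.state.setdefault(i, self._init_state(p))
            self._update(p, g, st)

    def _init_state(self, p):
        raise NotImplementedError

    def _update(self, p, g, st):
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps

    def _init_state(self, p):
        return {"m": np.zeros_like(p), "v": np.zeros_like(p)}

    def _update(self, p, g, st):
        st["m"] = self.b1 * st["m"] + (1 - self.b1) * g
        st["v"] = self.b2 * st["v"] + (1 - self.b2) * g * g
        mhat = st["m"] / (1 - self.b1**self.t)
        vhat = st["v"] / (1 - self.b2**self.t)
        p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adagrad(Optimizer):
    def __init__(self, lr=0.001, eps=1e-7):
        super().__init__(lr)
        self.eps = eps

    def _init_state(self, p):
        return {"G": np.zeros_like(p)}

    def _update(self, p, g, st):
        st["G"] += g * g
        p -= self.lr * g / (np.sqrt(st["G"]) + self.eps)


class Adamax(Optimizer):
    def __init__(self, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps

    def _init_state(self, p):
        return {"m": np.zeros_like(p), "u": np.zeros_like(p)}

    def _update(self, p, g, st):
        st["m"] = self.b1 * st["m"] + (1 - self.b1) * g
        st["u"] = np.maximum(self.b2 * st["u"], np.abs(g))
        p -= self.lr / (1 - self.b1**self.t) * st["m"] / (st["u"] + self.eps)


class Nadam(Optimizer):
    """Adam with a Nesterov look-ahead on the first moment."""

    def __init__(self, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps

    def _init_state(self, p):
        return {"m": np.zeros_like(p), "v": np.zeros_like(p)}

    def _update(self, p, g, st):
        st["m"] = self.b1 * st["m"] + (1 - self.b1) * g
        st["v"] = self.b2 * st["v"] + (1 - self.b2) * g * g
        mhat = st["m"] / (1 - self.b1 ** (self.t + 1))
        vhat = st["v"] / (1 - self.b2**self.t)
        m_bar = self.b1 * mhat + (1 - self.b1) * g / (1 - self.b1**self.t)
        p -= self.lr * m_bar / (np.sqrt(vhat) + self.eps)


_OPTIMIZERS = {"adam": Adam, "adagrad": Adagrad, "adamax": Adamax, "nadam": Nadam}


def make_optimizer(name: str, lr: float = 0.001, **kwargs) -> Optimizer:
    if name not in _OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}; options: {sorted(_OPTIMIZERS)}")
    return _OPTIMIZERS[name](lr=lr, **kwargs)
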