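"""Adam optimizer used by every trainable model in the pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .errors import ContractError

__all__ = ["OptimizerConfig", "Adam"]


@dataclass
class OptimizerConfig:
    algorithm: str = "adam"
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    learning_rate: float = 0.05
    epochs: int = 60
    batch_size: int = 4096
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm != "adam":
            raise ContractError(f"unsupported optimizer {self.algorithm!r}")
        if not (0.0 < self.beta1 < 1.0 and 0.0 < self.beta2 < 1.0):
            raise ContractError("beta1 and beta2 must lie in (0, 1)")
        if self.epsilon <= 0:
            raise ContractError("epsilon must be positive")
        if self.epochs < 1:
            raise ContractError("epochs must be >= 1")


class Adam:
    """First/second-moment adaptive gradient steps over named parameter arrays."""

    def __init__(self, cfg: OptimizerConfig):
        self.cfg = cfg
        self.t = 0
        self._m: Dict[str, np.ndarray] = {}
        self._v: Dict[str, np.ndarray] = {}

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        for key, g in grads.items():
            p = params[key]
            m = self._m.setdefault(key, np.zeros_like(p))
            v = self._v.setdefault(key, np.zeros_like(p))
            m *= c.beta1
            m += (1 - c.beta1) * g
            v *= c.beta2
            v += (1 - c.beta2) * g * g
            m_hat = m / (1 - c.beta1 ** self.t)
            v_hat = v / (1 - c.beta2 ** self.t)
            p -= c.learning_rate * m_hat / (np.sqrt(v_hat) + c.epsilon)
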