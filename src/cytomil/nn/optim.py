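"""Adam optimizer over (params, grads, key) slots."""

from __future__ import annotations

import numpy as np

ParamSlot = tuple[dict, dict, str]


class Adam:
    """Adam with bias correction. ``lr`` is mutable so a plateau
    scheduler can rescale it between epochs."""

    def __init__(
        self,
        slots: list[ParamSlot],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.slots = slots
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p[k]) for p, _, k in slots]
        self._v = [np.zeros_like(p[k]) for p, _, k in slots]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, (params, grads, key) in enumerate(self.slots):
            g = grads[key]
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / bc1
            v_hat = self._v[i] / bc2
            params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
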