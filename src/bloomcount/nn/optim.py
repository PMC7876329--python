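"""Adam optimizer over the layer parameter/gradient dict contract."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with L2 weight decay added to the gradient.

    ``layers`` is any iterable of objects exposing ``params()`` and
    ``grads()`` dicts with matching keys; parameter arrays are updated
    in place so the owning model sees the new values.
    """

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.99, weight_decay: float = 1e-5,
                 eps: float = 1e-8) -> None:
        self.layers = [lyr for lyr in layers if lyr.params()]
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in lyr.params().items()}
                   for lyr in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in lyr.params().items()}
                   for lyr in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for lyr, m_s, v_s in zip(self.layers, self._m, self._v):
            ps, gs = lyr.params(), lyr.grads()
            for k, p in ps.items():
                g = gs[k]
                if self.weight_decay:
                    g = g + self.weight_decay * p
                m = m_s[k]
                v = v_s[k]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
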