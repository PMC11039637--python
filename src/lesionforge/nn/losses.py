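"""Training losses: smoothed-Jaccard (segmentation) and softmax cross-entropy."""
from __future__ import annotations

import numpy as np

__all__ = ["smoothed_jaccard_loss", "softmax", "softmax_cross_entropy"]


def smoothed_jaccard_loss(probs: np.ndarray, masks: np.ndarray,
                          eps: float = 1.0) -> tuple[float, np.ndarray]:
    """Mean over the batch of ``1 - J_eps`` with the smoothed Jaccard

    ``J_eps = (eps + sum(p*y)) / (eps + sum(y) + sum(p) - sum(p*y))``

    computed per image over all pixels.  Returns ``(loss, dL/dprobs)``.
    """
    p = probs.reshape(probs.shape[0], -1).astype(np.float64)
    y = masks.reshape(masks.shape[0], -1).astype(np.float64)
    inter = (p * y).sum(axis=1)
    num = eps + inter
    den = eps + y.sum(axis=1) + p.sum(axis=1) - inter
    j = num / den
    loss = float(np.mean(1.0 - j))
    # dJ/dp_k = (y_k * den - num * (1 - y_k)) / den^2 ; dL/dp = -dJ/dp / N
    djdp = (y * den[:, None] - num[:, None] * (1.0 - y)) / (den[:, None] ** 2)
    dprobs = (-djdp / p.shape[0]).reshape(probs.shape).astype(np.float32)
    return loss, dprobs


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch; labels are local integer indices."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32)
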