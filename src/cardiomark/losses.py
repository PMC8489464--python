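"""The combined training loss: Kullback-Leibler divergence + soft Dice.

The network's per-pixel scores are softmaxed into a class distribution and
compared against the ground-truth heatmap two ways:

* **KL term** — mean over pixels of ``sum_c p_c log(p_c / q_c)`` between the
  truth ``p`` and prediction ``q``: the entropy-based part, sensitive to the
  full distribution shape.
* **soft Dice term** — one minus the mean (over landmark channels, background
  excluded) of ``2 * sum(p q) / (sum p + sum q + eps)``: the region-overlap
  part.  The Dice *similarity* enters the total as ``1 - dice`` so that the
  sum of the two terms is a proper loss, zero at a perfect one-hot match.

Analytic gradients with respect to the raw scores are provided (chained
through the softmax), which also powers the saliency map: the magnitude of
the loss derivative with respect to each input pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_Q_FLOOR = 1e-12
_DICE_EPS = 1e-8


@dataclass
class LossValue:
    """KL term, soft-Dice term, and their sum."""

    kl_term: float
    dice_term: float

    @property
    def total(self) -> float:
        return self.kl_term + self.dice_term


def _as_nchw(arr: np.ndarray) -> np.ndarray:
    """Accept (C,H,W), (N,C,H,W) or (H,W,C) heatmap layouts; return NCHW."""
    a = np.asarray(arr)
    if a.dtype not in (np.float32, np.float64):
        a = a.astype(np.float64)
    if a.ndim == 3:
        # Heatmap containers are (H, W, C) with few channels; network tensors
        # are (C, H, W).  Disambiguate by which axis is smallest.
        if a.shape[2] <= a.shape[0] and a.shape[2] <= a.shape[1]:
            a = a.transpose(2, 0, 1)
        a = a[None]
    if a.ndim != 4:
        raise ValueError(f"expected 3D or 4D probability tensor, got shape {arr.shape}")
    return a


def softmax_probs(scores: np.ndarray, channel_axis: int = 1) -> np.ndarray:
    """Numerically stable per-pixel softmax over the channel axis."""
    s = np.asarray(scores)
    if s.dtype not in (np.float32, np.float64):
        s = s.astype(np.float64)
    s = s - s.max(axis=channel_axis, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=channel_axis, keepdims=True)


def kl_loss(truth: np.ndarray, pred: np.ndarray) -> float:
    """Mean over pixels of ``sum_c p log(p/q)``; ``0 log 0 = 0``, q floored."""
    p = _as_nchw(truth)
    q = _as_nchw(pred)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: truth {p.shape} vs pred {q.shape}")
    q = np.where(q > 0, q, _Q_FLOOR)  # floor only true zeros: KL(p, p) == 0 exactly
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * (np.log(p) - np.log(q)), 0.0)
    n_pix = p.shape[0] * p.shape[2] * p.shape[3]
    return float(terms.sum() / n_pix)


def soft_dice_term(truth: np.ndarray, pred: np.ndarray, background_index: int = 0) -> float:
    """``1 - mean soft Dice`` over landmark channels (background excluded).

    Per sample and landmark channel, ``dice = 2 sum(pq) / (sum p + sum q + eps)``.
    """
    p = _as_nchw(truth)
    q = _as_nchw(pred)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: truth {p.shape} vs pred {q.shape}")
    fg = [c for c in range(p.shape[1]) if c != background_index]
    pf, qf = p[:, fg], q[:, fg]
    inter = (pf * qf).sum(axis=(2, 3))
    denom = pf.sum(axis=(2, 3)) + qf.sum(axis=(2, 3)) + _DICE_EPS
    dice = 2.0 * inter / denom
    return float(1.0 - dice.mean())


def combined_loss(truth: np.ndarray, pred: np.ndarray) -> LossValue:
    """KL + (1 - soft Dice); zero iff the prediction matches a one-hot truth."""
    return LossValue(kl_loss(truth, pred), soft_dice_term(truth, pred))


def loss_grad_scores(truth: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Analytic gradient of the combined loss with respect to raw scores.

    KL through softmax contributes ``(q - p) / n_pixels``; the Dice part is
    chained through the softmax Jacobian ``dq_c = q_c (g_c - sum_k g_k q_k)``.
    """
    p = _as_nchw(truth)
    s = np.asarray(scores)
    if s.dtype not in (np.float32, np.float64):
        s = s.astype(np.float64)
    squeeze = s.ndim == 3
    if squeeze:
        s = s[None]
    q = softmax_probs(s, channel_axis=1)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: truth {p.shape} vs scores {s.shape}")
    N, C, H, W = p.shape
    n_pix = N * H * W
    grad = (q - p) / n_pix

    # Dice part: d(1 - mean dice)/dq for foreground channels.
    g = np.zeros_like(q)
    fg = list(range(1, C))
    inter = (p[:, fg] * q[:, fg]).sum(axis=(2, 3))
    psum = p[:, fg].sum(axis=(2, 3))
    qsum = q[:, fg].sum(axis=(2, 3))
    denom = psum + qsum + _DICE_EPS
    # d dice_c / d q_cx = (2 p_cx * denom - 2 inter) / denom^2
    coef_p = 2.0 / denom
    coef_const = 2.0 * inter / denom**2
    n_terms = N * len(fg)
    g[:, fg] = -(
        coef_p[:, :, None, None] * p[:, fg] - coef_const[:, :, None, None]
    ) / n_terms
    gq = (g * q).sum(axis=1, keepdims=True)
    grad += q * (g - gq)
    return grad[0] if squeeze else grad


def saliency_map(model, image: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Magnitude of the loss gradient with respect to each input pixel.

    ``image`` is a 2D (already normalized) pixel grid; ``truth`` the target
    heatmap in any accepted layout.  Regions with large values influenced the
    loss most — the standard input-gradient interpretation of what the model
    attends to.
    """
    x = np.asarray(image, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("image must be a 2D pixel grid")
    scores = model.forward(x[None, None])
    dscores = loss_grad_scores(truth, scores)
    model.zero_grad()
    dx = model.backward(dscores)
    if not np.all(np.isfinite(dx)):
        raise FloatingPointError("saliency gradient is not finite")
    return np.abs(dx[0, 0])
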