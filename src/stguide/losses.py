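"""Training objectives for both phases.

Phase 1 (supervised reference training):
    L_pre = L_A + alpha * L_G + beta * L_c
with L_G the mean per-spot squared reconstruction error, L_A the binary
cross-entropy between the composed-graph adjacency and its inner-product
reconstruction, and L_c the mean categorical cross-entropy of the
classifier against reference annotations.

Phase 2 (knowledge-guided joint training):
    L_joint = L_A + eta * L_G + theta * L_TL
where L_TL pulls the joint reference embedding z_r' toward the frozen
supervised embedding z_r (mean per-spot squared distance).  All four
weights default to 10.

Probabilities are clamped to [1e-7, 1 - 1e-7] before logarithms.  On
graphs above ``DENSE_ADJ_LIMIT`` nodes the adjacency loss is estimated
from all positive entries plus an equal-size uniform sample of negative
entries instead of the full dense n^2 block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor

__all__ = [
    "LossWeights",
    "expression_loss",
    "adjacency_loss",
    "classification_loss",
    "transfer_loss",
    "phase1_total",
    "phase2_total",
]

CLAMP = 1e-7
DENSE_ADJ_LIMIT = 2000


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composite objectives (all default to 10)."""

    alpha: float = 10.0
    beta: float = 10.0
    eta: float = 10.0
    theta: float = 10.0

    def __post_init__(self):
        for name in ("alpha", "beta", "eta", "theta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def expression_loss(x_rec, x) -> Tensor:
    """Mean over spots of squared Euclidean reconstruction error."""
    x_rec, x = _as_tensor(x_rec), _as_tensor(x)
    if x_rec.shape != x.shape:
        raise ValueError(f"shape mismatch {x_rec.shape} vs {x.shape}")
    return ((x_rec - x) ** 2.0).sum(axis=1).mean()


def _bce(pred: Tensor, target: np.ndarray) -> Tensor:
    p = pred.clip(CLAMP, 1.0 - CLAMP)
    t = Tensor(target)
    return -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()


def adjacency_loss(
    a_rec,
    a: np.ndarray,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Binary cross-entropy between adjacency and its reconstruction.

    ``a_rec`` may be the dense (n, n) reconstruction tensor, or — for
    graphs beyond :data:`DENSE_ADJ_LIMIT` — a callable ``(rows, cols) ->
    Tensor`` evaluating reconstruction entries, in which case the loss is
    estimated on all positive entries plus an equal uniform sample of
    negatives drawn from ``rng``.
    """
    a = np.asarray(a.todense() if hasattr(a, "todense") else a, dtype=np.float64)
    n = a.shape[0]
    if callable(a_rec):
        pos_r, pos_c = np.nonzero(a)
        n_neg = max(pos_r.size, 1)
        rng = rng or np.random.default_rng(0)
        neg_r = rng.integers(0, n, size=n_neg)
        neg_c = rng.integers(0, n, size=n_neg)
        rows = np.concatenate([pos_r, neg_r])
        cols = np.concatenate([pos_c, neg_c])
        pred = a_rec(rows, cols)
        return _bce(pred, a[rows, cols])
    a_rec = _as_tensor(a_rec)
    if a_rec.shape != a.shape:
        raise ValueError(f"shape mismatch {a_rec.shape} vs {a.shape}")
    if np.any((a_rec.data < 0) | (a_rec.data > 1)):
        raise ValueError("reconstructed adjacency outside [0, 1]")
    return _bce(a_rec, a)


def classification_loss(y_prob, y_true: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy over reference spots."""
    y_prob = _as_tensor(y_prob)
    y_true = np.asarray(y_true, dtype=np.intp)
    n, k = y_prob.shape
    if y_true.shape != (n,):
        raise ValueError("label vector length mismatch")
    if y_true.min() < 0 or y_true.max() >= k:
        raise ValueError("label code out of range")
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y_true] = 1.0
    p = y_prob.clip(CLAMP, 1.0 - CLAMP)
    return -(Tensor(onehot) * p.log()).sum(axis=1).mean()


def transfer_loss(z_target, z_current) -> Tensor:
    """Mean per-spot squared distance to the frozen phase-1 embedding.

    ``z_target`` carries no gradient: only the phase-2 embedding moves.
    """
    z_current = _as_tensor(z_current)
    z_target = Tensor(np.asarray(z_target.data if isinstance(z_target, Tensor) else z_target))
    if z_target.shape != z_current.shape:
        raise ValueError(f"row mismatch {z_target.shape} vs {z_current.shape}")
    return ((z_current - z_target) ** 2.0).sum(axis=1).mean()


def phase1_total(l_adj, l_expr, l_cls, weights: LossWeights) -> Tensor:
    return _as_tensor(l_adj) + weights.alpha * _as_tensor(l_expr) + weights.beta * _as_tensor(l_cls)


def phase2_total(l_adj, l_expr, l_transfer, weights: LossWeights) -> Tensor:
    return _as_tensor(l_adj) + weights.eta * _as_tensor(l_expr) + weights.theta * _as_tensor(l_transfer)
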