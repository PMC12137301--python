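"""Agreement metrics between transferred and ground-truth labels.

Accuracy compares codes literally (valid because transfer outputs live
in the reference vocabulary).  The adjusted Rand index is the
pair-counting Rand index corrected by its expectation under the
permutation model, and normalized mutual information is
``2 I(Y, Y') / (H(Y) + H(Y'))`` with natural-log entropies; both are
computed from the contingency table from first principles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricsReport",
    "accuracy",
    "adjusted_rand_index",
    "normalized_mutual_information",
    "compute_metrics",
]


@dataclass
class MetricsReport:
    accuracy: float
    ari: float
    nmi: float
    n_spots: int
    contingency: np.ndarray  # true x predicted counts

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "ari": self.ari,
            "nmi": self.nmi,
            "n_spots": self.n_spots,
            "contingency": self.contingency.tolist(),
        }


def _check(y_true, y_pred, min_len=1):
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    if y_true.size < min_len:
        raise ValueError(f"need at least {min_len} labels")
    return y_true, y_pred


def _contingency(y_true, y_pred) -> np.ndarray:
    t_cats, t_codes = np.unique(y_true, return_inverse=True)
    p_cats, p_codes = np.unique(y_pred, return_inverse=True)
    table = np.zeros((t_cats.size, p_cats.size), dtype=np.int64)
    np.add.at(table, (t_codes, p_codes), 1)
    return table


def accuracy(y_true, y_pred) -> float:
    """Fraction of spots whose predicted code equals the true code."""
    y_true, y_pred = _check(y_true, y_pred)
    return float(np.mean(y_true == y_pred))


def adjusted_rand_index(y_true, y_pred) -> float:
    """Pair-counting ARI with the permutation-model expectation.

    Degenerate cases where the correction denominator vanishes (e.g.
    both labelings a single cluster) return 1.0 by convention.
    """
    y_true, y_pred = _check(y_true, y_pred, min_len=2)
    table = _contingency(y_true, y_pred).astype(np.float64)
    n = table.sum()

    def comb2(x):
        return x * (x - 1.0) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def normalized_mutual_information(y_true, y_pred) -> float:
    """``2 I / (H_true + H_pred)`` with natural-log entropies.

    If both entropies are zero the labelings are identical partitions
    and 1.0 is returned; if exactly one is zero, 0.0.
    """
    y_true, y_pred = _check(y_true, y_pred)
    table = _contingency(y_true, y_pred).astype(np.float64)
    n = table.sum()
    p = table / n
    pt = p.sum(axis=1)
    pp = p.sum(axis=0)

    def entropy(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    h_t, h_p = entropy(pt), entropy(pp)
    if h_t + h_p == 0.0:
        return 1.0
    nz = p > 0
    mi = float((p[nz] * np.log(p[nz] / np.outer(pt, pp)[nz])).sum())
    return float(2.0 * mi / (h_t + h_p))


def compute_metrics(y_true, y_pred) -> MetricsReport:
    y_true, y_pred = _check(y_true, y_pred)
    return MetricsReport(
        accuracy=accuracy(y_true, y_pred),
        ari=adjusted_rand_index(y_true, y_pred),
        nmi=normalized_mutual_information(y_true, y_pred),
        n_spots=int(y_true.size),
        contingency=_contingency(y_true, y_pred),
    )
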