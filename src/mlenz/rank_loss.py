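"""Pairwise rank-exponential loss for multi-label learning (BP-MLL).

For an instance with per-class network outputs ``l`` in (0,1)^Q and true
label set ``L`` (complement ``L̄``), the per-instance loss is

    E_i = (1 / (|L| |L̄|)) * sum_{k in L, q in L̄} exp(-(l_k - l_q))

which penalizes every false label ranked above a true label, exponentially
in the score gap. Both ``L`` and its complement must be non-empty, otherwise
the normalization is undefined; degenerate label sets are a hard error here.

The independent-label alternative ``sum_j (l_j - d_j)^2`` is provided for
contrast and for the binary level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class LabelSet:
    """A subset of the classes ``{1, ..., Q}`` attached to one instance.

    Classes are 1-based (EC main classes 1-6 when Q = 6).
    """

    members: frozenset[int]
    q: int

    def __init__(self, members: Iterable[int], q: int):
        members = frozenset(int(m) for m in members)
        if q < 1:
            raise ValueError(f"Q must be >= 1, got {q}")
        if not members <= frozenset(range(1, q + 1)):
            bad = sorted(members - frozenset(range(1, q + 1)))
            raise ValueError(f"labels {bad} outside 1..{q}")
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "q", q)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, j: int) -> bool:
        return j in self.members

    def __iter__(self):
        return iter(sorted(self.members))

    def indicator(self) -> np.ndarray:
        """0/1 vector d with d[j-1] = 1 iff class j is a member."""
        d = np.zeros(self.q)
        for j in self.members:
            d[j - 1] = 1.0
        return d

    def complement(self) -> frozenset[int]:
        return frozenset(range(1, self.q + 1)) - self.members


class DegenerateLabelSetError(ValueError):
    """Label set empty or full: the rank loss normalization is undefined."""


def _masks(labels: LabelSet, q: int) -> tuple[np.ndarray, np.ndarray]:
    d = labels.indicator().astype(bool)
    if d.shape != (q,):
        raise ValueError(f"label set is over Q={labels.q} but scores have length {q}")
    if d.all() or not d.any():
        raise DegenerateLabelSetError(
            "rank loss undefined: empty label set or empty complement"
        )
    return d, ~d


def _as_scores(scores: Sequence[float] | np.ndarray) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1:
        raise ValueError(f"score vector must be 1-D, got shape {s.shape}")
    return s


def bpmll_loss(scores: Sequence[float] | np.ndarray, labels: LabelSet) -> float:
    """Per-instance pairwise rank-exponential loss.

    Vectorized over the |L| x |L̄| pair grid; strictly positive and smooth
    in the scores.
    """
    s = _as_scores(scores)
    pos, neg = _masks(labels, s.size)
    # exp(-(l_k - l_q)) over the pair grid = exp(-l_k) outer exp(+l_q)
    pair = np.exp(-s[pos])[:, None] * np.exp(s[neg])[None, :]
    return float(pair.sum() / (pos.sum() * neg.sum()))


def bpmll_gradient(scores: Sequence[float] | np.ndarray, labels: LabelSet) -> np.ndarray:
    """Analytic gradient of :func:`bpmll_loss` with respect to the scores.

    For a true class j: dE/dl_j = -(1/(|L||L̄|)) sum_{q in L̄} exp(-(l_j - l_q));
    for a false class j: dE/dl_j = +(1/(|L||L̄|)) sum_{k in L} exp(-(l_k - l_j)).
    """
    s = _as_scores(scores)
    pos, neg = _masks(labels, s.size)
    norm = 1.0 / (pos.sum() * neg.sum())
    grad = np.zeros_like(s)
    exp_neg = np.exp(s[neg]).sum()
    exp_pos = np.exp(-s[pos]).sum()
    grad[pos] = -norm * np.exp(-s[pos]) * exp_neg
    grad[neg] = norm * np.exp(s[neg]) * exp_pos
    return grad


def batch_loss(
    scores_list: Sequence[Sequence[float] | np.ndarray],
    labels_list: Sequence[LabelSet],
) -> float:
    """Sum of per-instance rank losses over a batch (the training objective).

    An empty batch sums to 0. A degenerate instance raises with its index.
    """
    if len(scores_list) != len(labels_list):
        raise ValueError(
            f"got {len(scores_list)} score vectors but {len(labels_list)} label sets"
        )
    total = 0.0
    for i, (s, lab) in enumerate(zip(scores_list, labels_list)):
        try:
            total += bpmll_loss(s, lab)
        except DegenerateLabelSetError as exc:
            raise DegenerateLabelSetError(f"instance {i}: {exc}") from exc
    return total


def squared_loss(scores: Sequence[float] | np.ndarray, labels: LabelSet) -> float:
    """Independent-label squared error: sum_j (l_j - d_j)^2."""
    s = _as_scores(scores)
    d = labels.indicator()
    if d.size != s.size:
        raise ValueError(f"label set over Q={labels.q} but scores have length {s.size}")
    return float(((s - d) ** 2).sum())
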