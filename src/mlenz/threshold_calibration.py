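"""Self-adapted label-assignment threshold.

A trained multi-label network outputs a score vector ``l(x)`` in (0,1)^Q;
labels are assigned as ``{j : l_j > t(x)}`` where the per-instance threshold
is a linear function of the scores, ``t(x) = w . l(x) + b``.

The threshold function is fitted by linear least squares to per-instance
*optimal* thresholds: for a training instance with true set ``L``, the
optimal threshold minimizes the misclassified-label count

    f(t) = |{k in L : l_k <= t}| + |{q not in L : l_q >= t}|.

``f`` is piecewise constant between the distinct score values, so its
minimizers form open intervals; the middle value of the minimizing interval
is taken as the target threshold (e.g. scores (0.9, 0.8, 0.3, 0.1, 0.1, 0.1)
with true classes {1, 2} give the interval (0.3, 0.8) and target 0.55).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from mlenz.rank_loss import LabelSet


@dataclass(frozen=True)
class ThresholdModel:
    """Linear threshold parameters t(x) = w . l(x) + b."""

    w: np.ndarray
    b: float
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 1 or not np.all(np.isfinite(w)) or not np.isfinite(self.b):
            raise ValueError("threshold parameters must be finite and w 1-D")
        object.__setattr__(self, "w", w)

    def threshold(self, scores: np.ndarray) -> float:
        return float(self.w @ np.asarray(scores, dtype=float) + self.b)


@dataclass(frozen=True)
class PredictedLabelSet:
    """Predicted subset of {1..Q}; ``fallback_used`` marks instances where
    every score fell below the threshold and the top-scoring class was
    assigned instead."""

    members: frozenset[int]
    q: int
    fallback_used: bool = False

    def __eq__(self, other) -> bool:  # compare against plain LabelSets too
        if isinstance(other, (PredictedLabelSet, LabelSet)):
            return self.members == other.members
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.members)

    def __contains__(self, j: int) -> bool:
        return j in self.members

    def __iter__(self):
        return iter(sorted(self.members))


def count_objective(
    scores: Sequence[float] | np.ndarray, labels: LabelSet, t: float
) -> int:
    """Misclassified-label count at threshold ``t`` (boundary comparisons
    are <= for true labels and >= for false labels, as defined)."""
    s = np.asarray(scores, dtype=float)
    d = labels.indicator().astype(bool)
    return int((s[d] <= t).sum() + (s[~d] >= t).sum())


def _candidate_intervals(s: np.ndarray) -> list[tuple[float, float, float]]:
    """Open intervals on which the count objective is constant, each as
    (midpoint, width, representative point). Unbounded end intervals are
    given a synthetic width/midpoint offset of half the mean adjacent gap."""
    distinct = np.unique(s)
    if distinct.size > 1:
        half_gap = float(np.diff(distinct).mean()) / 2.0
    else:
        half_gap = 0.05  # single distinct score; any positive offset works
    intervals: list[tuple[float, float, float]] = []
    lo = float(distinct[0]) - half_gap
    intervals.append((lo, half_gap, lo))
    for a, b in zip(distinct[:-1], distinct[1:]):
        mid = float(a + b) / 2.0
        intervals.append((mid, float(b - a), mid))
    hi = float(distinct[-1]) + half_gap
    intervals.append((hi, half_gap, hi))
    return intervals


def optimal_instance_threshold(
    scores: Sequence[float] | np.ndarray, labels: LabelSet
) -> float:
    """Per-instance optimal threshold: midpoint of the minimizing interval
    of the count objective.

    The objective is piecewise constant, so it suffices to evaluate it once
    per open interval between consecutive distinct scores plus the two
    unbounded end intervals. When several disjoint intervals attain the
    minimum, the widest is taken, with ties broken toward the lower
    midpoint — a deterministic rule for a case the midpoint convention does
    not itself resolve.

    Degenerate label sets are allowed here (they occur when calibrating on
    arbitrary data): an empty set puts the threshold above the maximum
    score, a full set below the minimum, offset by half the mean adjacent
    score gap.
    """
    s = np.asarray(scores, dtype=float)
    intervals = _candidate_intervals(s)
    d = labels.indicator().astype(bool)
    if d.all():
        return intervals[0][0]  # below min: everything predicted
    if not d.any():
        return intervals[-1][0]  # above max: nothing predicted
    objective = np.array([count_objective(s, labels, rep) for _, _, rep in intervals])
    best = objective.min()
    minimizers = [iv for iv, f in zip(intervals, objective) if f == best]
    # widest interval first, then lower midpoint
    minimizers.sort(key=lambda iv: (-iv[1], iv[0]))
    return minimizers[0][0]


def fit_threshold_function(
    score_matrix: np.ndarray, labels_list: Sequence[LabelSet]
) -> ThresholdModel:
    """Fit t(x) = w . l(x) + b by least squares to per-instance optimal
    thresholds.

    Solved with an SVD-based solver, so rank-deficient systems (including
    m = 1) receive the minimum-norm solution. The root-mean-square residual
    over the training instances is recorded on the returned model.
    """
    X = np.asarray(score_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"score matrix must be m x Q, got shape {X.shape}")
    m, q = X.shape
    if m == 0:
        raise ValueError("cannot fit a threshold function to zero instances")
    if len(labels_list) != m:
        raise ValueError(f"{m} score rows but {len(labels_list)} label sets")
    targets = np.array(
        [optimal_instance_threshold(X[i], labels_list[i]) for i in range(m)]
    )
    return fit_threshold_to_targets(X, targets)


def fit_threshold_to_targets(
    score_matrix: np.ndarray, targets: Sequence[float] | np.ndarray
) -> ThresholdModel:
    """Least-squares fit of (w, b) to given per-instance target thresholds."""
    X = np.asarray(score_matrix, dtype=float)
    targets = np.asarray(targets, dtype=float)
    m, q = X.shape
    design = np.hstack([X, np.ones((m, 1))])
    coef, *_ = np.linalg.lstsq(design, targets, rcond=None)
    residuals = design @ coef - targets
    rms = float(np.sqrt(np.mean(residuals**2)))
    return ThresholdModel(w=coef[:q], b=float(coef[q]), residual_rms=rms)


def apply_threshold(
    scores: Sequence[float] | np.ndarray, model: ThresholdModel
) -> PredictedLabelSet:
    """Assign labels by strict comparison against the instance threshold.

    ``members = {j : l_j > t(x)}``. An enzyme is never left without a main
    class: if no score clears the threshold, the top-scoring class (lowest
    index among ties) is assigned and the prediction is flagged.
    """
    s = np.asarray(scores, dtype=float)
    t = model.threshold(s)
    members = frozenset(int(j + 1) for j in np.flatnonzero(s > t))
    if members:
        return PredictedLabelSet(members=members, q=s.size)
    top = int(np.argmax(s)) + 1
    return PredictedLabelSet(members=frozenset({top}), q=s.size, fallback_used=True)
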