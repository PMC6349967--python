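import numpy as np
import pytest

from conftest import random_label_set
from mlenz.rank_loss import LabelSet
from mlenz.threshold_calibration import (
    ThresholdModel,
    apply_threshold,
    count_objective,
    fit_threshold_function,
    fit_threshold_to_targets,
    optimal_instance_threshold,
)


def grid_minimum(scores, labels):
    """Independent oracle: the count objective evaluated on a dense grid
    plus every data point value."""
    s = np.asarray(scores, dtype=float)
    grid = np.concatenate([np.linspace(s.min() - 1, s.max() + 1, 4001), s])
    return min(count_objective(s, labels, t) for t in grid)


class TestOptimalInstanceThreshold:
    def test_printed_example_gives_055(self, worked_example):
        scores, labels = worked_example
        assert optimal_instance_threshold(scores, labels) == pytest.approx(0.55)
        assert count_objective(scores, labels, 0.55) == 0

    def test_two_point_separable_midpoint(self):
        assert optimal_instance_threshold(
            np.array([0.9, 0.1]), LabelSet({1}, q=2)
        ) == pytest.approx(0.5)

    def test_inverted_ranking_pinned_by_oracle(self):
        # scores (0.2, 0.8) with true label {1}: the minimum count is 1,
        # attained below 0.2 (predict both) and above 0.8 (predict none);
        # the tie-break picks the lower interval, offset half the mean gap
        scores = np.array([0.2, 0.8])
        labels = LabelSet({1}, q=2)
        t = optimal_instance_threshold(scores, labels)
        assert count_objective(scores, labels, t) == grid_minimum(scores, labels) == 1
        assert t == pytest.approx(-0.1)

    def test_attains_global_minimum_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            q = int(rng.integers(2, 7))
            scores = rng.uniform(0, 1, size=q)
            if rng.random() < 0.3:  # inject ties
                scores = np.round(scores, 1)
            labels = random_label_set(rng, q)
            t = optimal_instance_threshold(scores, labels)
            assert count_objective(scores, labels, t) == grid_minimum(scores, labels)

    def test_perfect_separation_recovers_labels(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            q = int(rng.integers(2, 7))
            labels = random_label_set(rng, q)
            pos = labels.indicator().astype(bool)
            scores = np.where(pos, rng.uniform(0.7, 1.0, q), rng.uniform(0.0, 0.3, q))
            t = optimal_instance_threshold(scores, labels)
            assert count_objective(scores, labels, t) == 0
            predicted = frozenset(int(j + 1) for j in np.flatnonzero(scores > t))
            assert predicted == labels.members

    def test_degenerate_sets_push_threshold_outside_range(self):
        scores = np.array([0.2, 0.4, 0.6])
        t_empty = optimal_instance_threshold(scores, LabelSet(set(), q=3))
        t_full = optimal_instance_threshold(scores, LabelSet({1, 2, 3}, q=3))
        assert t_empty > scores.max()
        assert t_full < scores.min()
        # offset is half the mean adjacent gap (0.1 here)
        assert t_empty == pytest.approx(0.7)
        assert t_full == pytest.approx(0.1)


class TestFitThresholdFunction:
    def test_exact_linear_recovery(self):
        """Targets generated exactly as t_i = w*.l_i + b* on score rows in
        general position are recovered to 1e-8 with ~zero residual."""
        rng = np.random.default_rng(11)
        q, m = 6, 50
        w_star = rng.normal(size=q)
        b_star = 0.3
        scores = rng.uniform(0, 1, size=(m, q))
        model = fit_threshold_to_targets(scores, scores @ w_star + b_star)
        np.testing.assert_allclose(model.w, w_star, atol=1e-8)
        assert model.b == pytest.approx(b_star, abs=1e-8)
        assert model.residual_rms < 1e-8

    def test_matches_normal_equations_on_well_conditioned_system(self):
        """The SVD-based solve agrees with the normal-equations solution on
        real optimal-threshold targets."""
        rng = np.random.default_rng(12)
        q, m = 6, 50
        scores = rng.uniform(0, 1, size=(m, q))
        labels = [random_label_set(rng, q) for _ in range(m)]
        model = fit_threshold_function(scores, labels)
        t = np.array([optimal_instance_threshold(scores[i], labels[i]) for i in range(m)])
        design = np.hstack([scores, np.ones((m, 1))])
        normal = np.linalg.solve(design.T @ design, design.T @ t)
        np.testing.assert_allclose(np.append(model.w, model.b), normal, atol=1e-8)

    def test_separable_scores_zero_residual_linear_targets(self):
        """When every instance is perfectly separated at the same margin,
        the optimal thresholds are an exact linear function of the scores
        and the fit recovers them with ~zero residual."""
        rng = np.random.default_rng(21)
        q, m = 4, 60
        rows, labels = [], []
        for _ in range(m):
            members = rng.choice(np.arange(1, q + 1), size=2, replace=False)
            lab = LabelSet(members.tolist(), q=q)
            pos = lab.indicator().astype(bool)
            shift = rng.uniform(-0.1, 0.1)
            rows.append(np.where(pos, 0.8, 0.2) + shift)
            labels.append(lab)
        model = fit_threshold_function(np.array(rows), labels)
        assert model.residual_rms < 1e-8
        for row, lab in zip(rows, labels):
            assert apply_threshold(row, model).members == lab.members

    def test_single_instance_minimum_norm(self):
        scores = np.array([[0.9, 0.1]])
        labels = [LabelSet({1}, q=2)]
        model = fit_threshold_function(scores, labels)
        assert model.threshold(scores[0]) == pytest.approx(0.5, abs=1e-8)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(13)
        scores = rng.uniform(0, 1, size=(30, 6))
        labels = [random_label_set(rng, 6) for _ in range(30)]
        once = fit_threshold_function(scores, labels)
        twice = fit_threshold_function(
            np.vstack([scores, scores]), labels + labels
        )
        np.testing.assert_allclose(once.w, twice.w, atol=1e-8)
        assert once.b == pytest.approx(twice.b, abs=1e-8)

    def test_residual_beats_constant_threshold_baseline(self):
        """The fitted linear threshold fits at least as well as the best
        constant threshold (computed by an independent closed form)."""
        rng = np.random.default_rng(17)
        q, m = 6, 200
        rows, labels = [], []
        for _ in range(m):
            lab = random_label_set(rng, q)
            pos = lab.indicator().astype(bool)
            rows.append(
                np.clip(np.where(pos, 0.75, 0.25) + rng.normal(0, 0.08, q), 0.01, 0.99)
            )
            labels.append(lab)
        rows = np.array(rows)
        model = fit_threshold_function(rows, labels)
        targets = np.array(
            [optimal_instance_threshold(rows[i], labels[i]) for i in range(m)]
        )
        constant_rms = float(np.sqrt(np.mean((targets - targets.mean()) ** 2)))
        assert model.residual_rms <= constant_rms + 1e-12
        assert model.residual_rms < targets.std() + 1e-12

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="zero instances"):
            fit_threshold_function(np.zeros((0, 6)), [])


class TestApplyThreshold:
    def test_printed_example_with_flat_threshold(self, worked_example):
        scores, _ = worked_example
        model = ThresholdModel(w=np.zeros(6), b=0.55)
        pred = apply_threshold(scores, model)
        assert pred.members == frozenset({1, 2})
        assert not pred.fallback_used

    def test_all_below_threshold_falls_back_to_top1(self):
        model = ThresholdModel(w=np.zeros(4), b=0.9)
        pred = apply_threshold(np.array([0.1, 0.5, 0.3, 0.2]), model)
        assert pred.members == frozenset({2})
        assert pred.fallback_used

    def test_tie_at_threshold_excluded_then_lowest_index_wins(self):
        model = ThresholdModel(w=np.zeros(2), b=0.5)
        pred = apply_threshold(np.array([0.5, 0.5]), model)
        assert pred.members == frozenset({1})
        assert pred.fallback_used

    def test_end_to_end_zero_hamming_on_linear_thresholds(self):
        """When optimal thresholds are exactly linear in the scores, the
        fitted function reassigns every training label set exactly."""
        rng = np.random.default_rng(31)
        q, m = 5, 80
        rows, labels = [], []
        for _ in range(m):
            members = rng.choice(np.arange(1, q + 1), size=2, replace=False)
            lab = LabelSet(members.tolist(), q=q)
            pos = lab.indicator().astype(bool)
            rows.append(np.where(pos, 0.9, 0.1) + rng.uniform(-0.05, 0.05))
            labels.append(lab)
        model = fit_threshold_function(np.array(rows), labels)
        mistakes = sum(
            apply_threshold(row, model).members != lab.members
            for row, lab in zip(rows, labels)
        )
        assert mistakes == 0
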