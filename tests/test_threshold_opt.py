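"""Stratified splitting, grid ROC, trapezoidal AUC and Youden threshold."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from smiledetect import (
    SplitResult,
    THRESHOLD_GRID,
    UndefinedStatisticError,
    ValidationError,
    participant_map,
    roc_curve,
    stratified_split,
    youden_optimal,
)


def _series(pos, neg):
    """Scores and truth Series from positive/negative score lists."""
    ids = [f"S{i}" for i in range(len(pos) + len(neg))]
    scores = pd.Series(list(pos) + list(neg), index=ids)
    truth = pd.Series([1] * len(pos) + [0] * len(neg), index=ids)
    return scores, truth


def _mann_whitney(pos, neg):
    """Brute-force pairwise concordance (ties count half)."""
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


def _offgrid_scores(rng, n):
    """Distinct scores strictly between grid points: (k + 0.5) / 1000."""
    ks = rng.choice(np.arange(1, 999), size=n, replace=False)
    return (ks + 0.5) / 1000.0


class TestStratifiedSplit:
    def test_even_stratum_splits_in_half(self):
        labels = pd.Series([1] * 4, index=list("abcd"))
        parts = pd.Series(["P1"] * 4, index=list("abcd"))
        split = stratified_split(labels, parts, seed=0)
        assert len(split.train_ids) == 2 and len(split.test_ids) == 2

    def test_odd_stratum_splits_three_two(self):
        labels = pd.Series([1] * 5, index=list("abcde"))
        parts = pd.Series(["P1"] * 5, index=list("abcde"))
        sizes = set()
        for seed in range(20):
            split = stratified_split(labels, parts, seed=seed)
            sizes.add((len(split.train_ids), len(split.test_ids)))
        assert sizes <= {(2, 3), (3, 2)}
        assert len(sizes) == 2  # both orientations occur across seeds

    def test_default_geometry_yields_79_79(self, default_dataset):
        segments, truth = default_dataset
        parts = participant_map(segments)
        for seed in range(10):
            split = stratified_split(truth, parts, seed=seed)
            assert len(split.train_ids) == 79
            assert len(split.test_ids) == 79
            assert not set(split.train_ids) & set(split.test_ids)

    def test_per_stratum_imbalance_at_most_one(self, default_dataset):
        segments, truth = default_dataset
        parts = participant_map(segments)
        split = stratified_split(truth, parts, seed=3)
        train = set(split.train_ids)
        frame = pd.DataFrame({"participant": parts, "label": truth})
        for _, group in frame.groupby(["participant", "label"]):
            in_train = sum(sid in train for sid in group.index)
            assert abs(in_train - (len(group) - in_train)) <= 1

    def test_deterministic_per_seed(self, default_dataset):
        segments, truth = default_dataset
        parts = participant_map(segments)
        assert stratified_split(truth, parts, seed=5) == stratified_split(
            truth, parts, seed=5
        )

    def test_empty_labels_rejected(self):
        with pytest.raises(ValidationError):
            stratified_split(pd.Series(dtype=int), pd.Series(dtype=str), seed=0)

    def test_overlap_rejected_by_split_result(self):
        with pytest.raises(ValidationError, match="overlap"):
            SplitResult(train_ids=("a", "b"), test_ids=("b", "c"))


class TestROC:
    def test_perfect_separation(self):
        curve = roc_curve(*_series([0.8, 0.6], [0.4, 0.2]))
        assert curve.auc == pytest.approx(1.0)

    def test_uninformative_scores(self):
        curve = roc_curve(*_series([0.5, 0.5], [0.5, 0.5, 0.5]))
        assert curve.auc == pytest.approx(0.5)

    def test_partial_overlap_matches_concordance(self):
        """pos {0.6, 0.3} vs neg {0.4, 0.1}: 3 of 4 pairs concordant."""
        curve = roc_curve(*_series([0.6, 0.3], [0.4, 0.1]))
        assert curve.auc == pytest.approx(0.75)

    def test_grid_shape_and_ranges(self):
        curve = roc_curve(*_series([0.9], [0.1]))
        assert len(curve.thresholds) == 1001
        assert curve.thresholds[0] == 0.0 and curve.thresholds[-1] == 1.0
        for arr in (curve.tpr, curve.fpr):
            assert arr.min() >= 0.0 and arr.max() <= 1.0
        assert np.all(np.abs(curve.j) <= 1.0)

    def test_monotone_in_threshold(self, default_dataset):
        segments, truth = default_dataset
        from smiledetect import aggregate_segments

        scores = aggregate_segments(
            segments, ["mouthSmile_L", "mouthSmile_R"]
        ).max(axis=1)
        curve = roc_curve(scores, truth)
        assert np.all(np.diff(curve.tpr) <= 0)
        assert np.all(np.diff(curve.fpr) <= 0)

    def test_single_class_rejected(self):
        scores = pd.Series([0.2, 0.4], index=["a", "b"])
        truth = pd.Series([1, 1], index=["a", "b"])
        with pytest.raises(UndefinedStatisticError):
            roc_curve(scores, truth)

    def test_matches_sklearn_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n_pos = int(rng.integers(2, 25))
            n_neg = int(rng.integers(2, 25))
            scores = _offgrid_scores(rng, n_pos + n_neg)
            s, t = _series(scores[:n_pos], scores[n_pos:])
            assert roc_curve(s, t).auc == pytest.approx(
                roc_auc_score(t, s), abs=1e-9
            )

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_auc_equals_mann_whitney_for_tie_free_scores(self, seed):
        rng = np.random.default_rng(seed)
        n_pos = int(rng.integers(1, 20))
        n_neg = int(rng.integers(1, 20))
        scores = _offgrid_scores(rng, n_pos + n_neg)
        pos, neg = scores[:n_pos], scores[n_pos:]
        curve = roc_curve(*_series(pos, neg))
        assert curve.auc == pytest.approx(_mann_whitney(pos, neg), abs=1e-9)


class TestYouden:
    def test_smallest_maximizer_selected(self):
        """Separable {0.8, 0.6} vs {0.4, 0.2}: J first reaches 1 at 0.400."""
        curve = roc_curve(*_series([0.8, 0.6], [0.4, 0.2]))
        assert youden_optimal(curve) == pytest.approx(0.400)

    def test_all_scores_equal_returns_zero(self):
        curve = roc_curve(*_series([0.5], [0.5]))
        assert np.all(curve.j == 0.0)
        assert youden_optimal(curve) == 0.0

    def test_matches_exhaustive_grid_scan(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            scores = _offgrid_scores(rng, 20)
            s, t = _series(scores[:8], scores[8:])
            curve = roc_curve(s, t)
            best, best_j = None, -np.inf
            for theta in THRESHOLD_GRID:
                tpr = np.mean(s[t == 1].to_numpy() > theta)
                fpr = np.mean(s[t == 0].to_numpy() > theta)
                if tpr - fpr > best_j:
                    best, best_j = theta, tpr - fpr
            assert youden_optimal(curve) == pytest.approx(best)

    def test_perfect_separation_iff_max_j_one(self, default_dataset):
        segments, truth = default_dataset
        from smiledetect import aggregate_segments

        scores = aggregate_segments(
            segments, ["mouthSmile_L", "mouthSmile_R"]
        ).max(axis=1)
        curve = roc_curve(scores, truth)
        assert curve.j.max() == pytest.approx(1.0)
        theta = youden_optimal(curve)
        assert scores[truth == 0].max() <= theta < scores[truth == 1].min()
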