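"""Stratified splitting, grid ROC, Youden-optimal thresholds, trapezoidal AUC.

The ROC is computed on a fixed threshold grid from 0 to 1 in steps of 0.001
(1001 points, both endpoints included).  At each grid threshold theta,

    TPR(theta) = #{positives with score > theta} / #positives,
    FPR(theta) = #{negatives with score > theta} / #negatives,

with the strict-exceed convention inherited from the classifier.  The AUC is
the trapezoidal integral of the piecewise-linear curve through the unique
(FPR, TPR) points sorted by FPR then TPR and anchored at (0, 0) and (1, 1);
for tie-free scores this coincides with the Mann-Whitney pairwise
concordance probability.

The optimal operating point maximises Youden's J = TPR - FPR; ties are
broken toward the smallest threshold, which maximises sensitivity at equal
J.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import BilateralClassifier, BLENDSHAPE_PAIRS
from .core import UndefinedStatisticError, ValidationError

__all__ = [
    "THRESHOLD_GRID",
    "ROCCurve",
    "SplitResult",
    "stratified_split",
    "roc_curve",
    "youden_optimal",
    "fit_threshold",
]

#: Canonical threshold grid: 0.000, 0.001, ..., 1.000.
THRESHOLD_GRID = np.arange(1001) / 1000.0


@dataclass(frozen=True)
class ROCCurve:
    """Receiver operating characteristic sampled on the fixed grid."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    @property
    def j(self) -> np.ndarray:
        """Youden's J = TPR - FPR at each grid threshold."""
        return self.tpr - self.fpr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr,
             "fpr": self.fpr, "j": self.j}
        )


@dataclass(frozen=True)
class SplitResult:
    """Disjoint train/test partition of segment ids."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValidationError(
                f"train and test overlap: {sorted(overlap)[:5]}"
            )


def stratified_split(
    labels: pd.Series, participants: pd.Series, seed: int | None = None
) -> SplitResult:
    """50/50 split stratified jointly by participant and class label.

    Within each (participant, label) stratum the segments are shuffled by
    the seeded generator and assigned alternately to the two halves, so
    stratum sizes differ by at most one between halves.  The half that
    receives the surplus segment of an odd stratum alternates from one odd
    stratum to the next (starting side drawn once from the generator);
    because an even total implies an even number of odd strata, an
    even-sized dataset always splits exactly in half.
    """
    if len(labels) == 0:
        raise ValidationError("label set is empty")
    missing = labels.index.difference(participants.index)
    if len(missing):
        raise ValidationError(
            f"segments without participant: {sorted(missing)[:5]}"
        )
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    halves = (train, test)
    side = int(rng.integers(2))  # which half receives the next odd surplus
    strata = sorted(
        (str(participants[sid]), int(lab), str(sid)) for sid, lab in labels.items()
    )
    frame = pd.DataFrame(strata, columns=["participant", "label", "segment_id"])
    for _, group in frame.groupby(["participant", "label"], sort=True):
        ids = group["segment_id"].to_numpy()
        rng.shuffle(ids)
        first, second = halves[side], halves[1 - side]
        first.extend(ids[0::2])
        second.extend(ids[1::2])
        if len(ids) % 2 == 1:
            side = 1 - side
    return SplitResult(train_ids=tuple(sorted(train)), test_ids=tuple(sorted(test)))


def _trapezoidal_auc(neg_counts: np.ndarray, pos_counts: np.ndarray,
                     n_neg: int, n_pos: int) -> float:
    """Trapezoidal integral through unique anchored (FPR, TPR) points.

    Works on the integer exceedance counts behind FPR and TPR so the
    numerator is exact: a perfectly separating curve integrates to exactly
    1.0 and tie-free instances reproduce the Mann-Whitney concordance.
    """
    points = np.column_stack([neg_counts, pos_counts])
    points = np.vstack([points, [[0, 0], [n_neg, n_pos]]])
    points = np.unique(points, axis=0)  # sorts by FPR then TPR counts
    dx = np.diff(points[:, 0])
    ysum = points[1:, 1] + points[:-1, 1]
    return float(int(np.sum(dx * ysum)) / (2 * n_neg * n_pos))


def roc_curve(scores: pd.Series, truth: pd.Series) -> ROCCurve:
    """ROC over the fixed grid for per-segment scores against binary truth.

    Raises :class:`UndefinedStatisticError` when truth contains a single
    class (one of TPR or FPR is then undefined).
    """
    truth = truth.loc[scores.index]
    pos = scores[truth == 1].to_numpy(dtype=float)
    neg = scores[truth == 0].to_numpy(dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedStatisticError(
            "ROC requires both classes in the truth labels"
        )
    pos_counts = (pos[:, None] > THRESHOLD_GRID[None, :]).sum(axis=0)
    neg_counts = (neg[:, None] > THRESHOLD_GRID[None, :]).sum(axis=0)
    return ROCCurve(
        thresholds=THRESHOLD_GRID.copy(),
        tpr=pos_counts / len(pos),
        fpr=neg_counts / len(neg),
        auc=_trapezoidal_auc(neg_counts, pos_counts, len(neg), len(pos)),
    )


def youden_optimal(curve: ROCCurve) -> float:
    """Grid threshold maximising Youden's J; smallest threshold on ties."""
    return float(curve.thresholds[int(np.argmax(curve.j))])


def fit_threshold(
    features: pd.DataFrame,
    labels: pd.Series,
    pair: str = "mouthSmile",
    ids: tuple[str, ...] | list[str] | None = None,
) -> tuple[BilateralClassifier, ROCCurve]:
    """Fit the bilateral classifier's threshold by Youden's J on a grid ROC.

    ``ids`` restricts fitting to a subset (normally the training half of a
    :class:`SplitResult`); by default all rows of ``features`` are used.
    Returns the fitted classifier and its training ROC.
    """
    if ids is not None:
        features = features.loc[list(ids)]
        labels = labels.loc[list(ids)]
    left, right = BLENDSHAPE_PAIRS[pair]
    scores = features[[left, right]].max(axis=1)
    curve = roc_curve(scores, labels)
    theta = youden_optimal(curve)
    return BilateralClassifier(left=left, right=right, threshold=theta), curve
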