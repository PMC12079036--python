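"""Confusion-matrix metrics and Cohen's kappa for machine-vs-human agreement.

With the human consensus as reference and the smile event as positive
class, the test-half evaluation reduces to a 2x2 confusion matrix
(TP, FP, FN, TN; n = their sum), from which

    sensitivity = TP / (TP + FN),        specificity = TN / (TN + FP),
    p_o = (TP + TN) / n,
    p_e = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / n^2,
    kappa_C = (p_o - p_e) / (1 - p_e).

The 95% CI is the Wald interval kappa_C +/- 1.96 * SE with
SE = sqrt( p_o (1 - p_o) / (n (1 - p_e)^2) ), deliberately not truncated at
1; the p-value is a one-sided z-test of kappa = 0 using the null standard
error SE0 = sqrt( p_e / (n (1 - p_e)) ).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import BilateralClassifier, predict_segments
from .core import (
    BlendshapeSegment,
    UndefinedStatisticError,
    ValidationError,
    aggregate_segments,
)
from .threshold_opt import SplitResult

__all__ = [
    "ConfusionMatrix",
    "KappaResult",
    "EvalReport",
    "confusion",
    "sens_spec",
    "cohen_kappa",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 cross-tabulation of predictions against reference labels."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.n < 1:
            raise ValidationError("confusion matrix is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its ingredients and sampling uncertainty."""

    kappa: float
    p_o: float
    p_e: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci_95"] = [d.pop("ci_low"), d.pop("ci_high")]
        return d


@dataclass(frozen=True)
class EvalReport:
    """Full test-half evaluation of a fitted classifier."""

    classifier: BilateralClassifier
    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    kappa: KappaResult
    test_ids: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "classifier": {
                "left": self.classifier.left,
                "right": self.classifier.right,
                "threshold": self.classifier.threshold,
            },
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
                "tn": self.confusion.tn,
                "n": self.confusion.n,
            },
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "cohen_kappa": self.kappa.to_dict(),
            "n_test": len(self.test_ids),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        )


def confusion(predictions: pd.Series, truth: pd.Series) -> ConfusionMatrix:
    """Cross-tabulate binary predictions against reference labels.

    The id sets must match exactly; a mismatch raises listing the symmetric
    difference.
    """
    diff = predictions.index.symmetric_difference(truth.index)
    if len(diff):
        raise ValidationError(
            f"prediction/truth id mismatch: {sorted(map(str, diff))[:10]}"
        )
    p = predictions.loc[truth.index].to_numpy(dtype=np.int64)
    t = truth.to_numpy(dtype=np.int64)
    return ConfusionMatrix(
        tp=int(np.sum((p == 1) & (t == 1))),
        fp=int(np.sum((p == 1) & (t == 0))),
        fn=int(np.sum((p == 0) & (t == 1))),
        tn=int(np.sum((p == 0) & (t == 0))),
    )


def sens_spec(cm: ConfusionMatrix) -> tuple[float, float]:
    """(sensitivity, specificity) = (TP/(TP+FN), TN/(TN+FP)).

    Raises :class:`UndefinedStatisticError` when either margin is empty.
    """
    if cm.tp + cm.fn == 0:
        raise UndefinedStatisticError("no positives: sensitivity undefined")
    if cm.tn + cm.fp == 0:
        raise UndefinedStatisticError("no negatives: specificity undefined")
    return cm.tp / (cm.tp + cm.fn), cm.tn / (cm.tn + cm.fp)


def cohen_kappa(cm: ConfusionMatrix) -> KappaResult:
    """Cohen's kappa between two binary labellings summarised by ``cm``.

    Raises :class:`UndefinedStatisticError` when the chance agreement p_e
    equals 1 (both labellings constant and identical).
    """
    n = cm.n
    if n < 2:
        raise ValidationError("Cohen's kappa needs at least 2 items")
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / n**2
    if p_e >= 1.0:
        raise UndefinedStatisticError(
            "both labellings constant in the same category; kappa undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = float(np.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2)))
    se0 = float(np.sqrt(p_e / (n * (1.0 - p_e))))
    z = kappa / se0
    return KappaResult(
        kappa=float(kappa),
        p_o=float(p_o),
        p_e=float(p_e),
        se=se,
        ci_low=float(kappa - 1.96 * se),
        ci_high=float(kappa + 1.96 * se),
        p_value=float(stats.norm.sf(z)),
        n=n,
    )


def evaluate(
    segments: Sequence[BlendshapeSegment],
    classifier: BilateralClassifier,
    consensus_labels: pd.Series,
    split: SplitResult,
) -> EvalReport:
    """Apply a trained classifier to the held-out test half and report.

    The classifier must have been fitted on the disjoint training half;
    the :class:`SplitResult` invariant already forbids overlap, and the
    report is computed on ``split.test_ids`` only.
    """
    features = aggregate_segments(
        [s for s in segments if s.segment_id in set(split.test_ids)],
        names=[classifier.left, classifier.right],
    )
    missing = set(split.test_ids) - set(features.index)
    if missing:
        raise ValidationError(
            f"test segments absent from data: {sorted(missing)[:5]}"
        )
    predictions = predict_segments(features, classifier)
    truth = consensus_labels.loc[list(split.test_ids)]
    cm = confusion(predictions, truth)
    sens, spec = sens_spec(cm)
    return EvalReport(
        classifier=classifier,
        confusion=cm,
        sensitivity=sens,
        specificity=spec,
        kappa=cohen_kappa(cm),
        test_ids=tuple(split.test_ids),
    )
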