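"""The bilateral OR-threshold classifier.

A segment is called a smile event when either the left or the right channel
of a blendshape pair exceeds a shared threshold (strictly), which makes the
decision robust to head rotation hiding one side of the face.  Because

    (left > theta) or (right > theta)  <=>  max(left, right) > theta,

the classifier reduces to thresholding the scalar score
``max(feature[left], feature[right])``, which is what a single ROC sweep
operates on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .core import ValidationError

__all__ = [
    "BilateralClassifier",
    "BLENDSHAPE_PAIRS",
    "score_segment",
    "predict",
    "score_segments",
    "predict_segments",
]

#: Named bilateral action-unit pairs (AU12 = lip corner puller,
#: AU6 = cheek raiser).
BLENDSHAPE_PAIRS: dict[str, tuple[str, str]] = {
    "mouthSmile": ("mouthSmile_L", "mouthSmile_R"),
    "cheekSquint": ("cheekSquint_L", "cheekSquint_R"),
}


@dataclass(frozen=True)
class BilateralClassifier:
    """Left/right blendshape pair with one shared strict-exceed threshold."""

    left: str
    right: str
    threshold: float

    def __post_init__(self) -> None:
        if self.left == self.right:
            raise ValidationError("left and right blendshapes must differ")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValidationError(
                f"threshold must be in [0, 1], got {self.threshold}"
            )

    @classmethod
    def from_pair(cls, pair: str, threshold: float) -> "BilateralClassifier":
        """Build from a named pair (``mouthSmile`` or ``cheekSquint``)."""
        if pair not in BLENDSHAPE_PAIRS:
            raise KeyError(
                f"unknown pair {pair!r}; known: {sorted(BLENDSHAPE_PAIRS)}"
            )
        left, right = BLENDSHAPE_PAIRS[pair]
        return cls(left=left, right=right, threshold=threshold)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"left": self.left, "right": self.right,
                 "threshold": self.threshold},
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BilateralClassifier":
        spec = json.loads(Path(path).read_text())
        return cls(left=spec["left"], right=spec["right"],
                   threshold=spec["threshold"])


def score_segment(
    features: Mapping[str, float] | pd.Series, classifier: BilateralClassifier
) -> float:
    """Classifier score of one segment: max of the left and right features."""
    for name in (classifier.left, classifier.right):
        if name not in features:
            raise KeyError(f"blendshape {name!r} missing from features")
    return max(float(features[classifier.left]),
               float(features[classifier.right]))


def predict(
    features: Mapping[str, float] | pd.Series, classifier: BilateralClassifier
) -> int:
    """1 if the score strictly exceeds the threshold, else 0.

    Boundary equality classifies negative ("exceeded" is read as strict >).
    """
    return int(score_segment(features, classifier) > classifier.threshold)


def score_segments(
    features: pd.DataFrame, classifier: BilateralClassifier
) -> pd.Series:
    """Vectorised :func:`score_segment` over a feature table."""
    for name in (classifier.left, classifier.right):
        if name not in features.columns:
            raise KeyError(f"blendshape {name!r} missing from features")
    return features[[classifier.left, classifier.right]].max(axis=1).rename("score")


def predict_segments(
    features: pd.DataFrame, classifier: BilateralClassifier
) -> pd.Series:
    """Vectorised :func:`predict` over a feature table."""
    scores = score_segments(features, classifier)
    return (scores > classifier.threshold).astype(int).rename("label")
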