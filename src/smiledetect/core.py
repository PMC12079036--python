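"""Domain types and on-disk formats for blendshape segment data.

A *blendshape* is a normalized scalar in [0, 1] describing the activation of
one facial expression component derived from a tracked 3D face mesh
(0 = neutral, 1 = fully expressed).  The unit of analysis is a short video
*segment*: a fixed-rate sequence of per-frame blendshape values attributed to
one participant.  Smile detection works on the bilateral action-unit pairs
AU12 (lip corner puller, ``mouthSmile_L``/``mouthSmile_R``) and AU6 (cheek
raiser, ``cheekSquint_L``/``cheekSquint_R``).

On-disk formats (comma-separated, header row, UTF-8):

frames CSV
    ``segment_id,participant_id,frame_index,<blendshape columns...>``
    one row per frame; frame_index is 0-based; time = frame_index / fps.
labels CSV
    ``segment_id,label`` with label 0 (non-smile event) or 1 (smile event).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "UndefinedStatisticError",
    "BlendshapeSegment",
    "DEFAULT_BLENDSHAPES",
    "REQUIRED_FRAME_COLUMNS",
    "read_segments",
    "write_segments",
    "read_labels",
    "write_labels",
    "aggregate_segment",
    "aggregate_segments",
    "participant_map",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(ValueError):
    """Data violate a domain invariant (range, uniqueness, completeness)."""


class UndefinedStatisticError(ArithmeticError):
    """A statistic is mathematically undefined for the given input.

    Raised instead of returning NaN so degenerate inputs (e.g. an agreement
    coefficient whose chance-agreement term equals 1) cannot silently
    propagate.
    """


REQUIRED_FRAME_COLUMNS = ("segment_id", "participant_id", "frame_index")

#: The four action-unit channels used for smile detection (AU12 and AU6,
#: left/right).  Additional blendshape columns are carried through untouched.
DEFAULT_BLENDSHAPES = (
    "mouthSmile_L",
    "mouthSmile_R",
    "cheekSquint_L",
    "cheekSquint_R",
)

# Fixed print format for frame values; write->read->write round-trips
# byte-identically at this precision.
_FLOAT_FORMAT = "%.6f"


@dataclass
class BlendshapeSegment:
    """One fixed-length clip of per-frame blendshape values.

    Parameters
    ----------
    segment_id, participant_id
        String identifiers.
    frames
        DataFrame with one row per frame (ordered, 0-based positional index)
        and one column per blendshape name; every value must lie in [0, 1].
    fps
        Frames per second; frame time in seconds is ``frame_index / fps``.
    """

    segment_id: str
    participant_id: str
    frames: pd.DataFrame
    fps: float = 10.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        if len(self.frames) < 1:
            raise ValidationError(
                f"segment {self.segment_id!r} has no frames"
            )
        values = self.frames.to_numpy(dtype=float)
        bad = np.where((values < 0.0) | (values > 1.0))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"segment {self.segment_id!r}, frame {i}, blendshape "
                f"{self.frames.columns[j]!r}: value {values[i, j]} "
                "outside [0, 1]"
            )
        self.frames = self.frames.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def blendshape_names(self) -> tuple[str, ...]:
        return tuple(self.frames.columns)

    def times(self) -> np.ndarray:
        """Frame times in seconds (0-based index over fps)."""
        return np.arange(self.n_frames) / self.fps


def read_segments(path: str | Path, fps: float = 10.0) -> list[BlendshapeSegment]:
    """Read a frames CSV into a list of :class:`BlendshapeSegment`.

    Segments are grouped by ``segment_id`` and frames ordered by
    ``frame_index``.  Raises :class:`FormatError` for a missing required
    column and :class:`ValidationError` for duplicate (segment_id,
    frame_index) pairs or values outside [0, 1].
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"segment_id": str, "participant_id": str})
    for col in REQUIRED_FRAME_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    blendshapes = [c for c in df.columns if c not in REQUIRED_FRAME_COLUMNS]
    if not blendshapes:
        raise FormatError(f"{path}: no blendshape columns present")

    dup = df.duplicated(subset=["segment_id", "frame_index"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValidationError(
            f"duplicate frame: segment {row['segment_id']!r} "
            f"frame_index {int(row['frame_index'])}"
        )

    segments = []
    for seg_id, group in df.groupby("segment_id", sort=True):
        participants = group["participant_id"].unique()
        if len(participants) != 1:
            raise ValidationError(
                f"segment {seg_id!r} maps to multiple participants: "
                f"{sorted(participants)}"
            )
        group = group.sort_values("frame_index")
        segments.append(
            BlendshapeSegment(
                segment_id=str(seg_id),
                participant_id=str(participants[0]),
                frames=group[blendshapes].astype(float),
                fps=fps,
            )
        )
    return segments


def write_segments(segments: Sequence[BlendshapeSegment], path: str | Path) -> None:
    """Write segments to a frames CSV (inverse of :func:`read_segments`)."""
    if not segments:
        raise ValidationError("no segments to write")
    names = segments[0].blendshape_names
    for seg in segments:
        if seg.blendshape_names != names:
            raise ValidationError(
                f"segment {seg.segment_id!r} has blendshape set "
                f"{seg.blendshape_names}, expected {names}"
            )
    parts = []
    for seg in sorted(segments, key=lambda s: s.segment_id):
        block = seg.frames.copy()
        block.insert(0, "segment_id", seg.segment_id)
        block.insert(1, "participant_id", seg.participant_id)
        block.insert(2, "frame_index", np.arange(seg.n_frames))
        parts.append(block)
    table = pd.concat(parts, ignore_index=True)
    table.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_labels(path: str | Path) -> pd.Series:
    """Read a labels CSV into a Series mapping segment_id -> {0, 1}."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"segment_id": str})
    for col in ("segment_id", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["segment_id"].duplicated().any():
        dup_id = df.loc[df["segment_id"].duplicated(), "segment_id"].iloc[0]
        raise ValidationError(f"duplicate segment_id in labels: {dup_id!r}")
    labels = df.set_index("segment_id")["label"]
    if not labels.isin((0, 1)).all():
        bad = labels[~labels.isin((0, 1))].iloc[0]
        raise ValidationError(f"label must be 0 or 1, got {bad!r}")
    return labels.astype(np.int64)


def write_labels(labels: pd.Series, path: str | Path) -> None:
    """Write a segment_id -> label Series as a labels CSV."""
    out = labels.rename("label").rename_axis("segment_id").reset_index()
    out.to_csv(path, index=False)


def aggregate_segment(
    segment: BlendshapeSegment, names: Iterable[str] | None = None
) -> pd.Series:
    """Collapse a segment's frame series to one scalar per blendshape.

    The aggregate is the per-blendshape **maximum** over frames: a smile
    event is present in a clip if the expression appears at any moment, so
    the peak activation is the quantity the event-level threshold applies
    to.  The result is order-invariant in the frames.

    Raises ``KeyError`` naming any requested blendshape absent from the
    segment.
    """
    if names is None:
        names = segment.blendshape_names
    names = list(names)
    missing = [n for n in names if n not in segment.frames.columns]
    if missing:
        raise KeyError(
            f"blendshape(s) {missing} not present in segment "
            f"{segment.segment_id!r}"
        )
    return segment.frames[names].max(axis=0).rename(segment.segment_id)


def aggregate_segments(
    segments: Sequence[BlendshapeSegment], names: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-segment feature table: rows = segment_id, columns = blendshapes."""
    rows = [aggregate_segment(seg, names) for seg in segments]
    table = pd.DataFrame(rows)
    table.index.name = "segment_id"
    return table


def participant_map(segments: Sequence[BlendshapeSegment]) -> pd.Series:
    """Series mapping segment_id -> participant_id."""
    return pd.Series(
        {s.segment_id: s.participant_id for s in segments}, name="participant_id"
    ).rename_axis("segment_id")
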