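"""Multi-rater agreement statistics and consensus labels for binary ratings.

The rating matrix is a DataFrame indexed by segment_id with one column per
rater, entries in {0, 1}.  Agreement is summarised with Fleiss' kappa

    kappa_F = (P_bar - P_bar_e) / (1 - P_bar_e),

where the per-item agreement is P_i = (sum_j n_ij^2 - r) / (r (r - 1)) for
category counts n_ij over r raters, P_bar is its mean over items, and the
chance term is P_bar_e = sum_j p_j^2 with p_j the overall proportion of
ratings in category j.

The standard error uses the Fleiss–Nee–Landis large-sample variance of
overall kappa for fixed r raters per item,

    var(kappa_F) = 2 [ (sum_j p_j q_j)^2 - sum_j p_j q_j (q_j - p_j) ]
                   / [ n r (r - 1) (sum_j p_j q_j)^2 ],   q_j = 1 - p_j,

from which a Wald 95% CI (not truncated at 1) and a one-sided z-test of
kappa = 0 against kappa > 0 are formed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import FormatError, UndefinedStatisticError, ValidationError

__all__ = [
    "AgreementResult",
    "validate_rater_matrix",
    "fleiss_kappa",
    "majority_vote",
    "disagreement_count",
    "read_ratings",
    "write_ratings",
]


@dataclass(frozen=True)
class AgreementResult:
    """Chance-corrected agreement with its sampling uncertainty."""

    kappa: float
    ci_low: float
    ci_high: float
    p_value: float
    se: float
    n_items: int
    n_raters: int

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "ci_95": [self.ci_low, self.ci_high],
            "p_value": self.p_value,
            "se": self.se,
            "n_items": self.n_items,
            "n_raters": self.n_raters,
        }


def validate_rater_matrix(matrix: pd.DataFrame) -> None:
    """Check the structural invariants of a rating matrix.

    At least 2 items and 2 raters, no missing cells, all judgments binary,
    unique segment ids.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValidationError(
            f"rating matrix must be at least 2 items x 2 raters, "
            f"got {matrix.shape[0]} x {matrix.shape[1]}"
        )
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValidationError(f"duplicate segment_id in ratings: {dup!r}")
    if matrix.isna().any().any():
        raise ValidationError("rating matrix contains missing cells")
    if not matrix.isin((0, 1)).all().all():
        raise ValidationError("judgments must be 0 or 1")


def fleiss_kappa(matrix: pd.DataFrame) -> AgreementResult:
    """Fleiss' kappa for a binary rating matrix (items x raters).

    Raises :class:`UndefinedStatisticError` when every rating across the
    whole matrix falls in one category (chance agreement is then 1 and the
    coefficient is undefined).
    """
    validate_rater_matrix(matrix)
    n, r = matrix.shape
    ones = matrix.to_numpy(dtype=np.int64).sum(axis=1)
    counts = np.stack([r - ones, ones], axis=1)  # n_ij for categories {0, 1}

    p_j = counts.sum(axis=0) / (n * r)
    p_bar_e = float(np.sum(p_j**2))
    if p_bar_e >= 1.0:
        raise UndefinedStatisticError(
            "all ratings fall in a single category; Fleiss' kappa undefined"
        )
    p_i = (np.sum(counts**2, axis=1) - r) / (r * (r - 1))
    p_bar = float(p_i.mean())
    kappa = (p_bar - p_bar_e) / (1.0 - p_bar_e)

    q_j = 1.0 - p_j
    pq = p_j * q_j
    var = (
        2.0
        * (np.sum(pq) ** 2 - np.sum(pq * (q_j - p_j)))
        / (n * r * (r - 1) * np.sum(pq) ** 2)
    )
    se = float(np.sqrt(var))
    z = kappa / se
    return AgreementResult(
        kappa=float(kappa),
        ci_low=float(kappa - 1.96 * se),
        ci_high=float(kappa + 1.96 * se),
        p_value=float(stats.norm.sf(z)),
        se=se,
        n_items=n,
        n_raters=r,
    )


def majority_vote(matrix: pd.DataFrame, tie_policy: int | None = None) -> pd.Series:
    """Consensus label per item: the category chosen by more than r/2 raters.

    With an even panel a tie is possible; it raises unless ``tie_policy``
    supplies the label (0 or 1) to assign to tied items.
    """
    validate_rater_matrix(matrix)
    n, r = matrix.shape
    ones = matrix.to_numpy(dtype=np.int64).sum(axis=1)
    if r % 2 == 0:
        tied = ones * 2 == r
        if tied.any() and tie_policy is None:
            tied_ids = list(matrix.index[tied][:5])
            raise ValidationError(
                f"tie with an even rater panel (e.g. {tied_ids}); "
                "supply tie_policy=0 or 1"
            )
    consensus = (ones * 2 > r).astype(np.int64)
    if tie_policy is not None and r % 2 == 0:
        consensus[ones * 2 == r] = int(tie_policy)
    return pd.Series(consensus, index=matrix.index.copy(), name="label")


def disagreement_count(matrix: pd.DataFrame) -> int:
    """Number of items whose ratings are not unanimous."""
    validate_rater_matrix(matrix)
    values = matrix.to_numpy(dtype=np.int64)
    return int(np.sum(values.min(axis=1) != values.max(axis=1)))


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Read a ratings CSV (``segment_id,rater_1,...,rater_r``)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"segment_id": str})
    if "segment_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'segment_id'")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need at least 2 rater columns")
    matrix = df.set_index("segment_id")
    validate_rater_matrix(matrix)
    return matrix.astype(np.int64)


def write_ratings(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a rating matrix as a ratings CSV."""
    matrix.rename_axis("segment_id").reset_index().to_csv(path, index=False)
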