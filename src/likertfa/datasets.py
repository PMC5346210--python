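"""Ordinal questionnaire data: container, I/O, scoring and descriptives.

The canonical input is a respondent-by-item matrix of integer category
codes (0..C-1), e.g. the 12-item WHODAS 2.0 disability questionnaire with
five response categories per item.  Summary scores are simple item sums
(0-48 for the WHODAS 2.0 layout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LikertDataset",
    "SummaryScoreDistribution",
    "read_likert_csv",
    "complete_cases",
    "simple_score",
    "describe_scores",
]


class ValidationError(ValueError):
    """Raised when input data violate the ordinal-code contract."""


@dataclass
class LikertDataset:
    """Respondent-by-item matrix of ordinal category codes.

    Parameters
    ----------
    data : ndarray of shape (n, p)
        Integer codes in ``0..n_categories-1``.  Cells flagged in
        ``missing_mask`` are ignored (their stored value is arbitrary).
    n_categories : int
        Number of response categories C per item (codes ``0..C-1``).
    item_labels : list of str
        Unique item names; defaults to ``item_01..item_p``.
    missing_mask : ndarray of bool, shape (n, p)
        True where a response is missing.
    """

    data: np.ndarray
    n_categories: int = 5
    item_labels: list[str] = field(default_factory=list)
    missing_mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2-d respondent-by-item array")
        n, p = self.data.shape
        if p < 2:
            raise ValidationError("at least 2 items are required")
        if self.missing_mask is None:
            self.missing_mask = np.zeros((n, p), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (n, p):
            raise ValidationError("missing_mask shape must match data")
        if not self.item_labels:
            self.item_labels = [f"item_{j + 1:02d}" for j in range(p)]
        if len(self.item_labels) != p:
            raise ValidationError("item_labels length must equal item count")
        if len(set(self.item_labels)) != p:
            raise ValidationError("item_labels must be unique")
        observed = self.data[~self.missing_mask]
        if observed.size and (
                observed.min() < 0 or observed.max() > self.n_categories - 1):
            bad = np.argwhere(
                ~self.missing_mask
                & ((self.data < 0) | (self.data > self.n_categories - 1)))
            r, c = bad[0]
            raise ValidationError(
                f"code {self.data[r, c]} out of range 0..{self.n_categories - 1} "
                f"at row {r}, column '{self.item_labels[c]}'")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def p(self) -> int:
        return self.data.shape[1]

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def subset(self, rows) -> "LikertDataset":
        """Dataset restricted to the given row indices (order preserved)."""
        rows = np.asarray(rows)
        return LikertDataset(
            data=self.data[rows].copy(),
            n_categories=self.n_categories,
            item_labels=list(self.item_labels),
            missing_mask=self.missing_mask[rows].copy(),
        )


@dataclass
class SummaryScoreDistribution:
    """Distributional summary of simple-sum scores.

    ``skewness`` is the adjusted Fisher-Pearson coefficient
    g1 * sqrt(n(n-1))/(n-2) with classical standard error
    sqrt(6n(n-1)/((n-2)(n+1)(n+3))); percentiles use linear interpolation.
    """

    scores: np.ndarray
    mean: float
    sd: float
    skewness: float
    skewness_se: float
    percentiles: tuple[float, float, float]
    zero_proportion: float
    skewness_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "n": int(len(self.scores)),
            "mean": self.mean,
            "sd": self.sd,
            "skewness": self.skewness if self.skewness_defined else None,
            "skewness_se": self.skewness_se,
            "p25": self.percentiles[0],
            "p50": self.percentiles[1],
            "p75": self.percentiles[2],
            "zero_proportion": self.zero_proportion,
        }


def read_likert_csv(path, n_categories: int = 5,
                    missing_token: str = "") -> LikertDataset:
    """Read a respondent-by-item CSV of integer category codes.

    The file must have a header row of item labels and one respondent per
    row.  Empty cells (or ``missing_token``) become missing values; any
    other non-integer or out-of-range cell raises ``ValidationError``
    naming the offending row and column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    labels = [str(c) for c in df.columns]
    n, p = df.shape
    data = np.zeros((n, p), dtype=np.int64)
    mask = np.zeros((n, p), dtype=bool)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col].to_numpy()):
            cell = cell.strip()
            if cell == missing_token:
                mask[i, j] = True
                continue
            try:
                value = int(cell)
            except ValueError:
                raise ValidationError(
                    f"non-integer value '{cell}' at row {i}, column '{col}'")
            if not 0 <= value <= n_categories - 1:
                raise ValidationError(
                    f"code {value} out of range 0..{n_categories - 1} "
                    f"at row {i}, column '{col}'")
            data[i, j] = value
    return LikertDataset(data=data, n_categories=n_categories,
                         item_labels=labels, missing_mask=mask)


def complete_cases(ds: LikertDataset) -> LikertDataset:
    """Rows with no missing entries, in their original order."""
    keep = ~ds.missing_mask.any(axis=1)
    if not keep.any():
        raise ValidationError("no complete cases remain")
    return ds.subset(np.flatnonzero(keep))


def simple_score(ds: LikertDataset) -> np.ndarray:
    """Simple sum score per respondent (requires complete data)."""
    if not ds.is_complete:
        raise ValidationError(
            "simple_score requires complete data; apply complete_cases first")
    return ds.data.sum(axis=1)


def describe_scores(scores) -> SummaryScoreDistribution:
    """Mean, SD, adjusted skewness with SE, quartiles and zero proportion."""
    scores = np.asarray(scores)
    n = len(scores)
    if n < 4:
        raise ValidationError("describe_scores requires n >= 4")
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    se = math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
    if sd == 0.0:
        skew, defined = 0.0, False
    else:
        m2 = float(np.mean((scores - mean) ** 2))
        m3 = float(np.mean((scores - mean) ** 3))
        b1 = m3 / m2 ** 1.5
        skew = b1 * math.sqrt(n * (n - 1)) / (n - 2)
        defined = True
    p25, p50, p75 = np.percentile(scores, [25, 50, 75])
    return SummaryScoreDistribution(
        scores=scores,
        mean=mean,
        sd=sd,
        skewness=skew,
        skewness_se=se,
        percentiles=(float(p25), float(p50), float(p75)),
        zero_proportion=float(np.mean(scores == 0)),
        skewness_defined=defined,
    )
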