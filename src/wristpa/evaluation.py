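"""Evaluation statistics: confusion matrices, rank association, KS test.

Minute-wise agreement is reported through 5x5 confusion matrices (rows =
true category, columns = estimated, ordered sleep, sedentary, light,
moderate, vigorous). Non-wear and unknown minutes are excluded. Association
between a summary measure and the ordinal categories uses the Spearman rank
correlation with the natural intensity coding sleep=0 < ... < vigorous=4;
|rho| >= 0.3 is reported as statistically strong. Distribution comparisons
use the two-sample Kolmogorov-Smirnov test at the p = 0.01 level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    AlignmentError,
    Category,
    DataError,
    EpochSeries,
    LabelSeries,
    check_same_grid,
)

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "spearman_assoc",
    "ks_two_sample",
    "per_participant_summary",
    "STRONG_ASSOCIATION",
    "KS_ALPHA",
]

STRONG_ASSOCIATION = 0.3
KS_ALPHA = 0.01

_CATEGORY_ORDER = (
    Category.SLEEP,
    Category.SEDENTARY,
    Category.LIGHT,
    Category.MODERATE,
    Category.VIGOROUS,
)


@dataclass
class ConfusionMatrix:
    """5x5 minute-wise counts, true x estimated."""

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((5, 5), dtype=np.int64)
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (5, 5) or np.any(self.counts < 0):
            raise DataError("confusion counts must be a non-negative 5x5 grid")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total if self.total else float("nan")

    @property
    def per_category_correct(self) -> np.ndarray:
        """Fraction of each true category's minutes estimated correctly."""
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, np.diag(self.counts) / row, np.nan)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)

    def to_frame(self):
        import pandas as pd

        names = [c.name.lower() for c in _CATEGORY_ORDER]
        return pd.DataFrame(self.counts, index=names, columns=names)


def confusion(true: LabelSeries, est: LabelSeries) -> ConfusionMatrix:
    """Minute-wise confusion over the shared evaluated minutes.

    Minutes where either series is non-wear or unknown are excluded;
    matrices over disjoint minute sets add element-wise.
    """
    check_same_grid(true, est, what="label series")
    t = true.category
    e = est.category
    keep = (t >= 0) & (e >= 0)
    counts = np.zeros((5, 5), dtype=np.int64)
    np.add.at(counts, (t[keep], e[keep]), 1)
    return ConfusionMatrix(counts)


def spearman_assoc(values: EpochSeries | np.ndarray, labels: LabelSeries | np.ndarray) -> float:
    """Spearman rank correlation of epoch values with the ordinal categories.

    Average-rank tie handling; only minutes with one of the five categories
    and a finite value contribute. Raises ``DataError`` when the correlation
    is undefined (constant values or constant labels, or < 3 pairs).
    """
    v = values.values if isinstance(values, EpochSeries) else np.asarray(values, dtype=float)
    y = labels.category if isinstance(labels, LabelSeries) else np.asarray(labels, dtype=int)
    if len(v) != len(y):
        raise AlignmentError("values and labels differ in length")
    keep = np.isfinite(v) & (y >= 0)
    v, y = v[keep], y[keep]
    if len(v) < 3:
        raise DataError("Spearman correlation needs at least 3 paired minutes")
    if np.ptp(v) == 0 or np.ptp(y) == 0:
        raise DataError("Spearman correlation undefined for constant input")
    rho = stats.spearmanr(v, y).statistic
    return float(rho)


def ks_two_sample(a, b, exact: bool = False):
    """Two-sample KS test: ``(statistic, p_value, significant)``.

    D is the supremum distance between the two empirical CDFs; the p-value
    comes from the asymptotic KS distribution by default (sample sizes in
    this context are thousands of minutes) with the exact small-sample
    computation behind ``exact=True``. ``significant`` flags p < 0.01.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DataError("KS test needs two non-empty samples")
    res = stats.ks_2samp(a, b, method="exact" if exact else "asymp")
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < KS_ALPHA)


def per_participant_summary(folds):
    """Per-participant accuracies, their unweighted mean, and pooled matrix.

    ``folds`` is a sequence of per-participant :class:`ConfusionMatrix`.
    The pooled accuracy (minute-weighted) and the mean of per-participant
    accuracies differ when participants contribute unequal minute counts;
    both are reported.
    """
    folds = list(folds)
    if not folds:
        raise DataError("need at least one fold")
    accuracies = np.array([f.accuracy for f in folds])
    pooled = folds[0]
    for f in folds[1:]:
        pooled = pooled + f
    return {
        "per_participant_accuracy": accuracies,
        "mean_accuracy": float(accuracies.mean()),
        "pooled": pooled,
        "pooled_accuracy": pooled.accuracy,
    }
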