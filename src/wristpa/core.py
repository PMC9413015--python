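"""Shared domain types for wrist actigraphy processing.

All acceleration values are in gravitational units (g, 1 g = 9.81 m/s^2).
Time is carried as float seconds since the start of the recording; the
summarization epoch is one minute throughout, labeled by its *start* and
covering the half-open interval [start, start + 60 s).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

EPOCH_SECONDS = 60.0

MEASURES = ("enmonz", "mad", "ai", "rocam")


class Category(enum.IntEnum):
    """Five-level activity category, ordered by intensity.

    Negative codes are sentinels, not activity levels: ``NONWEAR`` marks
    minutes where the device was off-body and ``UNKNOWN`` marks minutes with
    incomplete raw data. Both are excluded from accuracy computations.
    """

    SLEEP = 0
    SEDENTARY = 1
    LIGHT = 2
    MODERATE = 3
    VIGOROUS = 4
    NONWEAR = -1
    UNKNOWN = -2

    @property
    def is_activity(self) -> bool:
        return self >= 0


#: The four awake physical-activity levels (excludes sleep and sentinels).
PA_LEVELS = (Category.SEDENTARY, Category.LIGHT, Category.MODERATE, Category.VIGOROUS)

#: Name <-> code table used by the text formats (case-insensitive on read).
CATEGORY_NAMES = {
    "sleep": Category.SLEEP,
    "sedentary": Category.SEDENTARY,
    "light": Category.LIGHT,
    "moderate": Category.MODERATE,
    "vigorous": Category.VIGOROUS,
    "nonwear": Category.NONWEAR,
    "non-wear": Category.NONWEAR,
    "unknown": Category.UNKNOWN,
}


def category_name(code: int) -> str:
    if code == Category.NONWEAR:
        return "nonwear"
    if code == Category.UNKNOWN:
        return "unknown"
    return Category(code).name.lower()


class WristpaError(Exception):
    """Base class for all package errors."""


class FormatError(WristpaError):
    """A file does not match the expected delimited-text layout."""


class DataError(WristpaError):
    """Input values violate a precondition (non-monotone time, too short...)."""


class AlignmentError(WristpaError):
    """Two per-minute series do not share the same epoch grid."""


class ConfigurationError(WristpaError):
    """Invalid parameter combination."""


class RangeError(WristpaError):
    """A requested window falls outside the record."""


class UnsupportedOperationError(WristpaError):
    """Operation outside the supported envelope (e.g. up-sampling)."""


@dataclass
class TriaxialRecord:
    """Raw tri-axial wrist acceleration at a fixed nominal sample rate.

    Parameters
    ----------
    timestamps : seconds since stream start, strictly increasing.
    x, y, z : per-axis acceleration in g.
    sample_rate_hz : nominal sample rate.
    dynamic_range_g : absolute sensor bound; samples are expected inside
        ``[-dynamic_range_g, +dynamic_range_g]`` (default ±8 g).
    jitter_tol : allowed relative deviation of successive timestamp gaps
        from ``1 / sample_rate_hz``.
    """

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sample_rate_hz: float
    dynamic_range_g: float = 8.0
    jitter_tol: float = 0.10

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.timestamps)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise DataError("timestamps, x, y, z must have identical length")
        if n < 2:
            raise DataError(f"record needs at least 2 samples, got {n}")
        gaps = np.diff(self.timestamps)
        if np.any(gaps <= 0):
            raise DataError("timestamps must be strictly increasing")
        nominal = 1.0 / self.sample_rate_hz
        if np.any(np.abs(gaps - nominal) > self.jitter_tol * nominal):
            raise DataError(
                "timestamp gaps deviate from the nominal sampling interval "
                f"{nominal:.6g} s by more than {self.jitter_tol:.0%}"
            )
        for name, a in (("x", self.x), ("y", self.y), ("z", self.z)):
            if np.any(np.abs(a) > self.dynamic_range_g + 1e-12):
                raise DataError(
                    f"axis {name} exceeds the ±{self.dynamic_range_g} g dynamic range"
                )

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) array view of the three axes."""
        return np.column_stack([self.x, self.y, self.z])

    def duration_seconds(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0]) + 1.0 / self.sample_rate_hz


@dataclass
class EpochSeries:
    """One summary-measure value per 1-minute epoch.

    ``values`` are in g for enmonz/mad/rocam; the activity index is a sum of
    sixty per-second variance averages and therefore carries g^2-derived
    units on a larger numeric scale.
    """

    epoch_start: np.ndarray
    values: np.ndarray
    measure_name: str
    sample_rate_hz: float | None = None
    epoch_seconds: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        self.epoch_start = np.asarray(self.epoch_start, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.measure_name not in MEASURES:
            raise ConfigurationError(
                f"unknown measure {self.measure_name!r}; expected one of {MEASURES}"
            )
        if len(self.epoch_start) != len(self.values):
            raise DataError("epoch_start and values must have identical length")
        if len(self.epoch_start) > 1:
            gaps = np.diff(self.epoch_start)
            if np.any(gaps <= 0) or np.any(np.abs(gaps / self.epoch_seconds % 1.0) > 1e-9):
                raise DataError("epoch_start must increase in whole-epoch steps")
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite < 0):
            raise DataError("summary-measure values must be non-negative")

    def __len__(self) -> int:
        return len(self.epoch_start)


@dataclass
class LabelSeries:
    """Per-minute activity category codes on a minute grid.

    ``transition`` optionally flags minutes adjacent to a schedule boundary in
    synthetic data so recovery statistics can exclude them.
    """

    epoch_start: np.ndarray
    category: np.ndarray
    transition: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epoch_start = np.asarray(self.epoch_start, dtype=float)
        self.category = np.asarray(self.category, dtype=int)
        if len(self.epoch_start) != len(self.category):
            raise DataError("epoch_start and category must have identical length")
        valid = {int(c) for c in Category}
        bad = set(np.unique(self.category)) - valid
        if bad:
            raise DataError(f"unknown category codes: {sorted(bad)}")
        if self.transition is not None:
            self.transition = np.asarray(self.transition, dtype=bool)
            if len(self.transition) != len(self.category):
                raise DataError("transition mask length mismatch")

    def __len__(self) -> int:
        return len(self.epoch_start)


def check_same_grid(*series, what: str = "series") -> np.ndarray:
    """Return the shared epoch grid of all inputs or raise ``AlignmentError``.

    Accepts any mix of EpochSeries / LabelSeries / raw arrays of epoch starts.
    """
    grids = []
    for s in series:
        if s is None:
            continue
        grid = s if isinstance(s, np.ndarray) else s.epoch_start
        grids.append(np.asarray(grid, dtype=float))
    if not grids:
        raise AlignmentError(f"no {what} provided")
    ref = grids[0]
    for g in grids[1:]:
        if len(g) != len(ref) or not np.allclose(g, ref, atol=1e-6):
            raise AlignmentError(f"{what} are not on the same epoch grid")
    return ref
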