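"""Non-wear and sleep segmentation of the minute grid.

Non-wear: a minute is *stationary* when all three per-axis standard
deviations within it stay at or below a small ceiling (13 mg per axis by
default, a widely used convention for an off-body device at rest); maximal
runs of stationary minutes lasting at least 60 minutes are flagged non-wear.
Shorter still periods (quiet sitting, sleep) are deliberately not flagged.

Sleep: a two-stage detector driven by the rate-of-change measure. Stage one
marks candidate minutes whose 1-minute epoch value lies below a candidate
threshold *and* whose within-minute 1-second means are quiet for at least a
given fraction of the minute (movement during sleep is sparse, so quietness
must hold through the minute, not just on average). Stage two joins
candidate segments separated by small gaps — brief awakenings or posture
shifts — and keeps only joined blocks of a minimum duration. Non-wear
minutes are never sleep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AlignmentError,
    ConfigurationError,
    EPOCH_SECONDS,
    EpochSeries,
    TriaxialRecord,
    check_same_grid,
)
from .summary_measures import MeasureConfig, rocam

__all__ = ["NonwearParams", "SleepParams", "detect_nonwear", "detect_sleep", "sleep_blocks"]


@dataclass
class NonwearParams:
    min_duration_minutes: int = 60
    stationarity_sd_g: float = 0.013

    def __post_init__(self) -> None:
        if self.min_duration_minutes < 1:
            raise ConfigurationError("min_duration_minutes must be >= 1")
        if self.stationarity_sd_g <= 0:
            raise ConfigurationError("stationarity_sd_g must be positive")


@dataclass
class SleepParams:
    """Defaults: candidate threshold at the sedentary floor (0.06 g) since
    sleep minutes sit below the lowest sedentary cut; 90% of 1-second
    windows must be quiet; candidate segments up to 30 min apart are joined
    and joined blocks must last at least 30 min."""

    candidate_threshold: float = 0.06
    quiet_fraction: float = 0.9
    join_gap_minutes: int = 30
    min_block_minutes: int = 30

    def __post_init__(self) -> None:
        if self.candidate_threshold <= 0:
            raise ConfigurationError("candidate_threshold must be positive")
        if not 0 < self.quiet_fraction <= 1:
            raise ConfigurationError("quiet_fraction must be in (0, 1]")
        if self.join_gap_minutes < 0 or self.min_block_minutes < 1:
            raise ConfigurationError("join/min-block durations out of range")


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def _minute_view(record: TriaxialRecord):
    """Trim the record to whole minutes aligned to the epoch grid."""
    fs = record.sample_rate_hz
    spm = int(round(EPOCH_SECONDS * fs))
    t0 = record.timestamps[0]
    origin = np.ceil(t0 / EPOCH_SECONDS - 1e-9) * EPOCH_SECONDS
    i0 = int(np.searchsorted(record.timestamps, origin - 1e-9))
    n_minutes = (len(record) - i0) // spm
    starts = origin + EPOCH_SECONDS * np.arange(n_minutes)
    return i0, spm, n_minutes, starts


def detect_nonwear(
    record: TriaxialRecord, params: NonwearParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute non-wear mask; returns ``(epoch_start, mask)``.

    Stationarity depends only on within-minute deviations, so the mask is
    invariant to constant offsets on any axis (device orientation does not
    matter).
    """
    params = params or NonwearParams()
    i0, spm, n_minutes, starts = _minute_view(record)
    stationary = np.ones(n_minutes, dtype=bool)
    for axis in (record.x, record.y, record.z):
        w = axis[i0 : i0 + n_minutes * spm].reshape(n_minutes, spm)
        stationary &= w.std(axis=1) <= params.stationarity_sd_g
    mask = np.zeros(n_minutes, dtype=bool)
    for a, b in _runs(stationary):
        if b - a >= params.min_duration_minutes:
            mask[a:b] = True
    return starts, mask


def detect_sleep(
    record: TriaxialRecord,
    epochs_rocam: EpochSeries,
    params: SleepParams | None = None,
    nonwear_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-minute sleep mask on the grid of ``epochs_rocam``.

    Joining is monotone: a larger ``join_gap_minutes`` never yields fewer
    sleep minutes.
    """
    params = params or SleepParams()
    if epochs_rocam.measure_name != "rocam":
        raise AlignmentError("sleep detection expects the rocam epoch series")
    i0, spm, n_minutes, starts = _minute_view(record)
    grid = check_same_grid(starts[: len(epochs_rocam)], epochs_rocam, what="sleep inputs")
    n = len(grid)
    if nonwear_mask is not None and len(nonwear_mask) != n:
        raise AlignmentError("non-wear mask is not on the epoch grid")

    # stage 1: candidates = quiet epoch AND quiet through the minute
    per_sample = rocam(record, MeasureConfig())
    fs = record.sample_rate_hz
    sps = int(round(fs))  # samples per second
    per_min = per_sample[i0 : i0 + n * spm].reshape(n, spm)
    seconds = per_min.reshape(n, int(EPOCH_SECONDS), sps).mean(axis=2)
    quiet_frac = (seconds < params.candidate_threshold).mean(axis=1)
    with np.errstate(invalid="ignore"):
        candidates = (
            (epochs_rocam.values[:n] < params.candidate_threshold)
            & (quiet_frac >= params.quiet_fraction)
        )
    candidates &= np.isfinite(epochs_rocam.values[:n])

    # stage 2: bridge small gaps, then enforce minimum block length
    joined = candidates.copy()
    runs = _runs(candidates)
    for (a1, b1), (a2, b2) in zip(runs, runs[1:]):
        if a2 - b1 <= params.join_gap_minutes:
            joined[b1:a2] = True
    sleep = np.zeros(n, dtype=bool)
    for a, b in _runs(joined):
        if b - a >= params.min_block_minutes:
            sleep[a:b] = True
    if nonwear_mask is not None:
        sleep &= ~np.asarray(nonwear_mask, dtype=bool)
    return sleep


def sleep_blocks(epoch_start: np.ndarray, sleep_mask: np.ndarray):
    """(onset, offset) epoch-start times of each sleep block.

    Onset is the first minute of the block; offset the start of its last
    minute.
    """
    out = []
    for a, b in _runs(np.asarray(sleep_mask, dtype=bool)):
        out.append((float(epoch_start[a]), float(epoch_start[b - 1])))
    return out
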