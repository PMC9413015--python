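"""The four acceleration summary measures and 1-minute epoch aggregation.

Each measure projects the tri-axial stream x(t), y(t), z(t) (in g) onto a
single non-negative series:

* ENMONZ — Euclidean norm minus one, clamped at zero. Removes the static
  1 g gravity component under the assumption of a calibrated, slowly
  re-orienting sensor: ``max(sqrt(x^2 + y^2 + z^2) - 1, 0)``.
* MAD — mean amplitude deviation of the Euclidean norm within a window of
  N samples: ``mean(|EN - mean(EN)|)``. Removes gravity through the window
  mean rather than the fixed 1 g constant.
* AI — activity index: the per-window average of the three per-axis
  population variances, clamped at zero after subtracting an optional
  device noise variance. Computed on 1-second windows and *summed* over the
  minute, following its original formulation.
* ROCAM — rate-of-change acceleration movement: the Euclidean norm of
  successive per-axis first differences,
  ``sqrt(dx_t^2 + dy_t^2 + dz_t^2)``, then smoothed with a running median
  whose length is the number of samples in one second. Successive
  differencing cancels gravity and calibration offsets outright, at the
  price of making the scale sample-rate dependent (per-sample differences
  shrink as the sample rate grows), hence rate-specific thresholds.

Minute epochs take the arithmetic mean of the intermediate values, except
AI where the sixty 1-second values are summed. Epochs are clock-aligned to
the minute grid of the first full minute; partial epochs are marked unknown
(NaN value) and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EPOCH_SECONDS, DataError, EpochSeries, TriaxialRecord

__all__ = [
    "MeasureConfig",
    "enmonz",
    "mad",
    "activity_index",
    "rocam",
    "epoch_aggregate",
    "summarize",
]


@dataclass
class MeasureConfig:
    """Windowing parameters for the summary measures.

    mad_window_seconds defaults to the full 1-minute epoch so the epoch
    average is taken over a single window; shorter windows (e.g. the 6 s
    convention of some studies) are supported. The AI window and the ROCAM
    median-filter length are fixed at one second by construction.
    """

    mad_window_seconds: float = 60.0
    ai_window_seconds: float = 1.0
    ai_noise_variance: float = 0.0
    rocam_median_window_seconds: float = 1.0
    epoch_seconds: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        for name in ("mad_window_seconds", "ai_window_seconds", "epoch_seconds",
                     "rocam_median_window_seconds"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")
        if self.ai_noise_variance < 0:
            raise DataError("ai_noise_variance must be non-negative")


def _euclidean_norm(record: TriaxialRecord) -> np.ndarray:
    return np.sqrt(record.x**2 + record.y**2 + record.z**2)


def enmonz(record: TriaxialRecord) -> np.ndarray:
    """Per-sample Euclidean norm minus one, floored at zero (g)."""
    return np.maximum(_euclidean_norm(record) - 1.0, 0.0)


def _aligned_origin_index(record: TriaxialRecord, grid_seconds: float) -> int:
    """Index of the first sample on or after the first whole grid boundary."""
    t0 = record.timestamps[0]
    origin = np.ceil(t0 / grid_seconds - 1e-9) * grid_seconds
    return int(np.searchsorted(record.timestamps, origin - 1e-9))


def _window_view(record: TriaxialRecord, window_seconds: float):
    """Tile the record into non-overlapping windows aligned to the minute grid.

    Returns ``(window_start_times, slice_of_first_sample_indices, N)`` where
    N is the sample count per window.
    """
    n_samples = int(round(window_seconds * record.sample_rate_hz))
    if n_samples < 2:
        raise DataError(
            f"window of {window_seconds} s holds fewer than 2 samples at "
            f"{record.sample_rate_hz} Hz"
        )
    if n_samples > len(record):
        raise DataError("window longer than the record")
    i0 = _aligned_origin_index(record, EPOCH_SECONDS)
    k = (len(record) - i0) // n_samples
    if k < 1:
        raise DataError("record does not cover a single full window after alignment")
    starts = record.timestamps[i0 + n_samples * np.arange(k)]
    return starts, i0, n_samples, k


def mad(record: TriaxialRecord, config: MeasureConfig | None = None):
    """Mean amplitude deviation of the vector norm per window.

    Returns ``(window_start_times, values)``; one value per non-overlapping
    window of ``config.mad_window_seconds``.
    """
    config = config or MeasureConfig()
    starts, i0, n, k = _window_view(record, config.mad_window_seconds)
    en = _euclidean_norm(record)[i0 : i0 + n * k].reshape(k, n)
    values = np.mean(np.abs(en - en.mean(axis=1, keepdims=True)), axis=1)
    return starts, values


def activity_index(record: TriaxialRecord, config: MeasureConfig | None = None):
    """Per-second activity index: clamped mean of the per-axis variances.

    Variances use the population (1/N) form. Returns
    ``(window_start_times, values)`` on the 1-second grid.
    """
    config = config or MeasureConfig()
    starts, i0, n, k = _window_view(record, config.ai_window_seconds)
    var_sum = np.zeros(k)
    for axis in (record.x, record.y, record.z):
        w = axis[i0 : i0 + n * k].reshape(k, n)
        var_sum += w.var(axis=1)  # population variance
    values = np.maximum(var_sum / 3.0 - config.ai_noise_variance, 0.0)
    return starts, values


def _running_lower_median(v: np.ndarray, window: int) -> np.ndarray:
    """Centered running median; even windows take the lower median, edges shrink.

    For window length w the sample at index i sees ``v[i-(w-1)//2 : i+w//2+1]``.
    """
    n = len(v)
    if window <= 1 or n == 0:
        return v.copy()
    left = (window - 1) // 2
    right = window // 2
    out = np.empty_like(v)
    if n >= window:
        sw = np.lib.stride_tricks.sliding_window_view(v, window)
        lower_mid = (window - 1) // 2
        out[left : n - right] = np.partition(sw, lower_mid, axis=1)[:, lower_mid]
        edge_idx = list(range(left)) + list(range(n - right, n))
    else:
        edge_idx = range(n)
    for i in edge_idx:
        w = v[max(0, i - left) : min(n, i + right + 1)]
        m = len(w)
        out[i] = np.partition(w, (m - 1) // 2)[(m - 1) // 2]
    return out


def rocam(record: TriaxialRecord, config: MeasureConfig | None = None) -> np.ndarray:
    """Per-sample rate-of-change acceleration movement (g).

    Euclidean norm of the per-axis successive differences, median-filtered
    over a 1-second window. The undefined t = 0 difference is set equal to
    the t = 1 value before filtering so the output length equals the record
    length.
    """
    config = config or MeasureConfig()
    d = np.sqrt(
        np.diff(record.x) ** 2 + np.diff(record.y) ** 2 + np.diff(record.z) ** 2
    )
    series = np.concatenate([[d[0]], d])
    window = int(round(config.rocam_median_window_seconds * record.sample_rate_hz))
    return _running_lower_median(series, window)


def epoch_aggregate(
    times: np.ndarray,
    values: np.ndarray,
    measure_name: str,
    samples_per_epoch: int,
    sample_rate_hz: float | None = None,
) -> EpochSeries:
    """Aggregate an intermediate series onto the 1-minute epoch grid.

    ENMONZ/MAD/ROCAM epochs are means of the intermediate values; AI epochs
    are the *sum* of the per-second values. Epochs with fewer than
    ``samples_per_epoch`` intermediate values are marked unknown (NaN).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) == 0:
        raise DataError("empty intermediate series")
    origin = np.ceil(times[0] / EPOCH_SECONDS - 1e-9) * EPOCH_SECONDS
    last = times[-1]
    n_epochs = int(np.floor((last - origin) / EPOCH_SECONDS + 1e-9)) + 1
    if n_epochs < 1:
        raise DataError("series does not overlap a single full epoch")
    idx = np.floor((times - origin) / EPOCH_SECONDS + 1e-9).astype(int)
    inside = (idx >= 0) & (idx < n_epochs)
    counts = np.bincount(idx[inside], minlength=n_epochs)
    sums = np.bincount(idx[inside], weights=values[inside], minlength=n_epochs)
    with np.errstate(invalid="ignore", divide="ignore"):
        if measure_name == "ai":
            out = sums
        else:
            out = sums / counts
    out = np.where(counts >= samples_per_epoch, out, np.nan)
    starts = origin + EPOCH_SECONDS * np.arange(n_epochs)
    return EpochSeries(
        epoch_start=starts,
        values=out,
        measure_name=measure_name,
        sample_rate_hz=sample_rate_hz,
    )


def summarize(
    record: TriaxialRecord, config: MeasureConfig | None = None
) -> dict[str, EpochSeries]:
    """All four measures of one record on a shared 1-minute epoch grid."""
    config = config or MeasureConfig()
    fs = record.sample_rate_hz
    out: dict[str, EpochSeries] = {}

    per_sample_n = int(round(EPOCH_SECONDS * fs))
    out["enmonz"] = epoch_aggregate(
        record.timestamps, enmonz(record), "enmonz", per_sample_n, fs
    )
    mad_t, mad_v = mad(record, config)
    out["mad"] = epoch_aggregate(
        mad_t, mad_v, "mad", int(round(EPOCH_SECONDS / config.mad_window_seconds)), fs
    )
    ai_t, ai_v = activity_index(record, config)
    out["ai"] = epoch_aggregate(
        ai_t, ai_v, "ai", int(round(EPOCH_SECONDS / config.ai_window_seconds)), fs
    )
    out["rocam"] = epoch_aggregate(
        record.timestamps, rocam(record, config), "rocam", per_sample_n, fs
    )
    return out
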