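"""End-to-end convenience: raw record -> epochs, masks and labels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EpochSeries, LabelSeries, TriaxialRecord
from .pa_classifier import ThresholdSet, classify_all_measures, default_thresholds
from .summary_measures import MeasureConfig, summarize
from .wear_sleep import NonwearParams, SleepParams, detect_nonwear, detect_sleep

__all__ = ["DayResult", "process_day"]


@dataclass
class DayResult:
    """Per-minute outputs of the full pipeline for one record."""

    epochs: dict[str, EpochSeries]
    nonwear_mask: np.ndarray
    sleep_mask: np.ndarray
    labels: dict[str, LabelSeries]


def process_day(
    record: TriaxialRecord,
    thresholds: dict[str, ThresholdSet] | None = None,
    measure_config: MeasureConfig | None = None,
    sleep_params: SleepParams | None = None,
    nonwear_params: NonwearParams | None = None,
) -> DayResult:
    """Summarize, segment and classify one record on the 1-minute grid.

    Returns the four epoch series, the non-wear and sleep masks, and one
    label series per measure (default thresholds unless given).
    """
    epochs = summarize(record, measure_config)
    grid_n = len(next(iter(epochs.values())))
    _, nonwear = detect_nonwear(record, nonwear_params)
    nonwear = nonwear[:grid_n]
    sleep = detect_sleep(record, epochs["rocam"], sleep_params, nonwear)
    thresholds = thresholds or {m: default_thresholds(m) for m in epochs}
    labels = classify_all_measures(epochs, thresholds, sleep, nonwear)
    return DayResult(
        epochs=epochs, nonwear_mask=nonwear, sleep_mask=sleep, labels=labels
    )
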