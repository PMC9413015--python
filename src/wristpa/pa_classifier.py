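"""Threshold-based minute-by-minute activity classification.

Each summary measure gets four ordered cut-points partitioning (0, inf)
into sleep / sedentary / light / moderate / vigorous bands with half-open
``lower < x <= upper`` semantics. The shipped defaults were derived on
free-living wrist data sampled at 10 Hz; thresholds are rate-specific, so
applying a set to epochs computed at a different rate emits a loud warning.

Precedence per minute: non-wear mask, then sleep mask, then the value
bands; a value at or below the sleep floor on a worn, awake minute is also
labeled sleep (movement below the sedentary floor is indistinguishable
from sleep at epoch scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AlignmentError,
    Category,
    ConfigurationError,
    EpochSeries,
    LabelSeries,
    MEASURES,
    check_same_grid,
)

__all__ = [
    "ThresholdSet",
    "default_thresholds",
    "classify_epochs",
    "classify_all_measures",
    "read_threshold_table",
    "write_threshold_table",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Four ordered cut-points for one measure at one sample rate (g)."""

    measure_name: str
    sample_rate_hz: float
    sleep_floor: float
    sed_light: float
    light_mod: float
    mod_vig: float

    def __post_init__(self) -> None:
        if self.measure_name not in MEASURES:
            raise ConfigurationError(
                f"unknown measure {self.measure_name!r}; expected one of {MEASURES}"
            )
        cuts = (self.sleep_floor, self.sed_light, self.light_mod, self.mod_vig)
        if not all(a < b for a, b in zip(cuts, cuts[1:])) or cuts[0] <= 0:
            raise ConfigurationError(
                f"cut-points must satisfy 0 < sleep_floor < sed_light < "
                f"light_mod < mod_vig, got {cuts}"
            )

    @property
    def cuts(self) -> np.ndarray:
        return np.array(
            [self.sleep_floor, self.sed_light, self.light_mod, self.mod_vig]
        )


# Default cut-points for data sampled at 10 Hz.
_DEFAULTS_10HZ = {
    "enmonz": (1e-9, 0.032, 0.173, 0.382),
    "mad": (0.001, 0.059, 0.242, 0.38),
    "ai": (0.010, 5.308, 17.010, 23.628),
    "rocam": (0.06, 0.175, 0.400, 0.483),
}
# The published ENMONZ sedentary band opens at 0; a strictly positive sleep
# floor is required for the ordering invariant, so an epsilon floor is used
# (ENMONZ == 0 exactly then maps to sleep, matching "x <= 0" -> below the
# sedentary band).


def default_thresholds(measure_name: str) -> ThresholdSet:
    """The shipped 10 Hz cut-points for one of the four measures."""
    key = measure_name.lower()
    if key not in _DEFAULTS_10HZ:
        raise ConfigurationError(
            f"no default thresholds for {measure_name!r}; choose one of {MEASURES}"
        )
    return ThresholdSet(key, 10.0, *_DEFAULTS_10HZ[key])


def band_labels(values: np.ndarray, thresholds: ThresholdSet) -> np.ndarray:
    """Map positive values to category codes by the ordered bands.

    ``value <= sleep_floor`` -> sleep; then (sleep_floor, sed_light] ->
    sedentary and so on; ``value > mod_vig`` -> vigorous. NaN -> unknown.
    """
    values = np.asarray(values, dtype=float)
    # number of cuts strictly below the value == category code
    codes = np.searchsorted(thresholds.cuts, values, side="left").astype(int)
    codes[np.isnan(values)] = int(Category.UNKNOWN)
    return codes


def classify_epochs(
    epochs: EpochSeries,
    thresholds: ThresholdSet,
    sleep_mask: np.ndarray | None = None,
    nonwear_mask: np.ndarray | None = None,
) -> LabelSeries:
    """Classify each minute; precedence non-wear > sleep mask > value bands."""
    if thresholds.measure_name != epochs.measure_name:
        raise ConfigurationError(
            f"thresholds are for {thresholds.measure_name!r} but epochs carry "
            f"{epochs.measure_name!r}"
        )
    if (
        epochs.sample_rate_hz is not None
        and abs(epochs.sample_rate_hz - thresholds.sample_rate_hz) > 1e-9
    ):
        warnings.warn(
            f"applying {thresholds.sample_rate_hz:g} Hz thresholds to epochs "
            f"derived at {epochs.sample_rate_hz:g} Hz: cut-points are "
            "sample-rate specific and will misclassify",
            stacklevel=2,
        )
    n = len(epochs)
    for name, mask in (("sleep", sleep_mask), ("non-wear", nonwear_mask)):
        if mask is not None and len(mask) != n:
            raise AlignmentError(f"{name} mask is not on the epoch grid")
    codes = band_labels(epochs.values, thresholds)
    if sleep_mask is not None:
        codes[np.asarray(sleep_mask, dtype=bool)] = int(Category.SLEEP)
    if nonwear_mask is not None:
        codes[np.asarray(nonwear_mask, dtype=bool)] = int(Category.NONWEAR)
    return LabelSeries(epoch_start=epochs.epoch_start.copy(), category=codes)


def classify_all_measures(
    epoch_tables: dict[str, EpochSeries],
    thresholds: dict[str, ThresholdSet] | None = None,
    sleep_mask: np.ndarray | None = None,
    nonwear_mask: np.ndarray | None = None,
) -> dict[str, LabelSeries]:
    """One label series per measure with shared sleep/non-wear handling."""
    thresholds = thresholds or {m: default_thresholds(m) for m in epoch_tables}
    check_same_grid(*epoch_tables.values(), what="epoch tables")
    return {
        m: classify_epochs(ep, thresholds[m], sleep_mask, nonwear_mask)
        for m, ep in epoch_tables.items()
    }


def write_threshold_table(thresholds, path) -> Path:
    """CSV ``measure,rate_hz,sleep_floor,sed_light,light_mod,mod_vig``."""
    if isinstance(thresholds, ThresholdSet):
        thresholds = [thresholds]
    rows = [
        {
            "measure": t.measure_name,
            "rate_hz": t.sample_rate_hz,
            "sleep_floor": t.sleep_floor,
            "sed_light": t.sed_light,
            "light_mod": t.light_mod,
            "mod_vig": t.mod_vig,
        }
        for t in thresholds
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
    return path


def read_threshold_table(path) -> dict[tuple[str, float], ThresholdSet]:
    """Read a threshold CSV keyed by ``(measure, rate_hz)``."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        t = ThresholdSet(
            str(row["measure"]).lower(),
            float(row["rate_hz"]),
            float(row["sleep_floor"]),
            float(row["sed_light"]),
            float(row["light_mod"]),
            float(row["mod_vig"]),
        )
        out[(t.measure_name, t.sample_rate_hz)] = t
    return out
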