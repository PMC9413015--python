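"""Delimited-text I/O for raw acceleration streams, epoch tables and labels.

File dialect: comma-separated with a header row. The time column is either
float seconds since stream start or ISO-8601 timestamps (auto-detected; the
first timestamp becomes t = 0). Values are gravitational units (g).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CATEGORY_NAMES,
    Category,
    DataError,
    EpochSeries,
    FormatError,
    LabelSeries,
    TriaxialRecord,
    category_name,
    check_same_grid,
)

log = logging.getLogger(__name__)

__all__ = ["read_triaxial", "write_triaxial", "write_epochs", "read_epochs", "read_labels", "write_labels"]


def _parse_time_column(col: pd.Series) -> np.ndarray:
    """Float seconds since start, accepting either numeric or ISO-8601 input."""
    numeric = pd.to_numeric(col, errors="coerce")
    if not numeric.isna().any():
        return numeric.to_numpy(dtype=float)
    try:
        stamps = pd.to_datetime(col, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"time column is neither numeric nor ISO-8601: {exc}") from None
    return (stamps - stamps.iloc[0]).dt.total_seconds().to_numpy(dtype=float)


def _require_columns(df: pd.DataFrame, needed: tuple[str, ...], path) -> pd.DataFrame:
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df


def read_triaxial(
    path,
    sample_rate_hz: float,
    dynamic_range_g: float = 8.0,
    jitter_tol: float = 0.10,
) -> TriaxialRecord:
    """Read a raw ``time,x,y,z`` CSV into a validated :class:`TriaxialRecord`.

    Samples outside ``±dynamic_range_g`` are clipped to the bound (sign
    preserved) and counted in a warning, so the epoch grid stays intact.
    """
    df = pd.read_csv(path)
    df = _require_columns(df, ("time", "x", "y", "z"), path)
    t = _parse_time_column(df["time"])
    if len(t) < 2:
        raise DataError(f"{path}: fewer than 2 samples")
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: time column is not strictly increasing")
    axes = {}
    n_clipped = 0
    for name in ("x", "y", "z"):
        a = df[name].to_numpy(dtype=float)
        over = np.abs(a) > dynamic_range_g
        n_clipped += int(over.sum())
        axes[name] = np.clip(a, -dynamic_range_g, dynamic_range_g)
    if n_clipped:
        warnings.warn(
            f"{path}: clipped {n_clipped} sample value(s) to ±{dynamic_range_g} g",
            stacklevel=2,
        )
    return TriaxialRecord(
        timestamps=t,
        sample_rate_hz=sample_rate_hz,
        dynamic_range_g=dynamic_range_g,
        jitter_tol=jitter_tol,
        **axes,
    )


def write_triaxial(record: TriaxialRecord, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"time": record.timestamps, "x": record.x, "y": record.y, "z": record.z}
    ).to_csv(path, index=False, float_format="%.10g")
    return path


def write_epochs(series, path, labels: LabelSeries | None = None) -> Path:
    """Write one or more :class:`EpochSeries` (plus optional labels) as CSV.

    One row per minute, one column per measure. All series must share the
    same epoch grid; values round-trip at 10 significant digits.
    """
    if isinstance(series, EpochSeries):
        series = [series]
    series = list(series)
    if not series and labels is None:
        raise DataError("nothing to write")
    grid = check_same_grid(*series, labels, what="epoch series")
    data: dict[str, np.ndarray] = {"time": grid}
    for s in series:
        data[s.measure_name] = s.values
    if labels is not None:
        data["label"] = np.array([category_name(c) for c in labels.category])
    path = Path(path)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")
    return path


def read_epochs(path, sample_rate_hz: float | None = None) -> dict[str, EpochSeries | LabelSeries]:
    """Read an epoch CSV back into per-measure series keyed by measure name.

    A ``label`` column, if present, is returned under the key ``"label"`` as
    a :class:`LabelSeries`.
    """
    df = pd.read_csv(path)
    df = _require_columns(df, ("time",), path)
    t = _parse_time_column(df["time"])
    out: dict[str, EpochSeries | LabelSeries] = {}
    for col in df.columns:
        if col == "time":
            continue
        if col == "label":
            out["label"] = _labels_from_strings(t, df[col], path)
        else:
            out[col] = EpochSeries(
                epoch_start=t,
                values=df[col].to_numpy(dtype=float),
                measure_name=col,
                sample_rate_hz=sample_rate_hz,
            )
    return out


def _labels_from_strings(t: np.ndarray, col: pd.Series, path) -> LabelSeries:
    codes = np.empty(len(col), dtype=int)
    for i, raw in enumerate(col):
        key = str(raw).strip().lower()
        if key not in CATEGORY_NAMES:
            raise FormatError(
                f"{path}: unknown category {raw!r}; expected one of "
                f"{sorted(set(CATEGORY_NAMES) - {'non-wear'})}"
            )
        codes[i] = CATEGORY_NAMES[key]
    return LabelSeries(epoch_start=t, category=codes)


def read_labels(path) -> LabelSeries:
    """Read a ``time,category`` CSV of per-minute ground-truth labels."""
    df = pd.read_csv(path)
    if df.empty and set(c.strip().lower() for c in df.columns) >= {"time", "category"}:
        return LabelSeries(epoch_start=np.empty(0), category=np.empty(0, dtype=int))
    df = _require_columns(df, ("time", "category"), path)
    t = _parse_time_column(df["time"])
    return _labels_from_strings(t, df["category"], path)


def write_labels(labels: LabelSeries, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "time": labels.epoch_start,
            "category": [category_name(c) for c in labels.category],
        }
    ).to_csv(path, index=False, float_format="%.10g")
    return path
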