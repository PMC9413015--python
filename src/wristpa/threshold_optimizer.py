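"""Learning activity-intensity cut-points from labeled epochs.

Three stages:

1. *Initialization* — per category, a diffusion-bandwidth kernel density of
   the epoch values; each adjacent-category cut starts at the point of
   minimal summed density between the two category modes (the "valley"
   where the stratified distributions overlap least).
2. *Refinement* — bounded maximization of pooled minute-wise accuracy over
   the four awake activity levels. The objective is piecewise-constant in
   each cut (it changes only when a cut crosses an observed value), so each
   coordinate is maximized exactly by scanning candidate cut positions at
   midpoints of adjacent sorted observed values; coordinate descent repeats
   until no sweep improves the objective. Sleep is excluded from the
   objective: it is detected separately, and the sleep floor is carried
   over from the initialization.
3. *Validation* — a leave-one-participant-out (LOPO) harness: thresholds
   are fitted on N-1 participants and evaluated on the held-out one; fold
   confusion matrices are collated into a single pooled matrix, and
   per-participant accuracies are also averaged.

``ThresholdModel`` / ``ThresholdResults`` wrap the same machinery in a
fit/results interface with a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._kde import kde_diffusion
from .core import (
    Category,
    ConfigurationError,
    DataError,
    EpochSeries,
    LabelSeries,
    PA_LEVELS,
    check_same_grid,
)
from .evaluation import ConfusionMatrix, confusion, per_participant_summary
from .pa_classifier import ThresholdSet, band_labels

__all__ = [
    "OptimizerSpec",
    "kde_diffusion",
    "init_thresholds",
    "optimize_thresholds",
    "lopo_run",
    "LopoResult",
    "ThresholdModel",
    "ThresholdResults",
]

_ORDER = (
    Category.SLEEP,
    Category.SEDENTARY,
    Category.LIGHT,
    Category.MODERATE,
    Category.VIGOROUS,
)
_MIN_PER_CATEGORY = 30


@dataclass
class OptimizerSpec:
    """Search configuration.

    bounds : optional list of four (lower, upper) pairs in g, one per cut
        (sleep floor, sed/light, light/mod, mod/vig). Defaults per cut to
        [5th percentile of the lower category, 95th percentile of the upper
        category], mirroring inspection of the stratified distributions and
        guarding against dominant classes swallowing a cut.
    init : a ThresholdSet or "auto" for the density-valley initialization.
    tolerance : minimum accuracy improvement to continue iterating.
    max_evaluations : cap on objective evaluations.
    max_candidates : per-coordinate cap on scanned cut positions (candidates
        are thinned evenly when more midpoints exist).
    """

    bounds: list[tuple[float, float]] | None = None
    init: ThresholdSet | str = "auto"
    objective: str = "pooled"
    tolerance: float = 1e-6
    max_evaluations: int = 5000
    max_candidates: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.objective not in ("pooled", "per_participant"):
            raise ConfigurationError("objective must be 'pooled' or 'per_participant'")
        if self.bounds is not None:
            if len(self.bounds) != 4 or any(lo >= hi for lo, hi in self.bounds):
                raise ConfigurationError("bounds must be four (lower < upper) pairs")
            los = [b[0] for b in self.bounds]
            his = [b[1] for b in self.bounds]
            if any(l2 >= h1 for l2, h1 in zip(los[1:], his[:-1])) and any(
                his[i] <= los[i] for i in range(4)
            ):
                raise ConfigurationError("bounds leave no feasible ordered cut set")


def _stratify(values: np.ndarray, labels: np.ndarray) -> dict[Category, np.ndarray]:
    out = {}
    for cat in _ORDER:
        v = values[(labels == int(cat)) & np.isfinite(values)]
        if len(v):
            out[cat] = v
    return out


def _valley_cut(lower: np.ndarray, upper: np.ndarray) -> float | None:
    """Minimum of the summed densities between the two category modes."""
    lo = min(lower.min(), upper.min())
    hi = max(lower.max(), upper.max())
    if hi - lo <= 0:
        return None
    limits = (lo - (hi - lo) / 10, hi + (hi - lo) / 10)
    try:
        grid, dens_lo, _ = kde_diffusion(lower, limits=limits)
        _, dens_hi, _ = kde_diffusion(upper, limits=limits)
    except DataError:
        return None
    mode_lo = grid[np.argmax(dens_lo)]
    mode_hi = grid[np.argmax(dens_hi)]
    if mode_hi <= mode_lo:
        return None
    between = (grid > mode_lo) & (grid < mode_hi)
    if not between.any():
        return None
    overlap = dens_lo + dens_hi
    return float(grid[between][np.argmin(overlap[between])])


def default_bounds(stratified: dict[Category, np.ndarray]) -> list[tuple[float, float]]:
    """Per-cut [5th pct of lower category, 95th pct of upper category]."""
    bounds = []
    prev_hi = 0.0
    for lower_cat, upper_cat in zip(_ORDER, _ORDER[1:]):
        lo_sample = stratified.get(lower_cat)
        hi_sample = stratified.get(upper_cat)
        lo = float(np.percentile(lo_sample, 5)) if lo_sample is not None else prev_hi
        hi = (
            float(np.percentile(hi_sample, 95))
            if hi_sample is not None
            else lo + 1.0
        )
        if hi <= lo:
            hi = lo + max(1e-6, abs(lo) * 0.1)
        bounds.append((max(lo, 1e-12), hi))
        prev_hi = hi
    return bounds


def init_thresholds(
    stratified: dict[Category, np.ndarray],
    measure_name: str = "rocam",
    sample_rate_hz: float = 10.0,
    bounds: list[tuple[float, float]] | None = None,
) -> ThresholdSet:
    """Density-valley initialization of the four cuts.

    For each adjacent category pair the cut minimizes the summed densities
    between the pair's modes; a missing or degenerate pair falls back to
    the midpoint of that cut's bounds with a warning. The sleep floor comes
    from the sleep/sedentary pair.
    """
    present = {
        c: v for c, v in stratified.items() if len(v) >= _MIN_PER_CATEGORY
    }
    if len(present) < 2:
        raise DataError(
            f"need at least 2 categories with >= {_MIN_PER_CATEGORY} values"
        )
    bounds = bounds or default_bounds(present)
    cuts = []
    for i, (lower_cat, upper_cat) in enumerate(zip(_ORDER, _ORDER[1:])):
        cut = None
        if lower_cat in present and upper_cat in present:
            cut = _valley_cut(present[lower_cat], present[upper_cat])
        if cut is None and lower_cat is Category.SLEEP and upper_cat in present:
            # no sleep data: place the floor below the observed awake values
            cut = 0.5 * float(np.percentile(present[upper_cat], 5))
            cuts.append(max(cut, 1e-12))
            continue
        if cut is None:
            cut = (bounds[i][0] + bounds[i][1]) / 2.0
            warnings.warn(
                f"no separable densities for {lower_cat.name}/{upper_cat.name}; "
                f"initializing cut at the bound midpoint {cut:.4g}",
                stacklevel=2,
            )
        cuts.append(float(np.clip(cut, bounds[i][0], bounds[i][1])))
    cuts = _enforce_ordering(np.array(cuts))
    return ThresholdSet(measure_name, sample_rate_hz, *cuts)


def _enforce_ordering(cuts: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    out = cuts.copy()
    out[0] = max(out[0], eps)
    for i in range(1, len(out)):
        out[i] = max(out[i], out[i - 1] * (1 + 1e-9) + eps)
    return out


def _pa_level_accuracy(values: np.ndarray, y4: np.ndarray, cuts: np.ndarray) -> float:
    """Pooled accuracy of the 3-cut partition over the four awake levels."""
    pred = (
        (values > cuts[0]).astype(np.int8)
        + (values > cuts[1])
        + (values > cuts[2])
    )
    return float(np.mean(pred == y4))


def optimize_thresholds(
    epochs: EpochSeries,
    labels: LabelSeries,
    spec: OptimizerSpec | None = None,
) -> tuple[ThresholdSet, float]:
    """Accuracy-maximizing cut refinement; returns ``(thresholds, accuracy)``.

    Only worn, awake minutes with one of the four activity levels enter the
    objective; the achieved accuracy is never below the initialization's.
    """
    spec = spec or OptimizerSpec()
    check_same_grid(epochs, labels, what="epochs and labels")
    values = epochs.values
    y = labels.category
    keep = np.isfinite(values) & np.isin(y, [int(c) for c in PA_LEVELS])
    v = values[keep]
    y4 = (y[keep] - 1).astype(np.int8)  # sedentary..vigorous -> 0..3
    present_levels = np.unique(y4)
    if len(present_levels) < 2:
        raise DataError(
            "threshold optimization needs at least 2 activity levels in the labels"
        )

    stratified = _stratify(values, y)
    if spec.init == "auto":
        init = init_thresholds(
            stratified,
            epochs.measure_name,
            epochs.sample_rate_hz or 10.0,
            bounds=spec.bounds,
        )
    else:
        init = spec.init
    bounds = spec.bounds or default_bounds(stratified)
    pa_bounds = bounds[1:]  # the three awake-level cuts

    cuts = _enforce_ordering(
        np.clip(
            np.array([init.sed_light, init.light_mod, init.mod_vig]),
            [b[0] for b in pa_bounds],
            [b[1] for b in pa_bounds],
        )
    )
    best = _pa_level_accuracy(v, y4, cuts)
    init_accuracy = best
    evaluations = 0
    order = np.argsort(v, kind="stable")
    v_sorted = v[order]

    improved = True
    while improved and evaluations < spec.max_evaluations:
        improved = False
        for j in range(3):
            lo = max(pa_bounds[j][0], cuts[j - 1] if j > 0 else -np.inf)
            hi = min(pa_bounds[j][1], cuts[j + 1] if j < 2 else np.inf)
            cands = _candidate_cuts(v_sorted, lo, hi, spec.max_candidates)
            if len(cands) == 0:
                continue
            others = [(k, cuts[k]) for k in range(3) if k != j]
            base = np.zeros(len(v), dtype=np.int8)
            for _, c in others:
                base += v > c
            # accuracy for every candidate at once
            pred = base[None, :] + (v[None, :] > cands[:, None])
            acc = np.mean(pred == y4[None, :], axis=1)
            evaluations += len(cands)
            k = int(np.argmax(acc))  # first max -> smallest cut on ties
            if acc[k] > best + spec.tolerance or (
                acc[k] >= best and cands[k] < cuts[j]
            ):
                if acc[k] > best + spec.tolerance:
                    improved = True
                cuts[j] = cands[k]
                best = max(best, float(acc[k]))

    cuts = _enforce_ordering(cuts)
    floor = min(init.sleep_floor, cuts[0] * 0.5)
    result = ThresholdSet(
        epochs.measure_name,
        epochs.sample_rate_hz or init.sample_rate_hz,
        max(floor, 1e-12),
        *cuts,
    )
    achieved = _pa_level_accuracy(v, y4, cuts)
    if achieved + 1e-12 < init_accuracy:  # pragma: no cover - by construction
        raise AssertionError("optimizer lost accuracy relative to initialization")
    return result, achieved


def _candidate_cuts(v_sorted: np.ndarray, lo: float, hi: float, cap: int) -> np.ndarray:
    """Midpoints of adjacent distinct sorted values inside (lo, hi)."""
    i0, i1 = np.searchsorted(v_sorted, [lo, hi])
    window = np.unique(v_sorted[max(i0 - 1, 0) : i1 + 1])
    if len(window) < 2:
        return np.empty(0)
    mids = (window[:-1] + window[1:]) / 2.0
    mids = mids[(mids > lo) & (mids < hi)]
    if len(mids) > cap:
        idx = np.linspace(0, len(mids) - 1, cap).round().astype(int)
        mids = mids[np.unique(idx)]
    return mids


@dataclass
class LopoResult:
    """Leave-one-participant-out outputs."""

    fold_thresholds: list[ThresholdSet]
    fold_matrices: list[ConfusionMatrix]
    pooled: ConfusionMatrix
    per_participant_accuracy: np.ndarray
    mean_accuracy: float

    @property
    def pooled_accuracy(self) -> float:
        return self.pooled.accuracy


def lopo_run(cohort, spec: OptimizerSpec | None = None) -> LopoResult:
    """Optimize on N-1 participants, evaluate on the held-out one, N times.

    ``cohort`` is a list of ``(EpochSeries, LabelSeries)`` pairs. Each fold's
    test minutes are classified with the fold's thresholds over the full
    five categories (values at or below the sleep floor count as sleep);
    fold matrices are element-wise summed into the pooled matrix.
    """
    spec = spec or OptimizerSpec()
    if len(cohort) < 2:
        raise ConfigurationError("leave-one-participant-out needs >= 2 participants")
    fold_thresholds: list[ThresholdSet] = []
    fold_matrices: list[ConfusionMatrix] = []
    for i, (test_epochs, test_labels) in enumerate(cohort):
        train_values = np.concatenate(
            [e.values for j, (e, _) in enumerate(cohort) if j != i]
        )
        train_labels = np.concatenate(
            [l.category for j, (_, l) in enumerate(cohort) if j != i]
        )
        grid = 60.0 * np.arange(len(train_values))
        train_ep = EpochSeries(
            grid, np.where(np.isfinite(train_values), train_values, np.nan),
            test_epochs.measure_name, test_epochs.sample_rate_hz,
        )
        train_lab = LabelSeries(grid, train_labels)
        thresholds, _ = optimize_thresholds(train_ep, train_lab, spec)
        fold_thresholds.append(thresholds)

        est = band_labels(test_epochs.values, thresholds)
        est_series = LabelSeries(test_epochs.epoch_start, est)
        fold_matrices.append(confusion(test_labels, est_series))
    summary = per_participant_summary(fold_matrices)
    return LopoResult(
        fold_thresholds=fold_thresholds,
        fold_matrices=fold_matrices,
        pooled=summary["pooled"],
        per_participant_accuracy=summary["per_participant_accuracy"],
        mean_accuracy=summary["mean_accuracy"],
    )


class ThresholdModel:
    """Cut-point model for one summary measure, fitted to labeled epochs.

    A thin fit/results interface over :func:`optimize_thresholds`::

        res = ThresholdModel(epochs, labels).fit()
        print(res.summary())
        labels_hat = res.predict(new_epochs)
    """

    def __init__(self, epochs: EpochSeries, labels: LabelSeries):
        check_same_grid(epochs, labels, what="epochs and labels")
        self.epochs = epochs
        self.labels = labels

    @classmethod
    def from_dataframe(
        cls, frame, measure_name: str, sample_rate_hz: float | None = None
    ) -> "ThresholdModel":
        """Build from a DataFrame with columns ``time``, the measure, ``label``
        (category codes or names)."""
        from .core import CATEGORY_NAMES

        t = frame["time"].to_numpy(dtype=float)
        values = frame[measure_name].to_numpy(dtype=float)
        raw = frame["label"]
        if raw.dtype == object:
            codes = np.array([int(CATEGORY_NAMES[str(s).strip().lower()]) for s in raw])
        else:
            codes = raw.to_numpy(dtype=int)
        return cls(
            EpochSeries(t, values, measure_name, sample_rate_hz),
            LabelSeries(t, codes),
        )

    def fit(self, spec: OptimizerSpec | None = None) -> "ThresholdResults":
        spec = spec or OptimizerSpec()
        thresholds, accuracy = optimize_thresholds(self.epochs, self.labels, spec)
        return ThresholdResults(self, thresholds, accuracy, spec)


class ThresholdResults:
    """Fitted cut-points, their training accuracy and a summary table."""

    def __init__(
        self,
        model: ThresholdModel,
        thresholds: ThresholdSet,
        accuracy: float,
        spec: OptimizerSpec,
    ):
        self.model = model
        self.thresholds = thresholds
        self.accuracy = accuracy
        self.spec = spec

    def predict(self, epochs: EpochSeries | None = None) -> LabelSeries:
        epochs = epochs if epochs is not None else self.model.epochs
        return LabelSeries(epochs.epoch_start, band_labels(epochs.values, self.thresholds))

    def confusion(self) -> ConfusionMatrix:
        return confusion(self.model.labels, self.predict())

    def summary(self) -> str:
        t = self.thresholds
        n = int(
            np.sum(
                np.isfinite(self.model.epochs.values)
                & np.isin(self.model.labels.category, [int(c) for c in PA_LEVELS])
            )
        )
        lines = [
            "Activity threshold model",
            "=" * 46,
            f"measure:            {t.measure_name}",
            f"sample rate:        {t.sample_rate_hz:g} Hz",
            f"training minutes:   {n}",
            f"training accuracy:  {self.accuracy:.4f} (4 awake levels)",
            "-" * 46,
            f"sleep floor:        x <= {t.sleep_floor:.4g}",
            f"sedentary:          {t.sleep_floor:.4g} < x <= {t.sed_light:.4g}",
            f"light:              {t.sed_light:.4g} < x <= {t.light_mod:.4g}",
            f"moderate:           {t.light_mod:.4g} < x <= {t.mod_vig:.4g}",
            f"vigorous:           x > {t.mod_vig:.4g}",
            "=" * 46,
        ]
        return "\n".join(lines)
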