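"""Random-forest fusion of the four per-measure category estimates.

Each summary measure's threshold classifier produces its own per-minute
category estimate; the four estimates disagree in characteristic ways
(e.g. the rate-of-change measure resolves sleep and vigorous activity best
while norm-based measures can resolve light activity better). A random
forest of 500 trees combines them, choosing the split feature from a
random subset of floor(sqrt(d)) features per node. Three input modes:

* ``estimates`` (default) — the four categorical estimates, one-of-k
  encoded (5 categories x 4 measures = 20 columns);
* ``measures`` — the four raw epoch values (4 columns);
* ``both`` — the concatenation (24 columns).

The forest only re-labels worn, awake minutes; sleep and non-wear pass
through the mask precedence unchanged (see
:func:`combine_with_masks`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .core import (
    AlignmentError,
    Category,
    ConfigurationError,
    DataError,
    EpochSeries,
    LabelSeries,
    MEASURES,
    check_same_grid,
)

__all__ = [
    "RFConfig",
    "FittedCombiner",
    "fit_combiner",
    "predict_combiner",
    "combine_with_masks",
    "lopo_combine",
]

_ESTIMATE_CATEGORIES = 5  # sleep..vigorous one-of-k positions per measure


@dataclass
class RFConfig:
    n_trees: int = 500
    seed: int = 0
    input_mode: str = "estimates"  # estimates | measures | both
    class_weight: str | None = None  # optional "balanced"; default off

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.input_mode not in ("estimates", "measures", "both"):
            raise ConfigurationError(
                "input_mode must be 'estimates', 'measures' or 'both'"
            )


def _encode(
    mode: str,
    estimates: dict[str, LabelSeries] | None,
    measures: dict[str, EpochSeries] | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix plus a validity mask (rows with NaN/unknown are invalid)."""
    blocks = []
    valid = None
    grid = None

    def _and(mask):
        nonlocal valid
        valid = mask if valid is None else (valid & mask)

    if mode in ("estimates", "both"):
        if not estimates:
            raise ConfigurationError(f"input_mode {mode!r} requires category estimates")
        for name in MEASURES:
            if name not in estimates:
                raise ConfigurationError(f"missing estimate series for {name!r}")
            series = estimates[name]
            grid = series.epoch_start if grid is None else check_same_grid(
                grid, series, what="combiner inputs"
            )
            codes = series.category
            onehot = np.zeros((len(codes), _ESTIMATE_CATEGORIES))
            ok = codes >= 0
            onehot[np.arange(len(codes))[ok], codes[ok]] = 1.0
            blocks.append(onehot)
            _and(ok)
    if mode in ("measures", "both"):
        if not measures:
            raise ConfigurationError(f"input_mode {mode!r} requires raw measure values")
        for name in MEASURES:
            if name not in measures:
                raise ConfigurationError(f"missing measure series for {name!r}")
            series = measures[name]
            grid = series.epoch_start if grid is None else check_same_grid(
                grid, series, what="combiner inputs"
            )
            blocks.append(series.values[:, None])
            _and(np.isfinite(series.values))
    X = np.hstack(blocks)
    return X, valid


@dataclass
class FittedCombiner:
    forest: RandomForestClassifier
    config: RFConfig
    n_features: int

    @property
    def features_per_split(self) -> int:
        return int(np.sqrt(self.n_features))


def fit_combiner(
    labels: LabelSeries,
    config: RFConfig | None = None,
    estimates: dict[str, LabelSeries] | None = None,
    measures: dict[str, EpochSeries] | None = None,
) -> FittedCombiner:
    """Train the forest on worn, awake-or-asleep labeled minutes.

    Deterministic given ``config.seed``. Raises ``DataError`` when fewer
    than two classes are present after exclusions.
    """
    config = config or RFConfig()
    X, valid = _encode(config.input_mode, estimates, measures)
    if len(X) != len(labels):
        raise AlignmentError("combiner inputs and labels differ in length")
    keep = valid & (labels.category >= 0)
    y = labels.category[keep]
    if len(np.unique(y)) < 2:
        raise DataError("combiner training needs at least 2 label classes")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features="sqrt",
        random_state=config.seed,
        class_weight=config.class_weight,
        n_jobs=1,
    )
    forest.fit(X[keep], y)
    return FittedCombiner(forest=forest, config=config, n_features=X.shape[1])


def predict_combiner(
    fitted: FittedCombiner,
    estimates: dict[str, LabelSeries] | None = None,
    measures: dict[str, EpochSeries] | None = None,
) -> LabelSeries:
    """One category per minute; inputs must match the fitted input mode."""
    mode = fitted.config.input_mode
    if mode in ("estimates", "both") and not estimates:
        raise ConfigurationError(f"combiner was fitted in {mode!r} mode: estimates required")
    if mode in ("measures", "both") and not measures:
        raise ConfigurationError(f"combiner was fitted in {mode!r} mode: measures required")
    if mode == "estimates" and estimates is None and measures is not None:
        raise ConfigurationError("combiner was fitted on estimates, got measures")
    X, valid = _encode(mode, estimates, measures)
    if X.shape[1] != fitted.n_features:
        raise ConfigurationError(
            f"expected {fitted.n_features} encoded features, got {X.shape[1]}"
        )
    grid = next(iter((estimates or measures).values())).epoch_start
    codes = np.full(len(X), int(Category.UNKNOWN))
    if valid.any():
        codes[valid] = fitted.forest.predict(X[valid])
    return LabelSeries(epoch_start=grid, category=codes)


def combine_with_masks(
    fitted: FittedCombiner,
    sleep_mask: np.ndarray | None = None,
    nonwear_mask: np.ndarray | None = None,
    estimates: dict[str, LabelSeries] | None = None,
    measures: dict[str, EpochSeries] | None = None,
) -> LabelSeries:
    """Forest prediction with sleep/non-wear precedence re-applied.

    The forest only re-labels worn, awake minutes; masked minutes keep
    their segmentation label.
    """
    out = predict_combiner(fitted, estimates=estimates, measures=measures)
    codes = out.category.copy()
    if sleep_mask is not None:
        codes[np.asarray(sleep_mask, dtype=bool)] = int(Category.SLEEP)
    if nonwear_mask is not None:
        codes[np.asarray(nonwear_mask, dtype=bool)] = int(Category.NONWEAR)
    return LabelSeries(epoch_start=out.epoch_start, category=codes)


def lopo_combine(cohort, optimizer_spec=None, config: RFConfig | None = None):
    """Leave-one-participant-out fusion of the four per-measure estimates.

    ``cohort`` is a list of ``(epoch_tables, labels)`` pairs, where
    ``epoch_tables`` maps each measure name to its :class:`EpochSeries`.
    Within each fold, per-measure thresholds are optimized on the training
    participants, the threshold estimates are computed for train and test
    minutes, a forest is trained on the training estimates, and the
    held-out participant is predicted. Returns a dict with the combined
    pooled :class:`~wristpa.evaluation.ConfusionMatrix` (key ``"combined"``)
    and each measure's single-threshold pooled matrix for comparison.
    """
    from .evaluation import confusion
    from .pa_classifier import band_labels
    from .threshold_optimizer import OptimizerSpec, optimize_thresholds

    config = config or RFConfig()
    optimizer_spec = optimizer_spec or OptimizerSpec()
    if len(cohort) < 2:
        raise ConfigurationError("fold-wise fusion needs >= 2 participants")

    per_measure_folds: dict[str, list] = {m: [] for m in MEASURES}
    combined_folds = []
    for i, (test_tables, test_labels) in enumerate(cohort):
        train = [c for j, c in enumerate(cohort) if j != i]
        fold_thresholds = {}
        for m in MEASURES:
            values = np.concatenate([t[m].values for t, _ in train])
            codes = np.concatenate([l.category for _, l in train])
            grid = 60.0 * np.arange(len(values))
            ep = EpochSeries(grid, values, m, test_tables[m].sample_rate_hz)
            la = LabelSeries(grid, codes)
            fold_thresholds[m], _ = optimize_thresholds(ep, la, optimizer_spec)

        def _estimates(tables):
            return {
                m: LabelSeries(
                    tables[m].epoch_start,
                    band_labels(tables[m].values, fold_thresholds[m]),
                )
                for m in MEASURES
            }

        train_grid = 60.0 * np.arange(sum(len(l) for _, l in train))
        train_tables = {
            m: EpochSeries(
                train_grid,
                np.concatenate([t[m].values for t, _ in train]),
                m,
                test_tables[m].sample_rate_hz,
            )
            for m in MEASURES
        }
        train_labels = LabelSeries(
            train_grid, np.concatenate([l.category for _, l in train])
        )
        fitted = fit_combiner(
            train_labels,
            config,
            estimates=_estimates(train_tables),
            measures=train_tables if config.input_mode != "estimates" else None,
        )
        test_estimates = _estimates(test_tables)
        predicted = predict_combiner(
            fitted,
            estimates=test_estimates,
            measures=test_tables if config.input_mode != "estimates" else None,
        )
        combined_folds.append(confusion(test_labels, predicted))
        for m in MEASURES:
            per_measure_folds[m].append(confusion(test_labels, test_estimates[m]))

    def _pool(folds):
        pooled = folds[0]
        for f in folds[1:]:
            pooled = pooled + f
        return pooled

    out = {m: _pool(per_measure_folds[m]) for m in MEASURES}
    out["combined"] = _pool(combined_folds)
    return out
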