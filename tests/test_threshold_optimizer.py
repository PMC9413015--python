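import numpy as np
import pytest

from wristpa.core import (
    Category,
    ConfigurationError,
    DataError,
    EpochSeries,
    LabelSeries,
)
from wristpa.threshold_optimizer import (
    OptimizerSpec,
    ThresholdModel,
    init_thresholds,
    kde_diffusion,
    lopo_run,
    optimize_thresholds,
)


def labeled_epochs(values, codes, measure="rocam", rate=10.0):
    grid = 60.0 * np.arange(len(values))
    return (
        EpochSeries(grid, np.asarray(values, dtype=float), measure, rate),
        LabelSeries(grid, np.asarray(codes, dtype=int)),
    )


def gaussian_classes(means, sd, n, seed=0):
    rng = np.random.default_rng(seed)
    values = np.concatenate([np.abs(rng.normal(m, sd, n)) for m in means])
    codes = np.repeat(np.arange(1, len(means) + 1), n)
    return labeled_epochs(values, codes)


class TestKdeDiffusion:
    def test_normal_sample_normalized_and_centered(self):
        x = np.random.default_rng(1).normal(size=10_000)
        grid, density, bandwidth = kde_diffusion(x)
        assert np.trapezoid(density, grid) == pytest.approx(1.0, abs=1e-3)
        assert abs(grid[np.argmax(density)]) < 0.1
        assert 0.0 < bandwidth < 1.0

    def test_bimodal_valley_resolved(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 5000), rng.normal(10, 1, 5000)])
        grid, density, _ = kde_diffusion(x)
        inner = (grid > 2) & (grid < 8)
        assert density[inner].min() < 0.2 * density.max()

    def test_constant_sample_rejected(self):
        with pytest.raises(DataError):
            kde_diffusion(np.full(100, 3.0))

    def test_too_few_values_rejected(self):
        with pytest.raises(DataError):
            kde_diffusion(np.arange(10, dtype=float))


class TestInitThresholds:
    def test_two_separated_gaussians(self):
        rng = np.random.default_rng(3)
        strat = {
            Category.SEDENTARY: rng.normal(0, 1, 2000),
            Category.LIGHT: rng.normal(10, 1, 2000),
        }
        t = init_thresholds(strat, "rocam", 10.0)
        assert t.sed_light == pytest.approx(5.0, abs=0.5)

    def test_three_gaussians_give_increasing_cuts(self):
        rng = np.random.default_rng(4)
        strat = {
            Category.SEDENTARY: rng.normal(0, 1, 2000),
            Category.LIGHT: rng.normal(5, 1, 2000),
            Category.MODERATE: rng.normal(10, 1, 2000),
        }
        t = init_thresholds(strat, "rocam", 10.0)
        assert t.sed_light == pytest.approx(2.5, abs=0.5)
        assert t.light_mod == pytest.approx(7.5, abs=0.5)
        assert t.sed_light < t.light_mod

    def test_identical_distributions_fall_back_with_warning(self):
        rng = np.random.default_rng(5)
        same = rng.normal(5, 1, 2000)
        strat = {Category.SEDENTARY: same, Category.LIGHT: same.copy()}
        with pytest.warns(UserWarning, match="bound midpoint"):
            t = init_thresholds(strat, "rocam", 10.0)
        assert t.sed_light > 0

    def test_missing_categories_rejected(self):
        with pytest.raises(DataError):
            init_thresholds({Category.SEDENTARY: np.arange(100.0)})


class TestOptimize:
    def test_recovers_bayes_boundaries(self):
        epochs, labels = gaussian_classes([0.1, 0.25, 0.45, 0.6], 0.05, 5000)
        thresholds, accuracy = optimize_thresholds(epochs, labels)
        for got, want in zip(
            (thresholds.sed_light, thresholds.light_mod, thresholds.mod_vig),
            (0.175, 0.35, 0.525),
        ):
            assert got == pytest.approx(want, rel=0.05)
        assert 0.8 < accuracy <= 1.0

    def test_accuracy_never_below_initialization(self):
        epochs, labels = gaussian_classes([0.1, 0.3], 0.04, 2000, seed=6)
        init = init_thresholds(
            {Category.SEDENTARY: epochs.values[:2000], Category.LIGHT: epochs.values[2000:]},
            "rocam",
            10.0,
        )
        spec = OptimizerSpec(init=init)
        _, accuracy = optimize_thresholds(epochs, labels, spec)
        pred_init = 1 + (epochs.values > init.sed_light) + (
            epochs.values > init.light_mod
        ) + (epochs.values > init.mod_vig)
        init_acc = np.mean(pred_init == labels.category)
        assert accuracy >= init_acc - 1e-12

    def test_separable_data_reaches_perfect_accuracy(self):
        values = np.concatenate([np.linspace(0.1, 0.2, 100), np.linspace(0.5, 0.6, 100)])
        codes = np.repeat([1, 2], 100)
        epochs, labels = labeled_epochs(values, codes)
        _, accuracy = optimize_thresholds(epochs, labels)
        assert accuracy == 1.0

    def test_single_class_labels_rejected(self):
        epochs, labels = labeled_epochs(np.linspace(0.1, 0.5, 100), np.full(100, 2))
        with pytest.raises(DataError):
            optimize_thresholds(epochs, labels)

    def test_result_respects_ordering(self):
        epochs, labels = gaussian_classes([0.1, 0.25, 0.45, 0.6], 0.08, 1000, seed=7)
        t, _ = optimize_thresholds(epochs, labels)
        assert t.sleep_floor < t.sed_light < t.light_mod < t.mod_vig


class TestLopo:
    def test_conservation_and_fold_count(self, cohort_epochs):
        cohort = [(tables["rocam"], labels) for tables, labels in cohort_epochs]
        result = lopo_run(cohort)
        assert len(result.fold_thresholds) == 3
        labeled = sum(int(np.sum(l.category >= 0)) for _, l in cohort)
        assert result.pooled.total == labeled
        assert result.pooled.total == sum(m.total for m in result.fold_matrices)

    def test_identical_participants_give_near_identical_thresholds(self):
        epochs, labels = gaussian_classes([0.1, 0.3, 0.5], 0.04, 400, seed=8)
        cohort = [(epochs, labels)] * 3
        result = lopo_run(cohort)
        cuts = np.array(
            [(t.sed_light, t.light_mod, t.mod_vig) for t in result.fold_thresholds]
        )
        assert np.ptp(cuts, axis=0).max() < 1e-9  # identical training sets

    def test_fewer_than_two_participants_rejected(self):
        epochs, labels = gaussian_classes([0.1, 0.3], 0.05, 100)
        with pytest.raises(ConfigurationError):
            lopo_run([(epochs, labels)])


class TestModelInterface:
    def test_fit_summary_and_predict(self):
        epochs, labels = gaussian_classes([0.1, 0.3, 0.5], 0.04, 500, seed=9)
        res = ThresholdModel(epochs, labels).fit()
        text = res.summary()
        assert "rocam" in text and "training accuracy" in text
        predicted = res.predict()
        assert len(predicted) == len(labels)
        assert res.confusion().accuracy == pytest.approx(res.accuracy, abs=0.05)

    def test_from_dataframe(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "time": 60.0 * np.arange(200),
                "rocam": np.concatenate(
                    [np.linspace(0.1, 0.15, 100), np.linspace(0.3, 0.4, 100)]
                ),
                "label": ["sedentary"] * 100 + ["light"] * 100,
            }
        )
        res = ThresholdModel.from_dataframe(frame, "rocam", 10.0).fit()
        assert res.accuracy == 1.0
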