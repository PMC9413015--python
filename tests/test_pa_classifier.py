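import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wristpa.core import (
    AlignmentError,
    Category,
    ConfigurationError,
    EpochSeries,
)
from wristpa.pa_classifier import (
    ThresholdSet,
    band_labels,
    classify_all_measures,
    classify_epochs,
    default_thresholds,
    read_threshold_table,
    write_threshold_table,
)


def rocam_epochs(values, rate=10.0):
    values = np.asarray(values, dtype=float)
    return EpochSeries(60.0 * np.arange(len(values)), values, "rocam", rate)


class TestDefaults:
    @pytest.mark.parametrize(
        "measure, cuts",
        [
            ("rocam", (0.06, 0.175, 0.400, 0.483)),
            ("ai", (0.010, 5.308, 17.010, 23.628)),
            ("mad", (0.001, 0.059, 0.242, 0.38)),
        ],
    )
    def test_published_10hz_cutpoints(self, measure, cuts):
        t = default_thresholds(measure)
        assert (t.sleep_floor, t.sed_light, t.light_mod, t.mod_vig) == cuts
        assert t.sample_rate_hz == 10.0

    def test_enmonz_floor_is_effectively_zero(self):
        t = default_thresholds("enmonz")
        assert 0 < t.sleep_floor < 1e-6
        assert (t.sed_light, t.light_mod, t.mod_vig) == (0.032, 0.173, 0.382)

    def test_unknown_measure_rejected(self):
        with pytest.raises(ConfigurationError):
            default_thresholds("counts")

    def test_unordered_cutpoints_rejected(self):
        with pytest.raises(ConfigurationError):
            ThresholdSet("rocam", 10.0, 0.2, 0.1, 0.3, 0.4)


class TestClassify:
    def test_band_examples(self):
        labels = classify_epochs(
            rocam_epochs([0.30, 0.05, 0.483, 0.4831]), default_thresholds("rocam")
        )
        assert list(labels.category) == [
            int(Category.LIGHT),     # 0.175 < 0.30 <= 0.400
            int(Category.SLEEP),     # below the 0.06 floor
            int(Category.MODERATE),  # upper bounds inclusive
            int(Category.VIGOROUS),  # strictly above 0.483
        ]

    def test_mask_precedence(self):
        epochs = rocam_epochs([0.30, 0.30, 0.30])
        labels = classify_epochs(
            epochs,
            default_thresholds("rocam"),
            sleep_mask=np.array([False, True, True]),
            nonwear_mask=np.array([False, False, True]),
        )
        assert list(labels.category) == [
            int(Category.LIGHT),
            int(Category.SLEEP),
            int(Category.NONWEAR),
        ]

    def test_nan_epochs_become_unknown(self):
        labels = classify_epochs(
            rocam_epochs([0.1, np.nan]), default_thresholds("rocam")
        )
        assert labels.category[1] == int(Category.UNKNOWN)

    def test_rate_mismatch_warns(self):
        with pytest.warns(UserWarning, match="sample-rate specific"):
            classify_epochs(rocam_epochs([0.3], rate=25.0), default_thresholds("rocam"))

    def test_measure_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_epochs(rocam_epochs([0.3]), default_thresholds("mad"))

    def test_mask_grid_mismatch(self):
        with pytest.raises(AlignmentError):
            classify_epochs(
                rocam_epochs([0.3, 0.3]),
                default_thresholds("rocam"),
                sleep_mask=np.array([True]),
            )


class TestPartition:
    def test_dense_scan_gives_contiguous_bands(self):
        t = default_thresholds("rocam")
        grid = np.linspace(1e-6, 1.2 * t.mod_vig, 20000)
        codes = band_labels(grid, t)
        # exactly one category per value, monotone, all five present
        assert set(np.unique(codes)) == {0, 1, 2, 3, 4}
        assert np.all(np.diff(codes) >= 0)
        # four contiguous runs above the sleep floor
        above = codes[grid > t.sleep_floor]
        assert len(np.flatnonzero(np.diff(above))) == 3

    def test_boundary_semantics_exact(self):
        t = default_thresholds("rocam")
        for cut, below in [
            (t.sleep_floor, Category.SLEEP),
            (t.sed_light, Category.SEDENTARY),
            (t.light_mod, Category.LIGHT),
            (t.mod_vig, Category.MODERATE),
        ]:
            assert band_labels(np.array([cut]), t)[0] == int(below)
            assert band_labels(np.array([np.nextafter(cut, 1)]), t)[0] == int(below) + 1

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-9, max_value=10.0, allow_nan=False))
    def test_every_positive_value_maps_once(self, value):
        t = default_thresholds("rocam")
        code = band_labels(np.array([value]), t)[0]
        assert code in {0, 1, 2, 3, 4}

    def test_label_monotone_in_value(self):
        t = default_thresholds("rocam")
        rng = np.random.default_rng(5)
        v = np.sort(rng.uniform(0.001, 1.0, 500))
        codes = band_labels(v, t)
        assert np.all(np.diff(codes) >= 0)


class TestAllMeasures:
    def test_shared_masks_across_measures(self):
        grid = 60.0 * np.arange(3)
        tables = {
            "rocam": EpochSeries(grid, [0.3, 0.3, 0.3], "rocam", 10.0),
            "enmonz": EpochSeries(grid, [0.1, 0.1, 0.1], "enmonz", 10.0),
        }
        sleep = np.array([True, False, False])
        out = classify_all_measures(tables, sleep_mask=sleep)
        for labels in out.values():
            assert labels.category[0] == int(Category.SLEEP)

    def test_all_zero_epochs_are_sleep(self):
        tables = {"rocam": rocam_epochs([0.0, 0.0])}
        out = classify_all_measures(tables)
        assert np.all(out["rocam"].category == int(Category.SLEEP))


def test_threshold_table_round_trip(tmp_path):
    sets = [default_thresholds(m) for m in ("enmonz", "mad", "ai", "rocam")]
    path = write_threshold_table(sets, tmp_path / "thresholds.csv")
    back = read_threshold_table(path)
    for t in sets:
        assert back[(t.measure_name, 10.0)] == t
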