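import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from conftest import make_record
from naive_oracles import naive_activity_index, naive_enmonz, naive_mad, naive_rocam
from wristpa.core import DataError, TriaxialRecord
from wristpa.resampling import resample_all
from wristpa.summary_measures import (
    MeasureConfig,
    activity_index,
    enmonz,
    epoch_aggregate,
    mad,
    rocam,
    summarize,
)


class TestEnmonz:
    @pytest.mark.parametrize(
        "sample, expected",
        [
            ((0.0, 0.0, 1.0), 0.0),  # unit gravity
            ((0.6, 0.8, 0.0), 0.0),  # 3-4-5 norm exactly 1
            ((2.0, 2.0, 1.0), 2.0),  # norm 3 minus 1
            ((0.0, 0.0, 0.2), 0.0),  # clamp of -0.8
        ],
    )
    def test_pointwise_values(self, sample, expected):
        x, y, z = sample
        rec = make_record([x, x], [y, y], [z, z])
        assert enmonz(rec) == pytest.approx([expected, expected], abs=1e-12)

    def test_bounded_by_norm_and_zero_below_unit(self, random_record):
        en = np.sqrt(
            random_record.x**2 + random_record.y**2 + random_record.z**2
        )
        v = enmonz(random_record)
        assert np.all(v <= en + 1e-12)
        assert np.all(v[en <= 1.0] == 0.0)


class TestMad:
    def test_constant_record_is_zero(self):
        rec = make_record(np.full(600, 0.3), np.full(600, 0.4), np.zeros(600))
        _, v = mad(rec)
        assert v == pytest.approx([0.0], abs=1e-15)

    @pytest.mark.parametrize(
        "norms, expected",
        [
            ([1.2, 0.8, 1.2, 0.8], 0.2),  # mean 1.0, deviations all 0.2
            ([1.0, 1.0, 1.0, 2.0], 0.375),  # mean 1.25, deviations 3x0.25 + 0.75
        ],
    )
    def test_hand_worked_windows(self, norms, expected):
        rec = make_record(norms, fs=4.0)
        _, v = mad(rec, MeasureConfig(mad_window_seconds=1.0))
        assert v[0] == pytest.approx(expected, abs=1e-12)

    def test_window_longer_than_record_raises(self):
        rec = make_record(np.ones(20), fs=10.0)
        with pytest.raises(DataError):
            mad(rec, MeasureConfig(mad_window_seconds=60.0))


class TestActivityIndex:
    def test_constant_axes_zero(self):
        rec = make_record(np.full(40, 0.5), np.full(40, -0.5), np.ones(40), fs=4.0)
        _, v = activity_index(rec)
        assert np.all(v == 0.0)

    def test_alternating_unit_axis_is_one_third(self):
        x = np.tile([1.0, -1.0], 20)
        rec = make_record(x, fs=4.0)
        _, v = activity_index(rec)
        # population variance of +-1 is 1; averaged over three axes -> 1/3
        assert v == pytest.approx(np.full(10, 1 / 3), abs=1e-12)

    def test_noise_variance_clamps_to_zero(self):
        x = np.tile([0.01, -0.01], 20)
        rec = make_record(x, fs=4.0)
        _, v = activity_index(rec, MeasureConfig(ai_noise_variance=1.0))
        assert np.all(v == 0.0)


class TestRocam:
    def test_constant_record_zero(self):
        rec = make_record(np.full(100, 0.7), np.full(100, 0.1), np.ones(100))
        assert np.all(rocam(rec) == 0.0)

    def test_linear_ramp_constant_rate(self):
        # slope 0.01 g/sample -> all successive differences 0.01
        rec = make_record(0.01 * np.arange(200), z=np.ones(200))
        v = rocam(rec)
        assert v[10:-10] == pytest.approx(np.full(180, 0.01), abs=1e-12)

    def test_single_spike_removed_by_median(self):
        x = np.zeros(100)
        x[50] = 1.0
        rec = make_record(x, z=np.ones(100))
        v = rocam(rec)
        # only 2 of the 10 window values are nonzero at the spike
        assert v[50] == 0.0

    def test_matches_naive_loop(self, random_record):
        got = rocam(random_record)
        want = naive_rocam(
            random_record.x, random_record.y, random_record.z, 10
        )
        np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-14)


class TestEpochAggregate:
    def test_mean_of_constant_rocam(self):
        rec = make_record(np.zeros(1200), z=np.ones(1200))
        ep = epoch_aggregate(rec.timestamps, np.full(1200, 0.2), "rocam", 600, 10.0)
        assert ep.values == pytest.approx([0.2, 0.2], abs=1e-12)

    def test_ai_epochs_are_sums(self):
        times = np.arange(120, dtype=float)  # 1-second grid
        ep = epoch_aggregate(times, np.full(120, 1 / 3), "ai", 60, 10.0)
        assert ep.values == pytest.approx([20.0, 20.0], abs=1e-9)

    def test_partial_epoch_marked_unknown(self):
        times = np.arange(90, dtype=float)  # 60 s full + 30 s partial
        ep = epoch_aggregate(times, np.ones(90), "rocam", 60, 1.0)
        assert len(ep) == 2
        assert ep.values[0] == pytest.approx(1.0)
        assert np.isnan(ep.values[1])

    def test_empty_series_raises(self):
        with pytest.raises(DataError):
            epoch_aggregate(np.empty(0), np.empty(0), "rocam", 600, 10.0)


class TestOracleEquivalence:
    def test_all_measures_match_naive_loops(self, random_record):
        x, y, z = random_record.x, random_record.y, random_record.z
        np.testing.assert_allclose(
            enmonz(random_record), naive_enmonz(x, y, z), rtol=1e-10, atol=1e-14
        )
        cfg = MeasureConfig(mad_window_seconds=60.0)
        np.testing.assert_allclose(
            mad(random_record, cfg)[1], naive_mad(x, y, z, 600), rtol=1e-10
        )
        np.testing.assert_allclose(
            activity_index(random_record)[1],
            naive_activity_index(x, y, z, 10),
            rtol=1e-10,
            atol=1e-14,
        )
        np.testing.assert_allclose(
            rocam(random_record), naive_rocam(x, y, z, 10), rtol=1e-10, atol=1e-14
        )


class TestInvariances:
    def test_rotation_invariance(self, random_record):
        rng = np.random.default_rng(7)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        xyz = random_record.xyz @ q.T
        rotated = TriaxialRecord(
            random_record.timestamps, xyz[:, 0], xyz[:, 1], xyz[:, 2], 10.0,
            dynamic_range_g=16.0,  # rotation can push single axes past 8 g
        )
        np.testing.assert_allclose(
            enmonz(rotated), enmonz(random_record), atol=1e-9
        )
        np.testing.assert_allclose(
            mad(rotated)[1], mad(random_record)[1], atol=1e-9
        )
        np.testing.assert_allclose(
            activity_index(rotated)[1], activity_index(random_record)[1], atol=1e-9
        )
        np.testing.assert_allclose(
            rocam(rotated), rocam(random_record), atol=1e-9
        )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        hnp.arrays(
            float,
            st.integers(min_value=20, max_value=60).map(lambda n: (n, 3)),
            elements=st.floats(-8, 8, allow_nan=False, width=32),
        )
    )
    def test_all_measures_non_negative(self, xyz):
        rec = TriaxialRecord(
            np.arange(len(xyz)) / 10.0, xyz[:, 0], xyz[:, 1], xyz[:, 2], 10.0
        )
        assert np.all(enmonz(rec) >= 0)
        assert np.all(rocam(rec) >= 0)
        _, ai = activity_index(rec)
        assert np.all(ai >= 0)
        _, mv = mad(rec, MeasureConfig(mad_window_seconds=1.0))
        assert np.all(mv >= 0)


def test_rocam_grows_as_rate_drops():
    """A fixed band-limited tone yields larger per-sample differences at
    lower rates, the basis for rate-specific thresholds."""
    fs = 100.0
    t = np.arange(int(fs * 300)) / fs
    x = 0.3 * np.sin(2 * np.pi * 2.0 * t)
    rec = TriaxialRecord(t, x, np.zeros_like(x), np.ones_like(x), fs)
    versions = resample_all(rec, [100, 50, 25, 10])
    means = []
    for rate in (100, 50, 25, 10):
        ep = summarize(versions[float(rate)])["rocam"]
        means.append(np.nanmean(ep.values[1:-1]))
    assert np.all(np.diff(means) > 0)
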