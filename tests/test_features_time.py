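"""Time-domain features: per-step statistics, regularity, trend, cross-axis."""

import numpy as np
import pytest

from _oracles import autocov_normalized
from gaitfall.errors import InvalidInputError
from gaitfall.features_time import (
    CROSS_AXIS_FEATURES,
    TIME_FEATURES,
    autocorr_regularity,
    autocov_at_lag,
    cross_axis_features,
    mean_trend,
    step_slices,
    time_features_axis,
)
from gaitfall.gait_events import StepSegmentation

FS = 100.0


def _seg(peaks, fs=FS):
    peaks = np.asarray(peaks)
    durations = np.diff(peaks) / fs
    n_pairs = len(durations) // 2
    return StepSegmentation(
        fs_hz=fs,
        peak_indices=peaks,
        step_durations_s=durations,
        stride_durations_s=durations[: 2 * n_pairs].reshape(n_pairs, 2).sum(axis=1),
        cadence_spm=60.0 / float(np.mean(durations)),
        accepted_intervals=np.arange(len(durations)),
    )


class TestStepSlices:
    def test_half_open_index_arithmetic(self):
        x = np.arange(250, dtype=float)
        sl = step_slices(x, _seg([0, 100, 200]))
        assert [len(s) for s in sl.slices] == [100, 100]
        np.testing.assert_array_equal(sl.slices[0], x[0:100])
        np.testing.assert_array_equal(sl.slices[1], x[100:200])

    def test_odd_slice_halves(self):
        x = np.arange(10, dtype=float)
        sl = step_slices(x, _seg([0, 5], fs=10.0))
        assert len(sl.first_halves[0]) == 3 and len(sl.last_halves[0]) == 2
        np.testing.assert_array_equal(
            np.concatenate([sl.first_halves[0], sl.last_halves[0]]), sl.slices[0]
        )

    def test_slices_partition_span(self):
        x = np.random.default_rng(0).normal(size=300)
        sl = step_slices(x, _seg([0, 70, 140, 210]))
        np.testing.assert_array_equal(np.concatenate(sl.slices), x[0:210])


class TestRegularity:
    def test_sinusoid_at_period_lag(self):
        t = np.arange(6000) / FS
        x = np.sin(2 * np.pi * 2.0 * t)
        stp, strd = autocorr_regularity(x, FS, 0.5, 1.0)
        assert stp == pytest.approx(1.0, abs=0.02)
        assert strd == pytest.approx(1.0, abs=0.02)

    def test_sinusoid_antiphase_at_half_period(self):
        t = np.arange(6000) / FS
        x = np.sin(2 * np.pi * 2.0 * t)
        assert autocov_at_lag(x, 25) == pytest.approx(-1.0, abs=0.02)

    def test_matches_double_loop_oracle(self):
        x = np.random.default_rng(7).normal(size=400)
        for lag in (13, 50, 97):
            assert autocov_at_lag(x, lag) == pytest.approx(
                autocov_normalized(x, lag), abs=1e-10
            )

    def test_lag_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            autocorr_regularity(np.zeros(400), FS, 2.0, 4.0)  # > duration/4

    def test_white_noise_low_step_regularity(self):
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=6000)
            stp, _ = autocorr_regularity(x, FS, 0.5, 1.0)
            assert stp < 0.2


class TestMeanTrend:
    def test_stationary_sinusoid_near_zero(self):
        t = np.arange(6000) / FS
        x = np.sin(2 * np.pi * 2.0 * t)
        assert mean_trend(x, FS, _seg(np.arange(0, 6000, 50))) < 0.01

    def test_drift_increases_trend(self):
        t = np.arange(6000) / FS
        seg = _seg(np.arange(0, 6000, 50))
        base = np.sin(2 * np.pi * 2.0 * t)
        drifted = base + 0.2 * np.sin(2 * np.pi * 0.05 * t)
        assert mean_trend(drifted, FS, seg) > mean_trend(base, FS, seg)

    def test_zero_signal_zero_trend(self):
        assert mean_trend(np.zeros(6000), FS, _seg(np.arange(0, 6000, 50))) == 0.0


class TestTimeFeaturesAxis:
    def test_pure_periodic_regularity_near_one(self):
        # exactly periodic multi-harmonic waveform, period = 50 samples
        t = np.arange(6000) / FS
        x = np.cos(2 * np.pi * 2.0 * t) + 0.3 * np.cos(2 * np.pi * 4.0 * t + 0.4)
        seg = _seg(np.arange(0, 6000, 50))
        feats = time_features_axis(x / np.max(np.abs(x)), seg, FS)
        assert feats["StpReg"] == pytest.approx(1.0, abs=0.02)
        assert feats["StrReg"] == pytest.approx(1.0, abs=0.02)

    def test_registry_has_21_features(self, clean_pre, clean_seg):
        feats = time_features_axis(clean_pre.axis_analysis("ML"), clean_seg, FS)
        assert list(feats) == list(TIME_FEATURES)
        assert len(feats) == 21
        assert all(np.isfinite(v) for v in feats.values())

    def test_per_step_mean_matches_bruteforce(self, clean_pre, clean_seg):
        x = clean_pre.axis_analysis("AP")
        feats = time_features_axis(x, clean_seg, FS)
        slices = step_slices(x, clean_seg).slices
        assert feats["mean"] == pytest.approx(
            sum(float(np.mean(s)) for s in slices) / len(slices), abs=1e-12
        )
        assert feats["energy"] == pytest.approx(
            sum(float(np.sum(s**2) / len(s)) for s in slices) / len(slices), abs=1e-12
        )

    def test_stability_under_one_appended_sample(self, clean_pre, clean_seg):
        x = clean_pre.axis_analysis("V")
        a = time_features_axis(x, clean_seg, FS)
        b = time_features_axis(np.append(x, x[-1]), clean_seg, FS)
        for name in TIME_FEATURES:
            assert b[name] == pytest.approx(a[name], rel=0.01, abs=1e-6), name


class TestCrossAxis:
    def test_self_pairing(self):
        x = np.random.default_rng(3).normal(size=500)
        feats = cross_axis_features(x, x.copy(), x.copy())
        assert feats["corr_V_ML"] == pytest.approx(1.0)
        assert feats["cov_V_ML"] == pytest.approx(np.var(x, ddof=1))

    def test_antipodal_pairing(self):
        x = np.random.default_rng(4).normal(size=500)
        feats = cross_axis_features(x, -x, x.copy())
        assert feats["corr_V_ML"] == pytest.approx(-1.0)

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(9)
        v, ml, ap = rng.normal(size=(3, 300))
        feats = cross_axis_features(v, ml, ap)
        n = len(v)

        def corr(a, b):
            am, bm = a - a.mean(), b - b.mean()
            return float(np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2)))

        def cov(a, b):
            return float(np.sum((a - a.mean()) * (b - b.mean())) / (n - 1))

        assert feats["corr_V_AP"] == pytest.approx(corr(v, ap), abs=1e-12)
        assert feats["cov_AP_ML"] == pytest.approx(cov(ap, ml), abs=1e-12)
        assert list(feats) == list(CROSS_AXIS_FEATURES)

    def test_constant_axis_rejected(self):
        with pytest.raises(InvalidInputError):
            cross_axis_features(np.ones(100), np.random.default_rng(0).normal(size=100), np.zeros(100) + 2)
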