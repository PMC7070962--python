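import math

import numpy as np
import pytest

from drowsyhrv.ground_truth import IntervalLabel
from drowsyhrv.hrv_features import (
    FEATURE_NAMES,
    BandDefinition,
    WindowSpec,
    default_freq_grid,
    extract_labeled_features,
    feature_vector,
    frequency_features,
    label_windows,
    lomb_scargle_psd,
    poincare_features,
    segment_windows,
    time_features,
)

from conftest import make_series, random_rr_window
import oracles


class TestSegmentWindows:
    def test_45min_drive_gives_1201_starts(self):
        series = make_series([1000.0] * 2700)  # beats at 0..2700 s
        windows = segment_windows(series, WindowSpec(300.0, 2.0))
        assert len(windows) == 1201
        assert windows[0].start == 0.0 and windows[-1].start == 2400.0

    def test_exactly_one_window(self):
        series = make_series([1000.0] * 300)
        assert len(segment_windows(series)) == 1

    def test_too_short_recording_gives_none(self, caplog):
        series = make_series([1000.0] * 299)
        assert segment_windows(series) == []

    def test_window_contains_only_beats_in_half_open_span(self):
        series = make_series([1000.0] * 600)
        w = segment_windows(series, WindowSpec(300.0, 2.0))[1]  # start 2 s
        assert w.beat_times.min() >= 2.0
        assert w.beat_times.max() < 302.0

    def test_sparse_window_dropped(self):
        # 3 beats in the first 300 s, then normal beats
        t = np.concatenate([[0.0, 100.0, 200.0], np.arange(300.0, 601.0)])
        rr = np.diff(t) * 1000.0
        from drowsyhrv.iodata import IBISeries, ECG
        series = IBISeries("s", ECG, beat_times=t, intervals=rr)
        windows = segment_windows(series, WindowSpec(300.0, 300.0))
        assert [w.start for w in windows] == [300.0]

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(300.0, 301.0)
        with pytest.raises(ValueError):
            WindowSpec(0.0, 1.0)


class TestTimeFeatures:
    def test_constant_series(self):
        f = time_features([800.0, 800.0, 800.0])
        assert f["meanRR"] == 800.0 and f["SDNN"] == 0.0 and f["RMSSD"] == 0.0
        assert f["meanHR"] == 75.0 and f["NN50"] == 0

    def test_nn50_strict_inequality_at_50ms(self):
        f = time_features([800.0, 850.0])
        assert f["RMSSD"] == 50.0
        assert f["NN50"] == 0 and f["pNN50"] == 0.0  # 50 is not > 50
        assert time_features([800.0, 851.0])["NN50"] == 1

    def test_four_element_window_matches_oracle(self):
        rr = [700.0, 800.0, 650.0, 900.0]
        ours = time_features(rr)
        ref = oracles.time_features_oracle(rr)
        assert ours["meanRR"] == 762.5 and ours["rangeRR"] == 250.0
        for k, v in ref.items():
            assert ours[k] == pytest.approx(v, rel=1e-9), k

    def test_random_windows_match_oracle(self, rng):
        for _ in range(10):
            rr = random_rr_window(rng)
            ours = time_features(rr)
            for k, v in oracles.time_features_oracle(rr).items():
                assert ours[k] == pytest.approx(v, rel=1e-9), k

    def test_hr_duality_invariants(self, rng):
        rr = random_rr_window(rng)
        f = time_features(rr)
        assert f["maxHR"] * f["minRR"] == pytest.approx(60000.0, rel=1e-12)
        assert f["minHR"] * f["maxRR"] == pytest.approx(60000.0, rel=1e-12)
        assert f["rangeRR"] == pytest.approx(f["maxRR"] - f["minRR"], rel=1e-12)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            time_features([800.0])


class TestLombScarglePSD:
    def test_single_tone_peak_location(self):
        t = np.cumsum(np.full(300, 0.85))
        rr = 850.0 + 30.0 * np.sin(2 * np.pi * 0.1 * t)
        grid = default_freq_grid()
        psd = lomb_scargle_psd(t, rr, grid)
        assert grid[np.argmax(psd)] == pytest.approx(0.1, abs=0.002)

    def test_uniform_sampling_matches_classical_periodogram(self, rng):
        """On unit-spaced samples the Lomb-Scargle periodogram equals the
        DFT periodogram at Fourier frequencies (up to the common
        variance rescaling)."""
        n = 256
        y = rng.normal(0, 1, n)
        t = np.arange(n, dtype=float)
        k_max = 100
        grid = np.arange(1, k_max + 1) / n
        psd = lomb_scargle_psd(t, y, grid)
        ref = oracles.dft_periodogram(y - y.mean(), k_max)
        ratio = psd / ref
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-6)

    def test_constant_series_gives_zero_psd(self):
        t = np.arange(10, dtype=float)
        psd = lomb_scargle_psd(t, np.full(10, 800.0), default_freq_grid())
        assert np.all(psd == 0.0)

    def test_variance_recovery_normalization(self, rng):
        rr = random_rr_window(rng)
        t = np.cumsum(rr) / 1000.0
        grid = default_freq_grid()
        psd = lomb_scargle_psd(t, rr, grid)
        integral = np.trapezoid(psd, grid)
        assert integral == pytest.approx(np.var(rr, ddof=1), rel=0.10)


class TestFrequencyFeatures:
    @staticmethod
    def _tone_window(lf_amp, hf_amp, n=350, dt=0.85):
        t = np.cumsum(np.full(n, dt))
        rr = (850.0 + lf_amp * np.sin(2 * np.pi * 0.10 * t)
              + hf_amp * np.sin(2 * np.pi * 0.25 * t))
        return t, rr

    def test_equal_tones_give_unit_lf_hf_ratio(self):
        t, rr = self._tone_window(25.0, 25.0)
        f = frequency_features(t, rr)
        assert f["LFHF_ratio"] == pytest.approx(1.0, abs=0.1)

    def test_doubled_hf_amplitude_flips_ordering(self):
        t, rr = self._tone_window(25.0, 50.0)
        f = frequency_features(t, rr)
        assert f["LFHF_ratio"] < 1.0
        assert f["HFnorm"] > f["LFnorm"]

    def test_percentages_sum_to_100(self, rng):
        rr = random_rr_window(rng)
        t = np.cumsum(rr) / 1000.0
        f = frequency_features(t, rr)
        assert f["pVLF"] + f["pLF"] + f["pHF"] == pytest.approx(100.0, abs=1e-9)
        assert f["Totalpower"] == pytest.approx(
            f["VLF"] + f["LFpower"] + f["HFpower"], rel=1e-12)

    def test_band_powers_match_oracle(self, rng):
        bands = BandDefinition()
        grid = default_freq_grid()
        for _ in range(5):
            rr = random_rr_window(rng)
            t = np.cumsum(rr) / 1000.0
            ours = frequency_features(t, rr, bands, grid)
            ref = oracles.band_powers_oracle(
                t, rr, grid, {"VLF": bands.vlf, "LFpower": bands.lf, "HFpower": bands.hf})
            for k, v in ref.items():
                assert ours[k] == pytest.approx(v, rel=1e-6), k


class TestPoincare:
    def test_alternating_series_closed_form(self):
        rr = np.array([800.0, 900.0] * 25)
        f = poincare_features(rr)
        # successive differences are +-100 with one population mean quirk:
        drr = np.diff(rr)
        assert f["SD1"] == pytest.approx(math.sqrt(np.var(drr) / 2.0), rel=1e-12)
        assert f["SD1"] > f["SD2"]

    def test_constant_series_degenerate(self):
        f = poincare_features([800.0] * 10)
        assert f["SD1"] == 0.0 and f["SD2"] == 0.0
        assert math.isnan(f["SD1SD2_ratio"])

    def test_sd1_identity_on_random_series(self, rng):
        rr = 800.0 + rng.normal(0, 30, 50)
        f = poincare_features(rr)
        ref = oracles.poincare_oracle(rr)
        assert f["SD1"] == pytest.approx(
            math.sqrt(0.5) * np.std(np.diff(rr)), rel=1e-9)
        for k in ("SD1", "SD2", "SD1SD2_ratio"):
            assert f[k] == pytest.approx(ref[k], rel=1e-9)

    def test_sd2_population_identity(self, rng):
        rr = 800.0 + rng.normal(0, 30, 100)
        f = poincare_features(rr)
        assert f["SD2"] ** 2 + f["SD1"] ** 2 == pytest.approx(
            2.0 * np.var(rr), rel=1e-9)


class TestLabelWindows:
    def _window(self, start, n=300):
        from drowsyhrv.hrv_features import Window
        t = start + np.arange(n, dtype=float)
        return Window(start=start, beat_times=t, rr=np.diff(t) * 1000.0)

    def test_window_labeled_by_containing_interval(self):
        pairs = label_windows([self._window(0.0)],
                              [IntervalLabel("a", 0, 2)])
        assert pairs[0][1].level == 2

    def test_end_time_rule_crosses_boundary(self):
        # window [298, 598) ends at 598 s, inside interval 1
        pairs = label_windows([self._window(298.0)],
                              [IntervalLabel("a", 0, 2), IntervalLabel("a", 1, 4)])
        assert pairs[0][1].level == 4

    def test_unlabeled_interval_dropped(self):
        assert label_windows([self._window(400.0)],
                             [IntervalLabel("a", 0, 2)]) == []


class TestFullVector:
    def test_feature_count_and_order(self, rng):
        rr = random_rr_window(rng)
        from drowsyhrv.hrv_features import Window
        t = np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
        w = Window(0.0, t, rr)
        f = feature_vector(w)
        assert list(f.keys()) == FEATURE_NAMES
        assert len(f) == 26

    def test_extract_drops_undefined_windows(self):
        # constant RR: zero PSD -> undefined percentages -> dropped
        series = make_series([1000.0] * 400, subject="a")
        labels = [IntervalLabel("a", 0, 2), IntervalLabel("a", 1, 2)]
        table = extract_labeled_features(series, labels, WindowSpec(300.0, 100.0))
        assert table.empty

    def test_extract_shape_and_labels(self, small_cohort):
        from drowsyhrv.pipeline import bundle_labels
        b = small_cohort[0]
        table = extract_labeled_features(b.ecg, bundle_labels(b),
                                         WindowSpec(300.0, 300.0))
        assert list(table.columns[3:29]) == FEATURE_NAMES
        assert set(table["binary_class"]) <= {"non_drowsy", "drowsy"}
        assert (table["level"].between(1, 6)).all()
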