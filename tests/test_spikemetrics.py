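import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from periax.spikemetrics import (
    PatternLabel,
    SpikeTrain,
    autocorrelogram,
    classify_pattern,
    conduction_metrics,
    detect_spikes,
    isi_stats,
    remove_artifacts,
)


def train(times):
    return SpikeTrain("t", np.asarray(times, dtype=float))


class TestRemoveArtifacts:
    def _trace(self):
        t = np.arange(0.0, 1.0, 0.001)
        return t, np.zeros_like(t)

    def test_linear_segment_is_fixed_point(self):
        t = np.arange(0.0, 1.0, 0.001)
        y = 3.0 * t + 1.0
        out = remove_artifacts(y, t, np.array([0.4]), 20.0)
        assert np.allclose(out, y, atol=1e-12)

    def test_square_artifact_removed(self):
        t, y = self._trace()
        y[(t >= 0.41) & (t <= 0.415)] = 40.0
        out = remove_artifacts(y, t, np.array([0.405]), 15.0)
        assert np.all(np.abs(out[(t >= 0.40) & (t <= 0.425)]) < 1e-9)

    def test_outside_windows_untouched(self):
        t, y = self._trace()
        rng = np.random.default_rng(0)
        y += rng.normal(0, 1, y.size)
        out = remove_artifacts(y, t, np.array([0.2, 0.7]), 10.0)
        mask = ((t < 0.2) | (t > 0.211)) & ((t < 0.7) | (t > 0.711))
        assert np.array_equal(out[mask], y[mask])

    def test_overlap_merged_with_warning(self):
        t, y = self._trace()
        with pytest.warns(RuntimeWarning, match="merged"):
            remove_artifacts(y, t, np.array([0.3, 0.305]), 10.0)


class TestDetect:
    def test_flat_trace_empty(self):
        t = np.arange(0, 1, 0.001)
        assert len(detect_spikes(np.full(t.size, -65.0), t)) == 0

    def test_well_separated_waveforms_counted(self):
        t = np.arange(0, 1, 0.0005)
        y = np.full(t.size, -65.0)
        spikes = [0.1, 0.3, 0.55, 0.9]
        for s in spikes:
            i = int(s / 0.0005)
            y[i:i + 4] = 30.0
        st_ = detect_spikes(y, t)
        assert len(st_) == len(spikes)
        assert np.allclose(st_.times, spikes, atol=0.001)

    def test_refractory_merges_close_crossings(self):
        # crossings 1 ms apart with 2 ms refractory -> one spike (enumeration)
        t = np.arange(0, 0.01, 0.0001)
        y = np.full(t.size, -65.0)
        y[10:12] = 10.0
        y[20:22] = 10.0
        assert len(detect_spikes(y, t, refractory_ms=2.0)) == 1
        assert len(detect_spikes(y, t, refractory_ms=0.5)) == 2


class TestISIStats:
    def test_constant_train(self):
        s = isi_stats(train(np.arange(0, 1, 0.01)))
        assert s.cv == pytest.approx(0.0)
        assert s.bi == pytest.approx(1.0)

    def test_worked_example_5_5_5_100(self):
        # ISIs 5,5,5,100 ms: mode 5, mean 28.75, BI 5.75, CV 1.652 (sample SD)
        times = np.array([0.0, 5.0, 10.0, 15.0, 115.0]) / 1000.0
        s = isi_stats(train(times))
        assert s.mode_ms == pytest.approx(5.0)
        assert s.mean_ms == pytest.approx(28.75)
        assert s.bi == pytest.approx(5.75)
        assert s.cv == pytest.approx(1.652, abs=1e-3)

    def test_scale_invariance_of_cv(self):
        rng = np.random.default_rng(3)
        t = np.cumsum(rng.exponential(0.05, 200))
        s1 = isi_stats(train(t))
        s3 = isi_stats(train(3 * t), mode_bin_ms=3.0)
        assert s3.cv == pytest.approx(s1.cv)
        assert s3.mean_ms == pytest.approx(3 * s1.mean_ms)
        assert s3.mode_ms == pytest.approx(3 * s1.mode_ms)

    def test_undefined_below_three_spikes(self):
        assert not isi_stats(train([0.0, 0.01])).defined

    def test_agrees_with_bruteforce_on_random_trains(self):
        # independent recomputation: plain mean/SD and a hand-rolled histogram
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(3, 40)
            t = np.cumsum(rng.exponential(rng.uniform(0.005, 0.3), n))
            s = isi_stats(train(t))
            isis = np.diff(t) * 1000
            assert s.mean_ms == pytest.approx(isis.mean())
            assert s.sd_ms == pytest.approx(isis.std(ddof=1))
            centres = np.arange(0, int(isis.max() + 1.5))
            counts = [
                np.sum((isis >= c - 0.5) & (isis < c + 0.5)) for c in centres
            ]
            mode = centres[int(np.argmax(counts))]
            if mode == 0:
                mode = 0.5
            assert s.mode_ms == pytest.approx(mode)


class TestClassify:
    def test_long_clustered_experimental(self):
        s = isi_stats(train([0.0, 0.005, 0.010, 0.015, 1.0, 1.005, 1.010, 3.0]))
        assert s.cv > 1.5
        assert classify_pattern(s) is PatternLabel.LONG_CLUSTERED

    def test_regular(self):
        s = isi_stats(train(np.arange(0, 1, 0.02)))
        assert classify_pattern(s) is PatternLabel.REGULAR

    def test_short_clustered_thresholds(self):
        # triplets at 5 ms ISI with 80 ms gaps: CV <= 1.5, BI > 5
        times = []
        t = 0.0
        for _ in range(50):
            times += [t, t + 0.005, t + 0.010]
            t += 0.090
        s = isi_stats(train(np.array(times)))
        assert s.cv <= 1.5 and s.bi > 5.0
        assert classify_pattern(s) is PatternLabel.SHORT_CLUSTERED

    def test_simulation_blocked_on_empty(self):
        from periax.spikemetrics import _undefined_stats

        lab = classify_pattern(_undefined_stats(), "simulation", n_spikes=0,
                               window_s=8.0)
        assert lab is PatternLabel.BLOCKED

    def test_simulation_tonic_vs_low_rate(self):
        tonic = isi_stats(train(np.arange(0, 2, 0.01)))
        assert classify_pattern(tonic, "simulation", n_spikes=200,
                                window_s=2.0) is PatternLabel.TONIC
        slow = isi_stats(train(np.arange(0, 2, 0.025)))
        assert classify_pattern(slow, "simulation", n_spikes=80,
                                window_s=2.0) is PatternLabel.LOW_RATE_REGULAR

    @given(cv=st.floats(0, 6, allow_nan=False),
           bi=st.floats(0.1, 60, allow_nan=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_partition_of_cv_bi_plane(self, cv, bi):
        from periax.spikemetrics import ISIStats

        s = ISIStats(np.array([1.0]), 10.0, 10.0 / bi if bi else 10.0,
                     cv * 10.0, cv, bi)
        lab = classify_pattern(s, "experimental")
        expected = (
            PatternLabel.LONG_CLUSTERED if cv > 1.5
            else PatternLabel.SHORT_CLUSTERED if bi > 5.0
            else PatternLabel.REGULAR
        )
        assert lab is expected


class TestConduction:
    def test_perfect_following(self):
        node = train(np.arange(0, 8, 0.01))
        soma = train(np.arange(0, 8, 0.01) + 0.0012)
        fm = conduction_metrics(node, soma, 800, window_s=8.0)
        assert fm.initiation_ratio == 1.0
        assert fm.conduction_ratio == 1.0
        assert fm.somatic_rate == pytest.approx(100.0)

    def test_empty_soma(self):
        node = train(np.arange(0, 8, 0.01))
        fm = conduction_metrics(node, train([]), 800, window_s=8.0)
        assert fm.conduction_ratio == 0.0 and fm.somatic_rate == 0.0

    def test_half_initiation_full_conduction(self):
        node = train(np.arange(0, 8, 0.02))
        soma = train(np.arange(0, 8, 0.02) + 0.001)
        fm = conduction_metrics(node, soma, 800, window_s=8.0)
        assert fm.initiation_ratio == pytest.approx(0.5)
        assert fm.conduction_ratio == pytest.approx(1.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        node_t = np.sort(rng.uniform(0, 8, 300))
        node_t = node_t[np.diff(np.r_[-1.0, node_t]) > 0.003]
        soma_t = node_t[::2] + 0.002
        a = conduction_metrics(train(node_t), train(soma_t), 800, window_s=8.0)
        b = conduction_metrics(train(node_t + 5.0), train(soma_t + 5.0), 800,
                               window_s=8.0)
        assert a.conduction_ratio == b.conduction_ratio
        assert a.initiation_ratio == b.initiation_ratio

    def test_zero_pulses_rejected(self):
        with pytest.raises(ValueError):
            conduction_metrics(train([0.0, 1.0]), train([]), 0)


class TestCsvRoundtrip:
    def test_trains_survive_roundtrip(self, tmp_path):
        from periax.spikemetrics import load_trains_csv, save_trains_csv

        a = train(np.arange(0, 1, 0.013))
        b = SpikeTrain("soma", np.arange(0.002, 1, 0.031))
        path = tmp_path / "trains.csv"
        save_trains_csv([a, b], path)
        back = {tr.site: tr for tr in load_trains_csv(path)}
        assert set(back) == {"t", "soma"}
        assert np.allclose(back["t"].times, a.times)
        assert np.allclose(back["soma"].times, b.times)


class TestAutocorrelogram:
    def test_regular_train_peaks_at_multiples_of_period(self):
        lags, counts = autocorrelogram(train(np.arange(0, 2, 0.01)),
                                       bin_ms=1.0, max_lag_ms=50.0)
        peaks = lags[counts > 0]
        # all mass within half a bin of the 10 ms period lattice
        dist = np.abs(peaks - np.round(peaks / 10.0) * 10.0)
        assert np.all(dist <= 0.5 + 1e-9)

    def test_burst_train_short_lag_peak_at_5ms(self):
        times = []
        t = 0.0
        rng = np.random.default_rng(8)
        for _ in range(100):
            for k in range(4):
                times.append(t + 0.005 * k)
            t += rng.exponential(0.25) + 0.02
        lags, counts = autocorrelogram(train(np.array(times)), 1.0, 50.0)
        assert lags[np.argmax(counts)] == pytest.approx(5.5)

    def test_single_spike_empty(self):
        lags, counts = autocorrelogram(train([0.5]), 1.0, 50.0)
        assert counts.sum() == 0

    def test_total_count_equals_pairs_within_lag(self):
        rng = np.random.default_rng(9)
        t = np.sort(rng.uniform(0, 1, 60))
        t = t[np.diff(np.r_[-1.0, t]) > 1e-4]
        lags, counts = autocorrelogram(train(t), 2.0, 80.0)
        brute = sum(
            1 for i in range(t.size) for j in range(i + 1, t.size)
            if (t[j] - t[i]) * 1000 <= 80.0
        )
        assert counts.sum() == brute
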