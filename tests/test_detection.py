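import numpy as np
import pytest

import multifq as m
from multifq.detection import DetectionConfig, Threshold

RATE = 25_000.0


def brute_force_detect(trace, thr, L, k, spacing, polarity="both"):
    """Independent oracle: enumerate supra-threshold local extrema by direct
    scan, censor greedily by magnitude (ties -> earlier), drop edge events."""
    x = np.asarray(trace, dtype=float)
    if polarity == "both":
        mag = np.abs(x)
    elif polarity == "positive":
        mag = np.where(x > 0, x, 0.0)
    else:
        mag = np.where(x < 0, -x, 0.0)
    cands = []
    i = 1
    while i < len(x) - 1:
        if mag[i] > mag[i - 1]:
            j = i
            while j + 1 < len(x) and mag[j + 1] == mag[i]:
                j += 1
            if j + 1 < len(x) and mag[j + 1] < mag[i] and mag[i] > thr:
                cands.append(i)  # first sample of the plateau
            i = j + 1
        else:
            i += 1
    kept = []
    for c in sorted(cands, key=lambda c: (-mag[c], c)):
        if all(abs(c - kc) >= spacing for kc in kept):
            kept.append(c)
    kept.sort()
    return [c for c in kept if c >= k - 1 and c <= len(x) - 1 - (L - k)]


class TestComputeThreshold:
    def test_calibrated_trace_gives_four(self):
        # median absolute value exactly 0.6745 -> threshold 4.0
        trace = np.tile([0.6745, -0.6745], 500)
        thr = m.compute_threshold(trace)
        assert thr.value == pytest.approx(4.0)

    def test_zero_trace_gives_zero(self):
        assert m.compute_threshold(np.zeros(100)).value == 0.0

    def test_gaussian_sigma_recovery(self):
        # median|N(0,1)| ~= 0.6745, so the estimator returns ~4.0
        rng = np.random.default_rng(12345)
        trace = rng.standard_normal(1_000_000)
        thr = m.compute_threshold(trace)
        assert abs(thr.value - 4.0) / 4.0 < 0.02

    def test_multiplier_scales_linearly(self):
        rng = np.random.default_rng(0)
        trace = rng.standard_normal(10_000)
        t4 = m.compute_threshold(trace, multiplier=4.0).value
        t5 = m.compute_threshold(trace, multiplier=5.0).value
        assert t5 == pytest.approx(t4 * 5.0 / 4.0)

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            m.compute_threshold(np.array([]))


class TestDetectPeaks:
    CFG = DetectionConfig(L=64, k=20, min_peak_spacing_samples=25)

    def test_subthreshold_trace_yields_nothing(self):
        rng = np.random.default_rng(0)
        trace = 0.1 * rng.standard_normal(2000)
        ev = m.detect_peaks(trace, Threshold(5.0), self.CFG, RATE)
        assert ev.n_events == 0

    def test_single_template_recovered_at_extremum(self, templates3):
        tpl = templates3.templates[0]
        x = np.zeros(2000)
        off = int(np.argmax(np.abs(tpl)))
        x[500 - off : 500 - off + 64] += tpl
        ev = m.detect_peaks(x, Threshold(0.5), self.CFG, RATE)
        assert ev.n_events == 1
        assert ev.peak_indices[0] == 500

    def test_censor_keeps_larger_tie_earlier(self):
        x = np.zeros(300)
        x[100] = 1.0
        x[110] = 1.0  # identical bumps 10 apart; spacing 25 -> keep earlier
        ev = m.detect_peaks(x, Threshold(0.5), self.CFG, RATE)
        assert list(ev.peak_indices) == [100]

    def test_censor_keeps_larger_magnitude(self):
        x = np.zeros(300)
        x[100] = 0.8
        x[110] = -1.0
        ev = m.detect_peaks(x, Threshold(0.5), self.CFG, RATE)
        assert list(ev.peak_indices) == [110]
        assert list(ev.peak_signs) == [-1]

    def test_edge_events_dropped(self):
        cfg = DetectionConfig(L=64, k=20, min_peak_spacing_samples=25)
        x = np.zeros(100)
        x[5] = 2.0  # cut needs 19 samples before the peak
        ev = m.detect_peaks(x, Threshold(1.0), cfg, RATE)
        assert ev.n_events == 0

    def test_polarity_restriction(self):
        x = np.zeros(300)
        x[100] = 1.0
        x[200] = -1.0
        cfg_neg = DetectionConfig(L=64, k=20, polarity="negative",
                                  min_peak_spacing_samples=25)
        ev = m.detect_peaks(x, Threshold(0.5), cfg_neg, RATE)
        assert list(ev.peak_indices) == [200]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        trace = rng.standard_normal(5000)
        counts = []
        for mult in [1.0, 2.0, 3.0, 4.0, 5.0]:
            thr = Threshold(mult * 0.6745 / 0.6745)
            counts.append(m.detect_peaks(trace, thr, self.CFG, RATE).n_events)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("polarity", ["both", "negative"])
    def test_matches_brute_force_oracle(self, seed, polarity):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(500, 5000))
        trace = rng.standard_normal(n)
        # sprinkle a few large deflections
        for _ in range(int(rng.integers(0, 10))):
            i = int(rng.integers(30, n - 60))
            trace[i] += rng.choice([-1, 1]) * rng.uniform(3, 8)
        cfg = DetectionConfig(L=64, k=20, polarity=polarity,
                              min_peak_spacing_samples=int(rng.integers(5, 60)))
        thr = Threshold(float(rng.uniform(1.5, 3.5)))
        ev = m.detect_peaks(trace, thr, cfg, RATE)
        expected = brute_force_detect(
            trace, thr.value, cfg.L, cfg.k, cfg.min_peak_spacing_samples, polarity
        )
        assert list(ev.peak_indices) == expected


class TestCutWaveforms:
    CFG = DetectionConfig(L=64, k=20, min_peak_spacing_samples=25)

    def _events(self, indices):
        return m.SpikeEvents(
            peak_indices=np.asarray(indices),
            peak_signs=np.ones(len(indices), dtype=int),
            rate_hz=RATE,
        )

    def test_window_arithmetic(self):
        # 1-based samples 81..144 of the trace == 0-based 80..143
        trace = np.arange(1000, dtype=float)
        ws = m.cut_waveforms(trace, self._events([100]), self.CFG)
        assert ws.waveforms.shape == (1, 64)
        np.testing.assert_array_equal(ws.waveforms[0], trace[81 : 81 + 64])
        # 0-based: the window starts at P-(k-1)=81 and the peak sits at
        # 1-based column 20 (0-based 19)
        assert ws.waveforms[0, 19] == trace[100]

    def test_alignment_column_holds_threshold_values(self):
        rng = np.random.default_rng(0)
        trace = rng.standard_normal(2000)
        ev = self._events([100, 500, 900])
        ws = m.cut_waveforms(trace, ev, self.CFG)
        np.testing.assert_array_equal(ws.waveforms[:, 19], trace[ev.peak_indices])

    def test_other_band_cut_at_detection_indices(self):
        # medium-band value at column k equals Dm[P], generally NOT its extremum
        rng = np.random.default_rng(1)
        dm = rng.standard_normal(2000)
        ev = self._events([300, 700])
        ws = m.cut_waveforms(dm, ev, self.CFG, band_index=1)
        np.testing.assert_array_equal(ws.waveforms[:, 19], dm[[300, 700]])
        assert not np.all(np.argmax(np.abs(ws.waveforms), axis=1) == 19)

    def test_out_of_range_event_raises(self):
        trace = np.zeros(100)
        with pytest.raises((IndexError, ValueError)):
            m.cut_waveforms(trace, self._events([95]), self.CFG)


class TestAssembleComposite:
    CFG64 = DetectionConfig(L=64, k=20)
    CFG32 = DetectionConfig(L=32, k=11)

    def _sets(self, n, cfg, bands):
        rng = np.random.default_rng(0)
        return [
            m.WaveformSet(rng.standard_normal((n, cfg.L)), band_index=i, config=cfg)
            for i in range(bands)
        ]

    def test_three_64_bands_gives_192_columns(self):
        comp = m.assemble_composite(self._sets(10, self.CFG64, 3))
        assert comp.matrix.shape == (10, 192)

    def test_three_32_bands_gives_96_columns(self):
        comp = m.assemble_composite(self._sets(7, self.CFG32, 3))
        assert comp.matrix.shape == (7, 96)

    def test_single_band_is_identity(self):
        sets = self._sets(5, self.CFG64, 1)
        comp = m.assemble_composite(sets)
        np.testing.assert_array_equal(comp.matrix, sets[0].waveforms)

    def test_round_trip_band_slicing(self):
        sets = self._sets(6, self.CFG64, 3)
        comp = m.assemble_composite(sets)
        for i, ws in enumerate(sets):
            np.testing.assert_array_equal(comp.band(i), ws.waveforms)

    def test_shape_mismatch_raises(self):
        a = m.WaveformSet(np.zeros((5, 64)), 0, self.CFG64)
        b = m.WaveformSet(np.zeros((4, 64)), 1, self.CFG64)
        with pytest.raises(ValueError):
            m.assemble_composite([a, b])
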