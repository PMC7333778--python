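"""Pulse detection: smoothing, onset detection, offset estimation, windows."""

import numpy as np
import pytest

from stimdict import DetectionParams, EpochedRecording
from stimdict.detect import (
    DetectionError,
    detect_onsets,
    estimate_offset,
    extract_pulses,
    savitzky_golay,
    select_reference_channel,
)
from stimdict.metrics import onset_matching


class TestSavitzkyGolay:
    def test_reproduces_cubic_exactly(self):
        """An order-3 least-squares smoother leaves cubic signals untouched."""
        x = np.linspace(-1, 1, 101)
        trace = 2.0 * x**3 - x**2 + 0.5 * x - 4.0
        out = savitzky_golay(trace, order=3, window=7)
        np.testing.assert_allclose(out, trace, atol=1e-9)

    def test_preserves_dc(self):
        out = savitzky_golay(np.full(50, 5.0), order=3, window=7)
        np.testing.assert_allclose(out, 5.0)

    def test_reduces_white_noise_variance(self, rng):
        trace = rng.standard_normal(5000)
        out = savitzky_golay(trace, order=3, window=7)
        assert out.var() < trace.var()

    @pytest.mark.parametrize("order,window", [(3, 6), (3, 3), (7, 7)])
    def test_invalid_window_rejected(self, order, window):
        with pytest.raises(ValueError):
            savitzky_golay(np.zeros(32), order=order, window=window)


class TestReferenceChannel:
    def test_largest_artifact_channel_wins(self, rng):
        data = rng.standard_normal((500, 9, 3))
        data[:, 7, :] *= 10.0  # channel 7 carries a 10x larger artifact
        rec = EpochedRecording(data, fs=1000.0, stim_channels=(0, 1))
        assert select_reference_channel(rec) == 7

    def test_single_candidate(self, rng):
        data = rng.standard_normal((500, 1, 2))
        rec = EpochedRecording(data, fs=1000.0, stim_channels=())
        assert select_reference_channel(rec) == 0

    def test_tie_breaks_to_lowest_index(self):
        data = np.zeros((500, 4, 2))
        data[100, 2:, :] = 50.0  # identical artifacts on channels 2 and 3
        rec = EpochedRecording(data, fs=1000.0, stim_channels=(0, 1))
        assert select_reference_channel(rec) == 2

    def test_flat_recording_is_error(self):
        rec = EpochedRecording(np.zeros((64, 3, 2)), fs=1000.0, stim_channels=(0, 1))
        with pytest.raises(DetectionError):
            select_reference_channel(rec)


class TestOnsets:
    def test_synthetic_train_recalled_exactly(self, uniform_sim, uniform_model):
        """Every true pulse onset is found within ±2 samples, no extras."""
        _, truth = uniform_sim
        recall, precision = onset_matching(
            truth.pulse_onsets, uniform_model.onsets_per_epoch, tol_samples=2
        )
        assert recall == 1.0 and precision == 1.0

    def test_single_square_pulse(self):
        trace = np.zeros(2000)
        trace[1000:1010] = 100.0
        smoothed = savitzky_golay(trace, 3, 7)
        onsets = detect_onsets(smoothed, DetectionParams(), fs=12207.0)
        assert onsets.size == 1
        assert abs(onsets[0] - 1000) <= 3  # within the smoothing half-window

    def test_subthreshold_trace_yields_no_onsets(self):
        # a sinusoid's |z| never exceeds sqrt(2) < 1.5
        trace = np.sin(2 * np.pi * np.arange(1000) / 100.0)
        assert detect_onsets(trace, DetectionParams(), fs=1000.0).size == 0

    def test_biphasic_lobes_merge_into_one_onset(self):
        trace = np.zeros(4000)
        for k in range(5):
            s = 500 + k * 600
            trace[s : s + 4] = 100.0
            trace[s + 6 : s + 10] = -100.0  # second lobe 6 samples later
        onsets = detect_onsets(trace, DetectionParams(min_interpulse_ms=2.0),
                               fs=12207.0)
        assert onsets.size == 5


class TestOffset:
    def _decaying_segment(self, n=200, tau=20.0):
        t = np.arange(n, dtype=float)
        return 100.0 * np.exp(-t / tau)

    def test_offset_monotone_in_percentage(self):
        """A higher percentage cutoff captures a longer artifact."""
        seg = self._decaying_segment()
        offs = []
        for pct in (50.0, 75.0, 90.0, 99.0):
            p = DetectionParams(offset_pct_voltage=pct, offset_pct_derivative=pct,
                                post_pad_ms=0.0)
            offs.append(estimate_offset(seg, p, fs=12207.0))
        assert all(a <= b for a, b in zip(offs, offs[1:]))
        assert offs[0] < offs[-1]

    def test_known_extent_covered(self, rng):
        """Artifact occupying the first 30 of 60 samples → offset ≈ 30 + pad.

        The artifact stays above a quarter of its peak for its whole extent,
        then drops into the noise floor.
        """
        seg = np.zeros(120)
        seg[:30] = 100.0 * np.exp(-np.arange(30) / 30.0)  # decays only to 38%
        seg += 0.5 * rng.standard_normal(120)
        params = DetectionParams(post_pad_ms=1.0)
        off = estimate_offset(seg, params, fs=12207.0)
        pad = round(1.0 * 12207.0 / 1000.0)
        assert 29 <= off <= 31 + pad

    def test_fixed_window_bypasses_estimation(self):
        seg = self._decaying_segment()
        params = DetectionParams(fixed_window=True, fixed_window_ms=1.0,
                                 post_pad_ms=0.0)
        assert estimate_offset(seg, params, fs=12207.0) == round(12207.0 / 1000.0)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            estimate_offset(np.zeros(2), DetectionParams(), fs=1000.0)


class TestExtractPulses:
    def test_window_count_is_product(self, uniform_model, uniform_sim):
        rec, _ = uniform_sim
        pulses = uniform_model.detect()
        n_rec_channels = len(rec.recording_channels)
        assert len(pulses) == 80 * rec.n_epochs * n_rec_channels

    def test_windows_disjoint_and_ordered(self, uniform_model):
        pulses = uniform_model.detect()
        for chan in pulses.channels:
            by_epoch = {}
            for w in pulses.for_channel(chan):
                by_epoch.setdefault(w.epoch, []).append(w)
            for ws in by_epoch.values():
                for a, b in zip(ws, ws[1:]):
                    assert a.stop <= b.start

    def test_baseline_correction_zeroes_leading_mean(self, uniform_model):
        nb = uniform_model.detection.n_baseline_samples
        for w in list(uniform_model.detect())[::500]:
            assert abs(np.mean(w.corrected[:nb])) < 1e-9

    def test_padding_contract(self, uniform_model):
        pulses = uniform_model.detect()
        for chan in pulses.channels:
            length = pulses.common_length(chan)
            for w in pulses.for_channel(chan):
                assert w.padded.size == length
                np.testing.assert_array_equal(w.padded[: len(w.corrected)],
                                              w.corrected)
                assert not w.padded[len(w.corrected):].any()

    def test_windows_capture_artifact_energy(self, uniform_sim, uniform_fit):
        """Detected windows hold ≥ 99% of the true artifact energy."""
        from stimdict.metrics import artifact_energy_capture, window_mask_from_ledger

        rec, truth = uniform_sim
        mask = window_mask_from_ledger(uniform_fit.ledger, rec.data.shape)
        capture = artifact_energy_capture(truth, mask, rec.recording_channels)
        assert capture >= 0.99
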