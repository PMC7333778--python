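"""Template matching, range scaling and subtraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stimdict.containers import ChannelDictionary, PulseWindow
from stimdict.metrics import recovery_metrics, window_mask_from_ledger
from stimdict.subtract import _correlation, match_template, scale_template


def _window(wave, start=0):
    wave = np.asarray(wave, dtype=float)
    return PulseWindow(channel=0, epoch=0, pulse=0, start=start,
                       stop=start + wave.size, raw=wave.copy(),
                       corrected=wave.copy())


def _dict(*templates):
    return ChannelDictionary(
        templates={i: np.asarray(t, dtype=float) for i, t in enumerate(templates)},
        labels=np.zeros(1, dtype=int), outlier_scores=np.zeros(1),
    )


BASE = np.sin(np.linspace(0, 3 * np.pi, 40)) * np.exp(-np.linspace(0, 3, 40))


class TestMatch:
    def test_scaled_offset_copy_matches_perfectly(self):
        """Correlation ignores scale and offset: 3.7·t + 10 µV picks t, r = 1."""
        other = np.cos(np.linspace(0, 2 * np.pi, 40))
        pulse = _window(3.7 * BASE + 10.0)
        tid, corr = match_template(pulse, _dict(other, BASE))
        assert tid == 1
        assert corr == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_never_beats_positively_correlated(self, rng):
        """Brute-force check: the signed-correlation argmax is returned."""
        templates = [BASE, 0.5 * BASE + np.roll(BASE, 17)]
        pulse = _window(-BASE)
        d = _dict(*templates)
        tid, corr = match_template(pulse, d)
        expected = np.argmax([_correlation(-BASE, t) for t in templates])
        assert tid == expected
        assert corr >= _correlation(-BASE, templates[1 - tid])

    def test_single_template_dictionary(self):
        tid, _ = match_template(_window(np.arange(40.0)), _dict(BASE))
        assert tid == 0

    def test_zero_variance_pulse_correlation_is_zero(self):
        tid, corr = match_template(_window(np.zeros(40)), _dict(BASE))
        assert corr == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(alpha=st.floats(0.01, 100.0), beta=st.floats(-500.0, 500.0))
    def test_match_invariant_under_positive_affine_maps(self, alpha, beta):
        """match(α·pulse + β) = match(pulse) for α > 0."""
        d = _dict(BASE, np.cos(np.linspace(0, 2 * np.pi, 40)))
        base_tid, _ = match_template(_window(BASE), d)
        tid, _ = match_template(_window(alpha * BASE + beta), d)
        assert tid == base_tid


class TestScale:
    def test_scale_is_range_ratio(self):
        pulse = _window(np.array([0.0, 200.0, 0.0, -0.0]))
        template = np.array([0.0, 100.0, 0.0, 0.0])
        scaled, scale = scale_template(template, pulse)
        assert scale == pytest.approx(2.0)
        assert np.ptp(scaled) == pytest.approx(np.ptp(pulse.corrected))

    def test_identity_when_pulse_equals_template(self):
        pulse = _window(BASE)
        scaled, scale = scale_template(BASE.copy(), pulse)
        assert scale == pytest.approx(1.0)
        np.testing.assert_allclose(scaled, BASE)

    def test_zero_range_template_is_noop(self):
        pulse = _window(BASE)
        scaled, scale = scale_template(np.zeros(40), pulse)
        assert scale == 1.0
        assert not scaled.any()

    def test_scaling_reduces_residual_on_amplitude_mismatch(self, nonuniform_sim):
        """On the non-uniform train, range scaling beats unscaled subtraction."""
        from stimdict import StimulationArtifactModel

        rec, truth = nonuniform_sim
        model = StimulationArtifactModel(rec)
        pulses = model.detect()
        from stimdict.dictionary import build_dictionary
        from stimdict.subtract import subtract_all

        dictionary = build_dictionary(pulses, model.clustering)
        scaled_res = subtract_all(rec, pulses, dictionary)
        # unscaled variant: subtract the matched template verbatim
        unscaled = rec.copy()
        from stimdict.subtract import match_template as mt

        for w in pulses:
            tid, _ = mt(w, dictionary[w.channel])
            tpl = dictionary[w.channel].templates[tid]
            n = w.stop - w.start
            unscaled.data[w.start : w.stop, w.channel, w.epoch] -= tpl[:n]
        from stimdict.metrics import in_window_rms

        mask = window_mask_from_ledger(scaled_res.ledger, rec.data.shape)
        chans = rec.recording_channels
        rms_scaled = in_window_rms(scaled_res.recovered.data - truth.clean, mask, chans)
        rms_unscaled = in_window_rms(unscaled.data - truth.clean, mask, chans)
        assert rms_scaled <= rms_unscaled


class TestRecover:
    def test_out_of_window_samples_bit_identical(self, uniform_sim, uniform_fit):
        rec, _ = uniform_sim
        mask = window_mask_from_ledger(uniform_fit.ledger, rec.data.shape)
        assert np.array_equal(rec.data[~mask], uniform_fit.recovered.data[~mask])

    def test_in_window_artifact_removed(self, uniform_sim, uniform_fit):
        """≥ 95% of in-window artifact RMS is removed."""
        rec, truth = uniform_sim
        mask = window_mask_from_ledger(uniform_fit.ledger, rec.data.shape)
        m = recovery_metrics(rec, uniform_fit.recovered, truth, mask)
        assert m["rms_reduction"] >= 0.95

    def test_ledger_covers_every_pulse(self, uniform_sim, uniform_fit):
        rec, truth = uniform_sim
        n_pulses = sum(o.size for o in truth.pulse_onsets)
        assert len(uniform_fit.ledger) == n_pulses * len(rec.recording_channels)
        assert set(uniform_fit.ledger["channel"]) == set(rec.recording_channels)

    def test_exact_template_recovers_clean_signal(self):
        """raw = clean + template exactly → recovered == clean in window."""
        from stimdict.subtract import subtract_pulse

        clean = np.linspace(-1, 1, 40)
        data = np.zeros((100, 1, 1))
        data[:, 0, 0] = 0.0
        data[30:70, 0, 0] = clean + BASE
        w = PulseWindow(channel=0, epoch=0, pulse=0, start=30, stop=70,
                        raw=data[30:70, 0, 0].copy(),
                        corrected=data[30:70, 0, 0].copy())
        subtract_pulse(data, w, BASE.copy())
        np.testing.assert_allclose(data[30:70, 0, 0], clean, atol=1e-12)
        assert not data[:30, 0, 0].any() and not data[70:, 0, 0].any()

    def test_undersampled_regime_flagged_failed(self, undersampled_fit):
        """1221 Hz sampling of 200 µs pulses: residuals stay on the artifact's
        scale and the run is flagged FAILED."""
        rec, truth, model, fit = undersampled_fit
        assert fit.failed
        mask = window_mask_from_ledger(fit.ledger, rec.data.shape)
        m = recovery_metrics(rec, fit.recovered, truth, mask)
        assert m["residual_ratio"] >= 0.1  # same order as the raw artifact
        from stimdict.subtract import FAILED_MIN_MEAN_ABS_CORR

        assert fit.result.diagnostics["mean_abs_correlation"] < FAILED_MIN_MEAN_ABS_CORR

    def test_good_regime_not_flagged(self, uniform_fit):
        assert not uniform_fit.failed

    def test_edge_blend_tapers_subtraction(self, uniform_sim, uniform_model):
        """With a taper, less of the template is removed at window edges, and
        out-of-window samples stay untouched."""
        from stimdict.dictionary import build_dictionary
        from stimdict.subtract import subtract_all

        rec, _ = uniform_sim
        pulses = uniform_model.detect()
        dictionary = build_dictionary(pulses, uniform_model.clustering)
        plain = subtract_all(rec, pulses, dictionary)
        blended = subtract_all(rec, pulses, dictionary, edge_blend=3)
        mask = window_mask_from_ledger(plain.ledger, rec.data.shape)
        assert np.array_equal(rec.data[~mask], blended.recovered.data[~mask])
        assert not np.array_equal(plain.recovered.data, blended.recovered.data)
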