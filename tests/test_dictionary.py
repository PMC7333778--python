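"""Feature extraction, density-based clustering and template dictionaries."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from stimdict import ClusteringParams, NOISE
from stimdict.containers import PulseSet, PulseWindow
from stimdict.dictionary import (
    _features_from_waveform,
    build_channel_dictionary,
    build_dictionary,
    cluster_pulses,
    extract_features,
    feature_matrix,
)


def _window(wave, channel=0, epoch=0, pulse=0, start=0):
    wave = np.asarray(wave, dtype=float)
    return PulseWindow(channel=channel, epoch=epoch, pulse=pulse, start=start,
                       stop=start + wave.size, raw=wave.copy(),
                       corrected=wave.copy())


class TestFeatures:
    def test_twelve_features_by_default(self):
        """Half-width 6 around the peak gives 12 features, peak excluded."""
        wave = np.zeros(64)
        wave[30] = 10.0
        feats = _features_from_waveform(wave, half_width=6)
        assert feats.size == 12
        assert 10.0 not in feats  # the peak sample itself is excluded

    def test_symmetric_pulse_gives_symmetric_features(self):
        wave = np.concatenate([np.arange(11.0), np.arange(11.0)[::-1][1:]])
        feats = _features_from_waveform(wave, half_width=6)
        np.testing.assert_allclose(feats, feats[::-1])

    def test_edge_peak_zero_filled(self):
        """Peak at sample 2 → the first 4 feature slots fall off the window."""
        wave = np.zeros(64)
        wave[2] = -50.0
        feats = _features_from_waveform(wave, half_width=6)
        assert not feats[:4].any()

    def test_all_zero_pulse_gives_zero_features(self):
        feats = extract_features(_windowed_zero(), ClusteringParams())
        assert not feats.any()


def _windowed_zero():
    w = _window(np.zeros(16))
    w.padded = np.zeros(16)
    return w


class TestClustering:
    def test_four_morphologies_recovered(self, uniform_sim, uniform_model,
                                         uniform_fit):
        """k=2, n=3, θ=0.9 finds the 4 sampling-phase clusters (ARI ≥ 0.9)."""
        _, truth = uniform_sim
        ref = 2  # strongest recording channel
        ws = uniform_model.detect().for_channel(ref)
        true_ids = [truth.shape_ids[w.epoch][w.pulse] for w in ws]
        chan_dict = uniform_fit.dictionary[ref]
        assert chan_dict.n_templates == 4
        assert adjusted_rand_score(true_ids, chan_dict.labels) >= 0.9

    def test_identical_pulses_form_one_cluster_without_noise(self):
        feats = np.tile(np.arange(12.0), (25, 1))
        labels, scores = cluster_pulses(feats, ClusteringParams())
        assert set(labels) == {0}
        assert not (labels == NOISE).any()
        assert np.all(scores == 0)

    def test_injected_outliers_labelled_noise(self, outlier_sim, outlier_fit):
        _, truth = outlier_sim
        model, fit = outlier_fit
        ws = model.detect().for_channel(2)
        tids = np.array([truth.shape_ids[w.epoch][w.pulse] for w in ws])
        labels = fit.dictionary[2].labels
        assert np.all(labels[tids == -1] == NOISE)
        # and no core-cluster pulse is discarded with them
        assert not (labels[tids != -1] == NOISE).any()

    def test_fewer_points_than_min_cluster_size_fall_back(self):
        feats = np.arange(24.0).reshape(2, 12)
        labels, scores = cluster_pulses(feats, ClusteringParams(n=3))
        assert np.all(labels == 0)

    def test_theta_noise_sets_nested(self, uniform_model):
        """Raising θ toward 1 can only shrink the noise set."""
        feats = feature_matrix(uniform_model.detect(), 2, ClusteringParams())
        noise_sets = []
        for theta in (0.5, 0.7, 0.9, 0.99):
            labels, _ = cluster_pulses(feats, ClusteringParams(theta=theta))
            noise_sets.append(set(np.flatnonzero(labels == NOISE)))
        for lo, hi in zip(noise_sets, noise_sets[1:]):
            assert hi <= lo

    def test_deterministic_for_fixed_input(self, uniform_model):
        feats = feature_matrix(uniform_model.detect(), 3, ClusteringParams())
        a, _ = cluster_pulses(feats, ClusteringParams())
        b, _ = cluster_pulses(feats, ClusteringParams())
        np.testing.assert_array_equal(a, b)


class TestTemplates:
    def _pulse_set(self, waves):
        windows = [_window(w, pulse=i) for i, w in enumerate(waves)]
        return PulseSet(windows, fs=1000.0)

    def test_mean_of_identical_is_the_waveform(self):
        w = np.sin(np.linspace(0, 3, 32)) * 40.0
        ps = self._pulse_set([w] * 10)
        d = build_channel_dictionary(ps, 0, np.zeros(10, dtype=int), np.zeros(10))
        np.testing.assert_allclose(d.templates[0], w)

    def test_one_template_per_cluster(self):
        ps = self._pulse_set([np.ones(16)] * 30 + [np.full(16, -3.0)] * 10)
        labels = np.array([0] * 30 + [1] * 10)
        d = build_channel_dictionary(ps, 0, labels, np.zeros(40))
        assert d.n_templates == 2

    def test_opposite_polarity_members_average_to_zero(self):
        """w and -w in one cluster cancel — clustering must separate polarity."""
        w = np.sin(np.linspace(0, 3, 32))
        ps = self._pulse_set([w, -w])
        d = build_channel_dictionary(ps, 0, np.zeros(2, dtype=int), np.zeros(2))
        np.testing.assert_allclose(d.templates[0], 0.0, atol=1e-12)

    def test_all_noise_channel_falls_back_to_grand_mean(self):
        waves = [np.ones(8), np.full(8, 3.0)]
        ps = self._pulse_set(waves)
        labels = np.full(2, NOISE)
        d = build_channel_dictionary(ps, 0, labels, np.ones(2))
        np.testing.assert_allclose(d.templates[0], 2.0)

    def test_empty_pulse_set_rejected(self):
        with pytest.raises(ValueError):
            build_dictionary(PulseSet([], fs=1000.0))

    def test_template_converges_to_true_shape(self, uniform_sim, uniform_model,
                                              uniform_fit):
        """Learned templates approach the true artifact shape as O(σ/√m)."""
        rec, truth = uniform_sim
        ch = 2
        ws = uniform_model.detect().for_channel(ch)
        chan_dict = uniform_fit.dictionary[ch]
        sigma = rec.data[:100, ch, 0].std()  # pre-train background level
        for lab, template in chan_dict.templates.items():
            members = [w for w, l in zip(ws, chan_dict.labels) if l == lab]
            m = len(members)
            # true artifact waveform for this cluster, from the artifact-only
            # signal of the generator (identical across members up to length)
            w0 = members[0]
            true_wave = truth.artifact[w0.start : w0.stop, ch, w0.epoch]
            n = min(true_wave.size, template.size)
            dev = np.max(np.abs(template[:n] - true_wave[:n]))
            assert dev <= 6.0 * sigma / np.sqrt(m) + 1e-9

    def test_label_permutation_leaves_template_set_unchanged(self):
        waves = [np.ones(8) * k for k in (1, 1, 1, 5, 5, 5)]
        ps = self._pulse_set(waves)
        labels = np.array([0, 0, 0, 1, 1, 1])
        d1 = build_channel_dictionary(ps, 0, labels, np.zeros(6))
        d2 = build_channel_dictionary(ps, 0, 1 - labels, np.zeros(6))
        set1 = {tuple(t) for t in d1.templates.values()}
        set2 = {tuple(t) for t in d2.templates.values()}
        assert set1 == set2
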