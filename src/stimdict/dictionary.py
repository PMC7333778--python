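"""Learning a per-channel dictionary of artifact templates.

Every pulse on a channel is reduced to a short feature vector around its
absolute-voltage peak and clustered with hierarchical density-based
clustering (HDBSCAN). The mean padded waveform of each cluster becomes one
artifact template; pulses whose outlier score exceeds θ are labelled noise
and excluded from the means (they are still matched and subtracted
downstream). Channels are always clustered independently.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.cluster import HDBSCAN

from .containers import NOISE, ChannelDictionary, PulseSet, PulseWindow, TemplateDictionary
from .params import ClusteringParams

logger = logging.getLogger(__name__)


def extract_features(pulse: PulseWindow, params: ClusteringParams) -> np.ndarray:
    """Feature vector: samples flanking the pulse's absolute-voltage peak.

    ``feature_half_width`` samples are taken on each side of the argmax of
    |voltage| in the padded pulse; the peak sample itself is excluded, so the
    vector has ``2 * feature_half_width`` entries (12 by default, i.e. 0.5 ms
    per side at 12 207 Hz). Positions falling outside the window are
    zero-filled.
    """
    return _features_from_waveform(pulse.padded, params.feature_half_width)


def _features_from_waveform(wave: np.ndarray, half_width: int) -> np.ndarray:
    wave = np.asarray(wave, dtype=np.float64)
    if wave.size == 0:
        raise ValueError("empty pulse waveform")
    if not wave.any():
        logger.debug("all-zero pulse; features are all zero")
        return np.zeros(2 * half_width)
    peak = int(np.argmax(np.abs(wave)))
    idx = np.concatenate(
        [np.arange(peak - half_width, peak), np.arange(peak + 1, peak + half_width + 1)]
    )
    feats = np.zeros(2 * half_width, dtype=np.float64)
    valid = (idx >= 0) & (idx < wave.size)
    feats[valid] = wave[idx[valid]]
    return feats


def feature_matrix(pulses: PulseSet, channel: int, params: ClusteringParams) -> np.ndarray:
    """Stack features of all the channel's pulses, (epoch, pulse)-ordered."""
    ws = pulses.for_channel(channel)
    if not ws:
        return np.empty((0, 2 * params.feature_half_width))
    return np.stack([extract_features(w, params) for w in ws])


def cluster_pulses(
    features: np.ndarray, params: ClusteringParams
) -> tuple[np.ndarray, np.ndarray]:
    """Density-based clustering of pulse feature vectors.

    Runs HDBSCAN with ``k`` core-distance neighbours and minimum cluster size
    ``n``; each pulse receives an outlier score in [0, 1] (one minus its
    cluster-membership strength — points the hierarchy itself rejects score
    1), and pulses scoring above θ are labelled ``NOISE``. Deterministic for
    a fixed input ordering.

    Returns ``(labels, outlier_scores)``; labels are consecutive integers from
    0 with ``NOISE`` (-1) for outliers.
    """
    features = np.asarray(features, dtype=np.float64)
    m = features.shape[0]
    if m == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    if m <= params.n:
        logger.info("only %d pulses (< min cluster size %d); single fallback cluster",
                    m, params.n)
        return np.zeros(m, dtype=np.int64), np.zeros(m)
    if np.allclose(features, features[0]):
        # degenerate: identical pulses form one cluster with no outliers
        return np.zeros(m, dtype=np.int64), np.zeros(m)

    clusterer = HDBSCAN(
        min_cluster_size=params.n,
        min_samples=params.k,
        metric=params.metric,
        copy=True,
    )
    clusterer.fit(features)
    labels = clusterer.labels_.astype(np.int64)
    scores = 1.0 - clusterer.probabilities_
    labels[scores > params.theta] = NOISE
    if np.all(labels == NOISE):
        logger.info("clustering labelled every pulse noise; single fallback cluster")
        return np.zeros(m, dtype=np.int64), scores
    # compact label ids to 0..K-1 preserving order of first appearance
    uniq = [u for u in np.unique(labels) if u != NOISE]
    remap = {u: i for i, u in enumerate(uniq)}
    labels = np.array([remap.get(l, NOISE) for l in labels], dtype=np.int64)
    return labels, scores


def shift_waveform(wave: np.ndarray, k: int) -> np.ndarray:
    """Shift a waveform by ``k`` samples, zero-filling the vacated end."""
    out = np.zeros_like(wave)
    if k >= 0:
        out[k:] = wave[: wave.size - k] if k else wave
    else:
        out[:k] = wave[-k:]
    return out


def _aligned_mean(mat: np.ndarray) -> np.ndarray:
    """Mean of waveforms after aligning their absolute-voltage peaks.

    Residual onset-detection jitter can leave members of one cluster offset
    by a sample or two in the window frame (the features that grouped them
    are peak-relative); averaging without re-alignment would smear the
    template's peak. Members are shifted to the cluster's median peak index
    before averaging; the template is re-aligned to each pulse's peak again
    at subtraction time.
    """
    peaks = np.argmax(np.abs(mat), axis=1)
    ref = int(np.median(peaks))
    return np.mean([shift_waveform(row, ref - p) for row, p in zip(mat, peaks)],
                   axis=0)


def build_channel_dictionary(
    pulses: PulseSet, channel: int, labels: np.ndarray, scores: np.ndarray
) -> ChannelDictionary:
    """Template per cluster = mean of member padded waveforms (peak-aligned).

    Noise pulses are excluded from every mean; if the whole channel is noise
    the grand mean of all pulses stands in as a single template.
    """
    mat = pulses.padded_matrix(channel)
    if mat.shape[0] != labels.size:
        raise ValueError("labels misaligned with channel pulses")
    templates: dict[int, np.ndarray] = {}
    for lab in np.unique(labels):
        if lab == NOISE:
            continue
        templates[int(lab)] = _aligned_mean(mat[labels == lab])
    if not templates:
        logger.warning("channel %d: all pulses noise; grand-mean fallback template",
                       channel)
        templates[0] = _aligned_mean(mat)
    return ChannelDictionary(templates=templates, labels=labels, outlier_scores=scores)


def build_dictionary(
    pulses: PulseSet, params: ClusteringParams | None = None,
    channels: list[int] | None = None,
) -> TemplateDictionary:
    """Cluster every channel's pulses and assemble the template dictionary."""
    params = params or ClusteringParams()
    if len(pulses) == 0:
        raise ValueError("cannot build a dictionary from an empty pulse set")
    channels = channels if channels is not None else pulses.channels
    out: dict[int, ChannelDictionary] = {}
    for chan in channels:
        feats = feature_matrix(pulses, chan, params)
        if feats.shape[0] == 0:
            continue
        labels, scores = cluster_pulses(feats, params)
        out[chan] = build_channel_dictionary(pulses, chan, labels, scores)
        logger.debug("channel %d: %d templates, noise fraction %.2f",
                     chan, out[chan].n_templates, out[chan].noise_fraction)
    return TemplateDictionary(out)
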