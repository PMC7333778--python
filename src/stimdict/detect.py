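"""Detection of stimulation-pulse windows.

Pulse timing is read off the recording itself rather than a hardware trigger:
onsets are detected on the channel with the largest artifact (volume
conduction makes artifact timing common to all channels), and each pulse's
artifact end is then estimated per channel and per pulse from the decay of
the smoothed voltage and its derivative. The Savitzky-Golay smoothed trace is
used for detection only and never enters the recovered signal.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import savgol_filter

from .containers import EpochedRecording, PulseSet, PulseWindow
from .params import DetectionParams

logger = logging.getLogger(__name__)


class DetectionError(RuntimeError):
    pass


def savitzky_golay(trace: np.ndarray, order: int, window: int) -> np.ndarray:
    """Least-squares local-polynomial smoothing of a 1-D voltage trace.

    Edges are handled by fitting the polynomial on the truncated window
    (scipy's ``mode="interp"``), avoiding padding bias at epoch boundaries.
    An order-``p`` filter reproduces polynomials up to degree ``p`` exactly.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if window % 2 == 0 or window <= order:
        raise ValueError(
            f"window must be odd and > order; got window={window}, order={order}"
        )
    if trace.size < window:
        raise ValueError(f"trace length {trace.size} shorter than window {window}")
    return savgol_filter(trace, window_length=window, polyorder=order, mode="interp")


def smooth_recording(rec: EpochedRecording, params: DetectionParams) -> np.ndarray:
    """Savitzky-Golay smooth every channel/epoch; returns a (t, c, e) array."""
    return savgol_filter(
        rec.data, window_length=params.sg_window, polyorder=params.sg_order,
        axis=0, mode="interp",
    )


def select_reference_channel(
    rec: EpochedRecording, params: DetectionParams | None = None,
    smoothed: np.ndarray | None = None,
) -> int:
    """Pick the non-stimulation channel with the largest artifact magnitude.

    Magnitude is the median across epochs of the peak-to-peak amplitude of the
    smoothed trace; ties break to the lowest channel index.
    """
    params = params or DetectionParams()
    if smoothed is None:
        smoothed = smooth_recording(rec, params)
    candidates = rec.recording_channels
    if not candidates:
        raise DetectionError("no non-stimulation channels available")
    ptp = smoothed.max(axis=0) - smoothed.min(axis=0)  # (c, e)
    score = np.median(ptp, axis=1)
    scores = score[candidates]
    if np.all(scores == 0):
        raise DetectionError("recording is flat on all candidate channels")
    best = int(candidates[int(np.argmax(scores))])
    n_best = int(np.sum(scores == scores.max()))
    if n_best > 1:
        logger.info(
            "reference-channel tie among %d channels; choosing lowest index %d",
            n_best, best,
        )
    logger.debug("reference channel %d (median p2p %.3g µV)", best, score[best])
    return best


def detect_onsets(
    ref_trace: np.ndarray, params: DetectionParams, fs: float
) -> np.ndarray:
    """Detect pulse onsets in one smoothed epoch of the reference channel.

    The trace is z-scored against its own epoch mean/std; contiguous
    supra-threshold runs of |z| closer than the minimum inter-pulse interval
    are merged (the two lobes of a biphasic pulse count once), runs shorter
    than ``min_run_samples`` are discarded as noise, and each surviving run's
    first sample is an onset.
    """
    trace = np.asarray(ref_trace, dtype=np.float64)
    std = trace.std()
    if std == 0:
        return np.empty(0, dtype=np.int64)
    z = np.abs((trace - trace.mean()) / std)
    above = z > params.onset_z_threshold
    if not above.any():
        logger.info("no supra-threshold samples in epoch; 0 onsets")
        return np.empty(0, dtype=np.int64)

    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)

    # drop sub-minimum runs (single-sample noise blips) before merging, so a
    # blip just ahead of a pulse cannot drag the merged run's onset earlier
    keep = (stops - starts) >= params.min_run_samples
    starts, stops = starts[keep], stops[keep]

    min_gap = params.min_interpulse_samples(fs)
    merged: list[list[int]] = []
    for s, e in zip(starts, stops):
        if merged and s - merged[-1][1] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])
    return np.asarray([s for s, _ in merged], dtype=np.int64)


def estimate_offset(
    pulse_segment: np.ndarray, params: DetectionParams, fs: float
) -> int:
    """Estimate where the artifact ends within a pulse's search segment.

    The segment spans one onset to the next (or the epoch end). For both the
    smoothed voltage and its first difference, |z| within the segment is
    thresholded and the last supra-threshold sample marks a candidate offset;
    the later candidate wins, and ``post_pad_ms`` of padding is appended
    (clipped to the segment end). In the default "peak-fraction" mode the
    threshold is ``(1 - pct/100) * max|z|`` — the artifact is over once the
    signal has decayed below that fraction of its peak, so a 99% cutoff tracks
    a long exponential tail while 75% suits short artifacts.

    Returns the offset as a sample count relative to the segment start
    (exclusive end of the artifact extent).
    """
    seg = np.asarray(pulse_segment, dtype=np.float64)
    if seg.size < 3:
        raise ValueError(f"segment too short for offset estimation ({seg.size} samples)")
    pad = int(round(params.post_pad_ms * fs / 1000.0))
    if params.fixed_window:
        fixed = int(round(params.fixed_window_ms * fs / 1000.0))
        return min(fixed + pad, seg.size)

    candidates = []
    for series, pct in (
        (seg, params.offset_pct_voltage),
        (np.diff(seg), params.offset_pct_derivative),
    ):
        std = series.std()
        if std == 0:
            candidates.append(1)
            continue
        z = np.abs((series - series.mean()) / std)
        if params.offset_mode == "peak-fraction":
            thresh = (1.0 - pct / 100.0) * z.max()
        else:
            thresh = np.percentile(z, 100.0 - pct)
        above = np.flatnonzero(z >= thresh)
        candidates.append(int(above[-1]) + 1 if above.size else 1)
    return min(max(candidates) + pad, seg.size)


def extract_pulses(
    rec: EpochedRecording,
    onsets_per_epoch: list[np.ndarray],
    params: DetectionParams,
    smoothed: np.ndarray | None = None,
    channels: list[int] | None = None,
) -> PulseSet:
    """Cut per-pulse windows from every recording channel.

    Onsets (shared across channels) come from :func:`detect_onsets` on the
    reference channel. Each window opens ``pre_window_ms`` before the onset;
    its end is estimated per channel and per pulse by :func:`estimate_offset`
    on the smoothed trace. Windows are clipped to epoch bounds and truncated
    at the next window's start if offset estimation overshoots. Each window is
    baseline-corrected by subtracting the mean of its first
    ``n_baseline_samples`` samples, then zero-padded to the channel-wide
    common length.
    """
    if smoothed is None:
        smoothed = smooth_recording(rec, params)
    if channels is None:
        channels = rec.recording_channels
    t = rec.n_samples
    pre = int(round(params.pre_window_ms * rec.fs / 1000.0))
    nb = params.n_baseline_samples

    windows: list[PulseWindow] = []
    for epoch in range(rec.n_epochs):
        onsets = np.asarray(onsets_per_epoch[epoch], dtype=np.int64)
        if onsets.size == 0:
            continue
        # stop each search segment shy of the next onset: smoothing spreads
        # the next pulse's rise up to half an SG window earlier
        guard = params.sg_window // 2
        seg_ends = np.append(np.maximum(onsets[1:] - guard, onsets[:-1] + 3), t)
        win_starts = np.clip(onsets - pre, 0, t)
        for chan in channels:
            trace = smoothed[:, chan, epoch]
            prev_stop = -1
            for p, (onset, seg_end) in enumerate(zip(onsets, seg_ends)):
                seg = trace[onset:seg_end]
                if seg.size < 3:
                    offset = seg.size
                else:
                    offset = estimate_offset(seg, params, rec.fs)
                start = int(win_starts[p])
                stop = min(int(onset) + int(offset), t)
                next_start = int(win_starts[p + 1]) if p + 1 < onsets.size else t
                if stop > next_start:
                    logger.debug(
                        "window overlap on channel %d epoch %d pulse %d; truncating",
                        chan, epoch, p,
                    )
                    stop = next_start
                start = max(start, prev_stop)
                if stop <= start:
                    continue
                prev_stop = stop
                raw = rec.data[start:stop, chan, epoch].copy()
                baseline = raw[: min(nb, raw.size)].mean()
                windows.append(
                    PulseWindow(
                        channel=chan, epoch=epoch, pulse=p,
                        start=start, stop=stop,
                        raw=raw, corrected=raw - baseline,
                    )
                )
    return PulseSet(windows, fs=rec.fs)


def detect_all(
    rec: EpochedRecording, params: DetectionParams | None = None,
    channels: list[int] | None = None,
) -> tuple[PulseSet, list[np.ndarray], int]:
    """Full detection stage: smooth, pick reference, find onsets, cut windows.

    Returns ``(pulses, onsets_per_epoch, reference_channel)``.
    """
    params = params or DetectionParams()
    smoothed = smooth_recording(rec, params)
    ref = select_reference_channel(rec, params, smoothed=smoothed)
    onsets_per_epoch = [
        detect_onsets(smoothed[:, ref, ep], params, rec.fs)
        for ep in range(rec.n_epochs)
    ]
    pulses = extract_pulses(rec, onsets_per_epoch, params, smoothed=smoothed,
                            channels=channels)
    return pulses, onsets_per_epoch, ref
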