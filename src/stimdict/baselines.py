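"""Comparison recovery methods: interpolation, low-pass filtering and
average-template subtraction.

These are the standard alternatives the dictionary method is judged against:
shape-preserving piecewise-cubic interpolation through each artifact window,
acausal 4th-order Butterworth low-pass filtering of the whole train, and
unscaled subtraction of a within-epoch (or global) mean pulse template.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, filtfilt

from .containers import LEDGER_COLUMNS, EpochedRecording, PulseSet, RecoveryResult

logger = logging.getLogger(__name__)

#: Flank samples anchoring the interpolant on each side of a window.
INTERP_FLANK = 3


def interpolate_artifact(rec: EpochedRecording, pulses: PulseSet) -> RecoveryResult:
    """Replace each artifact window by a monotone piecewise-cubic interpolant.

    The interpolant (PCHIP, shape-preserving) passes through ``INTERP_FLANK``
    samples on each flank of the window; windows abutting an epoch edge fall
    back to nearest-value fill. Samples outside windows are untouched.
    """
    recovered = rec.copy()
    rows = []
    for w in pulses:
        trace = recovered.data[:, w.channel, w.epoch]
        t = trace.size
        left = np.arange(max(0, w.start - INTERP_FLANK), w.start)
        right = np.arange(w.stop, min(t, w.stop + INTERP_FLANK))
        inside = np.arange(w.start, w.stop)
        if left.size == 0 or right.size == 0:
            fill_idx = right[0] if right.size else left[-1]
            logger.debug("window at epoch edge; nearest-value fill")
            trace[inside] = trace[fill_idx]
        else:
            anchors = np.concatenate([left, right])
            interp = PchipInterpolator(anchors, trace[anchors])
            trace[inside] = interp(inside)
        rows.append((w.channel, w.epoch, w.pulse, w.start, w.stop, -1, np.nan, np.nan))
    ledger = pd.DataFrame(rows, columns=LEDGER_COLUMNS)
    return RecoveryResult(recovered=recovered, ledger=ledger, method="interpolate")


def lowpass_filter(
    rec: EpochedRecording, cutoff_hz: float, order: int = 4
) -> EpochedRecording:
    """Zero-phase (forward-backward) Butterworth low-pass of every epoch.

    Filtering runs across the entire pulse train rather than per detected
    pulse, so — unlike every other method here — all samples are modified.
    """
    if not 0 < cutoff_hz < rec.fs / 2:
        raise ValueError(
            f"cutoff must lie in (0, fs/2)=(0, {rec.fs / 2:g}); got {cutoff_hz}"
        )
    b, a = butter(order, cutoff_hz, btype="low", fs=rec.fs)
    out = rec.copy()
    out.data = filtfilt(b, a, out.data, axis=0)
    return out


def epoch_average_template_subtract(
    rec: EpochedRecording, pulses: PulseSet, mode: str = "epoch"
) -> RecoveryResult:
    """Subtract an unscaled mean-pulse template per channel.

    ``mode="epoch"``: the template is the mean of the padded pulses within
    each stimulation epoch (a single-pulse epoch subtracts itself, logged).
    ``mode="global"``: one template from all the channel's pulses. Both fail
    by construction when pulse amplitude varies within a train.
    """
    if mode not in ("epoch", "global"):
        raise ValueError(f"mode must be 'epoch' or 'global'; got {mode!r}")
    recovered = rec.copy()
    rows = []
    for chan in pulses.channels:
        ws = pulses.for_channel(chan)
        mat = pulses.padded_matrix(chan)
        if mode == "global":
            template = mat.mean(axis=0)
        epochs = {w.epoch for w in ws}
        for ep in sorted(epochs):
            members = [i for i, w in enumerate(ws) if w.epoch == ep]
            if mode == "epoch":
                template = mat[members].mean(axis=0)
                if len(members) == 1:
                    logger.debug(
                        "single pulse in channel %d epoch %d; template is the pulse itself",
                        chan, ep,
                    )
            for i in members:
                w = ws[i]
                n = w.stop - w.start
                recovered.data[w.start : w.stop, chan, ep] -= template[:n]
                rows.append((chan, ep, w.pulse, w.start, w.stop, 0, np.nan, 1.0))
    ledger = pd.DataFrame(rows, columns=LEDGER_COLUMNS)
    return RecoveryResult(
        recovered=recovered, ledger=ledger,
        method="epoch-average" if mode == "epoch" else "global-average",
    )
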