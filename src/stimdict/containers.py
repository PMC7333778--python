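"""Core data containers for epoched stimulation recordings and results.

Conventions used throughout the package:

* voltages are in microvolts (µV),
* arrays of epoched data are ``(t, c, e)`` = time samples × channels × epochs,
* all indices are 0-based and all windows are half-open ``[start, stop)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cluster label assigned to pulses treated as noise/outliers.
NOISE = -1

#: Ledger column order used by every recovery method.
LEDGER_COLUMNS = [
    "channel",
    "epoch",
    "pulse",
    "start",
    "stop",
    "template_id",
    "correlation",
    "scale",
]


@dataclass
class EpochedRecording:
    """A multichannel voltage recording cut into stimulation epochs.

    Parameters
    ----------
    data : ndarray, shape (t, c, e)
        Voltages in microvolts: t time samples, c channels, e epochs.
    fs : float
        Sampling rate in Hz.
    stim_channels : tuple of int
        0-based indices of the bipolar stimulation pair. These channels carry
        the stimulation waveform itself and are excluded from signal recovery.
    epoch_onsets : ndarray or None
        Optional absolute start time of each epoch, in seconds.
    channel_labels : list of str or None
        Optional human-readable channel names.
    """

    data: np.ndarray
    fs: float
    stim_channels: tuple[int, int] = (0, 1)
    epoch_onsets: np.ndarray | None = None
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be 3-D (t, c, e); got shape {self.data.shape}"
            )
        t, c, e = self.data.shape
        if t < 1 or c < 1 or e < 1:
            raise ValueError(f"all dimensions must be >= 1; got {self.data.shape}")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive; got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        self.stim_channels = tuple(int(s) for s in self.stim_channels)
        for s in self.stim_channels:
            if not 0 <= s < c:
                raise ValueError(f"stim channel {s} out of range for {c} channels")
        if self.epoch_onsets is not None:
            self.epoch_onsets = np.asarray(self.epoch_onsets, dtype=np.float64)
            if self.epoch_onsets.shape != (e,):
                raise ValueError("epoch_onsets must have one entry per epoch")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[2]

    @property
    def recording_channels(self) -> list[int]:
        """Indices of non-stimulation channels (the ones recovery touches)."""
        return [c for c in range(self.n_channels) if c not in self.stim_channels]

    def copy(self) -> "EpochedRecording":
        return EpochedRecording(
            data=self.data.copy(),
            fs=self.fs,
            stim_channels=self.stim_channels,
            epoch_onsets=None if self.epoch_onsets is None else self.epoch_onsets.copy(),
            channel_labels=None if self.channel_labels is None else list(self.channel_labels),
        )


@dataclass
class PulseWindow:
    """One stimulation pulse's sample window on one channel in one epoch.

    ``corrected`` is ``raw`` minus the mean of its first ``n_baseline`` samples;
    ``padded`` is ``corrected`` zero-padded to the channel-wide common length.
    """

    channel: int
    epoch: int
    pulse: int
    start: int
    stop: int
    raw: np.ndarray
    corrected: np.ndarray
    padded: np.ndarray | None = None

    def __len__(self) -> int:
        return self.stop - self.start


class PulseSet:
    """All detected pulse windows, grouped per channel in (epoch, pulse) order."""

    def __init__(self, windows: list[PulseWindow], fs: float):
        self.fs = fs
        self._by_channel: dict[int, list[PulseWindow]] = {}
        for w in windows:
            self._by_channel.setdefault(w.channel, []).append(w)
        # fixed (epoch, pulse) ordering guarantees deterministic clustering
        for chan_windows in self._by_channel.values():
            chan_windows.sort(key=lambda w: (w.epoch, w.pulse))
        self._pad_to_common_length()

    def _pad_to_common_length(self) -> None:
        for chan, ws in self._by_channel.items():
            length = max(len(w.corrected) for w in ws)
            for w in ws:
                padded = np.zeros(length, dtype=np.float64)
                padded[: len(w.corrected)] = w.corrected
                w.padded = padded

    @property
    def channels(self) -> list[int]:
        return sorted(self._by_channel)

    def for_channel(self, channel: int) -> list[PulseWindow]:
        return self._by_channel.get(channel, [])

    def padded_matrix(self, channel: int) -> np.ndarray:
        """Stack the channel's padded waveforms into an (n_pulses, t_p) matrix."""
        ws = self.for_channel(channel)
        if not ws:
            return np.empty((0, 0))
        return np.stack([w.padded for w in ws])

    def common_length(self, channel: int) -> int:
        ws = self.for_channel(channel)
        return len(ws[0].padded) if ws else 0

    def __len__(self) -> int:
        return sum(len(ws) for ws in self._by_channel.values())

    def __iter__(self):
        for chan in self.channels:
            yield from self._by_channel[chan]


@dataclass
class ChannelDictionary:
    """Learned artifact templates for one channel.

    ``templates`` maps template id → mean waveform (channel common length).
    ``labels`` / ``outlier_scores`` are aligned with the channel's pulses in
    (epoch, pulse) order; label ``NOISE`` marks pulses excluded from template
    means.
    """

    templates: dict[int, np.ndarray]
    labels: np.ndarray
    outlier_scores: np.ndarray

    @property
    def n_templates(self) -> int:
        return len(self.templates)

    @property
    def noise_fraction(self) -> float:
        if self.labels.size == 0:
            return 0.0
        return float(np.mean(self.labels == NOISE))


class TemplateDictionary:
    """Per-channel dictionaries of mean artifact waveforms."""

    def __init__(self, channels: dict[int, ChannelDictionary]):
        self.channels = channels

    def __getitem__(self, channel: int) -> ChannelDictionary:
        return self.channels[channel]

    def __contains__(self, channel: int) -> bool:
        return channel in self.channels

    @property
    def n_templates_per_channel(self) -> dict[int, int]:
        return {c: d.n_templates for c, d in self.channels.items()}


@dataclass
class RecoveryResult:
    """A recovered recording plus the per-pulse subtraction ledger.

    The recovered array has the same shape and units as the input, agrees with
    it bit-exactly outside every pulse window, and the ledger records the
    window, chosen template, correlation and scale factor for every detected
    pulse on every recording channel.
    """

    recovered: EpochedRecording
    ledger: pd.DataFrame
    method: str = "dictionary"
    failed: bool = False
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Signal recovery summary",
            "=======================",
            f"method:          {self.method}",
            f"shape (t,c,e):   {self.recovered.data.shape}",
            f"fs:              {self.recovered.fs:g} Hz",
            f"pulses in ledger: {len(self.ledger)}",
            f"run flagged FAILED: {self.failed}",
        ]
        if len(self.ledger):
            per_chan = self.ledger.groupby("channel").agg(
                n_pulses=("pulse", "size"),
                mean_abs_corr=("correlation", lambda s: float(np.mean(np.abs(s)))),
                mean_scale=("scale", "mean"),
            )
            lines.append("")
            lines.append(per_chan.to_string())
        return "\n".join(lines)
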