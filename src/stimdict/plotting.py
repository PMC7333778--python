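"""Plotting helpers: raw-vs-recovered time series and time-frequency panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .containers import EpochedRecording, RecoveryResult
from .postprocess import TimeFrequencyResult


def plot_recovery_panel(
    raw: EpochedRecording,
    result: RecoveryResult,
    channel: int,
    epoch: int = 0,
    tf: TimeFrequencyResult | None = None,
    tf_z: np.ndarray | None = None,
    out_path=None,
):
    """Raw and recovered traces (with artifact windows shaded) plus an
    optional time-frequency panel underneath; saves to ``out_path`` if given.
    """
    n_rows = 2 if tf is not None else 1
    fig, axes = plt.subplots(n_rows, 1, figsize=(10, 4 * n_rows), squeeze=False)
    ax = axes[0][0]
    time = np.arange(raw.n_samples) / raw.fs
    ax.plot(time, raw.data[:, channel, epoch], color="k", lw=0.6, label="raw")
    ax.plot(time, result.recovered.data[:, channel, epoch], color="tab:orange",
            lw=0.6, label="recovered")
    windows = result.ledger
    if len(windows):
        sel = (windows["channel"] == channel) & (windows["epoch"] == epoch)
        for _, row in windows[sel].iterrows():
            ax.axvspan(row["start"] / raw.fs, row["stop"] / raw.fs,
                       color="gray", alpha=0.15, lw=0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("voltage (µV)")
    ax.legend(loc="upper right")
    ax.set_title(f"channel {channel}, epoch {epoch} ({result.method})")

    if tf is not None:
        axtf = axes[1][0]
        values = tf_z if tf_z is not None else tf.amplitude
        mesh = axtf.pcolormesh(tf.bin_times, tf.freqs, values, shading="auto",
                               cmap="RdBu_r")
        fig.colorbar(mesh, ax=axtf,
                     label="z-scored amplitude" if tf_z is not None else "amplitude (µV)")
        axtf.set_xlabel("time (s)")
        axtf.set_ylabel("frequency (Hz)")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
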