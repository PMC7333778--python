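"""Evaluation metrics against synthetic ground truth.

These quantify what the figures of merit for artifact removal are on data
where the clean signal is known: onset detection recall/precision, the
fraction of true artifact energy covered by the detected windows, the
in-window residual after recovery relative to the raw artifact, and spectral
error at a neural frequency of interest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import EpochedRecording
from .postprocess import morlet_tf
from .synth import SyntheticGroundTruth


def window_mask_from_ledger(
    ledger: pd.DataFrame, shape: tuple[int, int, int]
) -> np.ndarray:
    """Boolean (t, c, e) mask of all ledger windows."""
    mask = np.zeros(shape, dtype=bool)
    for _, row in ledger.iterrows():
        mask[int(row["start"]) : int(row["stop"]), int(row["channel"]), int(row["epoch"])] = True
    return mask


def onset_matching(
    true_onsets: list[np.ndarray],
    detected_onsets: list[np.ndarray],
    tol_samples: int = 2,
) -> tuple[float, float]:
    """Greedy one-to-one matching of detected to true onsets within ±tol.

    Returns ``(recall, precision)``.
    """
    n_true = n_det = n_hit = 0
    for truth, det in zip(true_onsets, detected_onsets):
        truth = np.sort(np.asarray(truth))
        det = np.sort(np.asarray(det))
        n_true += truth.size
        n_det += det.size
        used = np.zeros(det.size, dtype=bool)
        for t0 in truth:
            if det.size == 0:
                continue
            dist = np.abs(det - t0)
            dist[used] = tol_samples + 1
            j = int(np.argmin(dist))
            if dist[j] <= tol_samples:
                used[j] = True
                n_hit += 1
    recall = n_hit / n_true if n_true else np.nan
    precision = n_hit / n_det if n_det else np.nan
    return recall, precision


def artifact_energy_capture(
    truth: SyntheticGroundTruth, mask: np.ndarray, channels: list[int]
) -> float:
    """Fraction of ground-truth artifact energy inside detected windows."""
    art = truth.artifact[:, channels, :]
    m = mask[:, channels, :]
    total = float(np.sum(art**2))
    if total == 0:
        return np.nan
    return float(np.sum((art * m) ** 2) / total)


def in_window_rms(x: np.ndarray, mask: np.ndarray, channels: list[int]) -> float:
    m = mask[:, channels, :]
    if not m.any():
        return np.nan
    return float(np.sqrt(np.mean(x[:, channels, :][m] ** 2)))


def recovery_metrics(
    rec: EpochedRecording,
    recovered: EpochedRecording,
    truth: SyntheticGroundTruth,
    mask: np.ndarray,
    channels: list[int] | None = None,
) -> dict:
    """Residual-vs-artifact summary inside the detected windows.

    ``residual`` is recovered − clean (what remains of the artifact plus any
    damage to the neural signal); ``artifact_rms`` is the raw in-window
    artifact level. ``rms_reduction`` = 1 − residual/artifact.
    """
    channels = channels if channels is not None else rec.recording_channels
    residual = recovered.data - truth.clean
    raw_art = rec.data - truth.clean
    res_rms = in_window_rms(residual, mask, channels)
    art_rms = in_window_rms(raw_art, mask, channels)
    return {
        "residual_rms": res_rms,
        "artifact_rms": art_rms,
        "rms_reduction": 1.0 - res_rms / art_rms if art_rms else np.nan,
        "residual_ratio": res_rms / art_rms if art_rms else np.nan,
    }


def spectral_error_at(
    recovered: EpochedRecording,
    truth: SyntheticGroundTruth,
    freq_hz: float,
    channel: int,
    time_window: tuple[float, float] | None = None,
) -> float:
    """Mean absolute Morlet-amplitude error at one frequency, across epochs.

    Compares the recovered and clean signals' time-resolved amplitude at
    ``freq_hz`` on one channel, optionally restricted to a time window
    (seconds) — e.g. the stimulation train.
    """
    freqs = np.array([freq_hz])
    errs = []
    for ep in range(recovered.n_epochs):
        tf_rec = morlet_tf(recovered.data[:, channel, ep], recovered.fs, freqs=freqs)
        tf_clean = morlet_tf(truth.clean[:, channel, ep], recovered.fs, freqs=freqs)
        sel = tf_rec.valid[0]
        if time_window is not None:
            t0, t1 = time_window
            sel = sel & (tf_rec.bin_times >= t0) & (tf_rec.bin_times < t1)
        errs.append(np.abs(tf_rec.amplitude[0, sel] - tf_clean.amplitude[0, sel]).mean())
    return float(np.mean(errs))
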