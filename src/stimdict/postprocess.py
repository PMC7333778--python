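"""Post-processing of recovered signals: re-referencing, Morlet
time-frequency decomposition and baseline normalisation.

The time-frequency transform uses real-valued (non-analytic) Morlet kernels —
cosine-windowed Gaussians of a fixed number of cycles per frequency — with
amplitude taken as the magnitude of the band-passed signal's analytic
envelope, averaged into fixed-width time bins. Bins within half a kernel
length of the epoch edges are flagged invalid (edge effects grow toward low
frequencies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, hilbert

from .containers import EpochedRecording

logger = logging.getLogger(__name__)


def common_average_rereference(
    rec: EpochedRecording, exclude: set[int] | None = None
) -> EpochedRecording:
    """Subtract the across-channel mean (CAR) from every included channel.

    Stimulation channels and any ``exclude`` set are left out of both the
    average and the re-referencing; they pass through unchanged. Idempotent:
    applying CAR twice equals applying it once.
    """
    excluded = set(rec.stim_channels) | (exclude or set())
    included = [c for c in range(rec.n_channels) if c not in excluded]
    if len(included) < 2:
        raise ValueError(
            f"common average reference needs >= 2 included channels; got {len(included)}"
        )
    out = rec.copy()
    mean = out.data[:, included, :].mean(axis=1, keepdims=True)
    out.data[:, included, :] -= mean
    return out


@dataclass
class TimeFrequencyResult:
    """Binned Morlet amplitude: (n_freqs, n_bins), with axis metadata."""

    amplitude: np.ndarray
    freqs: np.ndarray
    bin_times: np.ndarray  # bin centres, seconds from trace start
    valid: np.ndarray  # bool (n_freqs, n_bins); False near epoch edges

    def z_against_baseline(
        self, baseline: tuple[float, float] | None = None
    ) -> np.ndarray:
        return zscore_normalize_tf(self, baseline)


def _morlet_kernel(f: float, fs: float, n_cycles: float) -> np.ndarray:
    """Real Morlet kernel at frequency ``f``: cosine × Gaussian envelope.

    Normalised so a unit-amplitude tone at ``f`` yields envelope amplitude
    ≈ 1.
    """
    sigma_t = n_cycles / (2.0 * np.pi * f)
    half = int(np.ceil(3.5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kernel = np.cos(2.0 * np.pi * f * t) * envelope
    # convolving cos(2πft) with the kernel gives amplitude (1/2)·Σ envelope/fs·...
    kernel /= envelope.sum() / 2.0
    return kernel


def morlet_tf(
    trace: np.ndarray,
    fs: float,
    freqs: np.ndarray | None = None,
    time_bin_ms: float = 10.0,
    n_cycles: float = 7.0,
) -> TimeFrequencyResult:
    """Time-frequency amplitude of a 1-D trace via real Morlet wavelets.

    Parameters
    ----------
    freqs : array or None
        Frequencies in Hz; default 5–300 Hz in 1 Hz steps.
    time_bin_ms : float
        Width of the time bins the instantaneous amplitude is averaged into.
    n_cycles : float
        Cycles per wavelet (fixed across frequencies).
    """
    trace = np.asarray(trace, dtype=np.float64)
    if freqs is None:
        freqs = np.arange(5.0, 301.0, 1.0)
    freqs = np.asarray(freqs, dtype=np.float64)
    if fs < 2.0 * freqs.max():
        raise ValueError(
            f"fs={fs:g} Hz cannot resolve {freqs.max():g} Hz (needs fs >= 2*fmax)"
        )
    bin_len = max(1, int(round(time_bin_ms * fs / 1000.0)))
    n_bins = trace.size // bin_len
    if n_bins == 0:
        raise ValueError("trace shorter than one time bin")
    usable = n_bins * bin_len

    amplitude = np.empty((freqs.size, n_bins))
    valid = np.ones((freqs.size, n_bins), dtype=bool)
    bin_centres_samples = (np.arange(n_bins) + 0.5) * bin_len
    for i, f in enumerate(freqs):
        kernel = _morlet_kernel(f, fs, n_cycles)
        # a kernel longer than the trace is allowed; every bin of that band
        # is then flagged invalid by the edge mask below
        band = fftconvolve(trace, kernel, mode="same")
        env = np.abs(hilbert(band))
        amplitude[i] = env[:usable].reshape(n_bins, bin_len).mean(axis=1)
        half = kernel.size // 2
        valid[i] = (bin_centres_samples >= half) & (bin_centres_samples < trace.size - half)
    return TimeFrequencyResult(
        amplitude=amplitude,
        freqs=freqs,
        bin_times=bin_centres_samples / fs,
        valid=valid,
    )


def zscore_normalize_tf(
    tf: TimeFrequencyResult, baseline: tuple[float, float] | None = None
) -> np.ndarray:
    """Z-score each frequency band against a baseline period (or whole trial).

    ``baseline=(t0, t1)`` selects bins whose centres fall in [t0, t1) seconds
    (e.g. 800 ms to 5 ms before stimulation onset); ``None`` normalises each
    band against the whole trial — for paradigms with no consistent baseline.
    Bands with zero baseline deviation are set to 0.
    """
    if baseline is None:
        sel = np.ones(tf.bin_times.size, dtype=bool)
    else:
        t0, t1 = baseline
        sel = (tf.bin_times >= t0) & (tf.bin_times < t1)
        if not sel.any():
            raise ValueError(f"no time bins inside baseline window {baseline}")
    mean = tf.amplitude[:, sel].mean(axis=1, keepdims=True)
    std = tf.amplitude[:, sel].std(axis=1, keepdims=True)
    z = np.zeros_like(tf.amplitude)
    ok = std[:, 0] > 0
    if not ok.all():
        logger.debug("zero baseline std in %d bands; set to 0", int((~ok).sum()))
    z[ok] = (tf.amplitude[ok] - mean[ok]) / std[ok]
    return z


def average_epochs(rec: EpochedRecording) -> np.ndarray:
    """Arithmetic mean across epochs; returns a (t, c) array."""
    return rec.data.mean(axis=2)
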