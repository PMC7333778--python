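"""Synthetic stimulation-contaminated recordings with full ground truth.

The generator emulates the recording regimes the method targets: constant-
current biphasic 200 Hz ECoG trains, non-uniform-amplitude trains (two high
pulses then 38 low ones), monophasic 185 Hz DBS trains at four voltages, and
an under-sampled failure regime at 1221 Hz. Pulses are rectangular lobes with
a finite slew rate and an exponential recovery tail, sampled at a per-pulse
sub-sample phase drawn from a small discrete set — mimicking partially
synchronised stimulation/recording clocks, which is what produces the small
number of distinct recorded artifact morphologies that clustering must
discover. The under-sampled preset draws phases continuously, so no distinct
morphologies exist by construction.

Everything is a pure function of (parameters, seed); ``observed`` is exactly
``clean + artifact``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import EpochedRecording

logger = logging.getLogger(__name__)


@dataclass
class ProtocolPreset:
    """One stimulation protocol: train timing, pulse shape and amplitudes."""

    name: str
    fs: float
    stim_hz: float
    train_ms: float
    pulse_width_us: float
    mode: str  # "biphasic" | "monophasic"
    epoch_ms: float
    train_start_ms: float
    n_epochs: int
    #: relative pulse amplitude per pulse within the train (length = n_pulses)
    #: or a single level; DBS-style per-epoch levels via ``epoch_levels``.
    amplitude_pattern: tuple[float, ...] = (1.0,)
    #: per-epoch amplitude level (cycled in blocks); None → all 1.0
    epoch_levels: tuple[float, ...] | None = None
    epochs_per_level: int = 1
    n_phases: int = 4
    phase_continuous: bool = False
    #: exponential recovery tail after the pulse; DBS-style artifacts decay
    #: slowly back to baseline, ECoG-train artifacts are brief
    tau_tail: float = 300e-6
    tail_frac: float = 0.05

    @property
    def n_pulses(self) -> int:
        return int(np.floor(self.train_ms / 1000.0 * self.stim_hz))


def _make_presets() -> dict[str, ProtocolPreset]:
    return {
        # 200 Hz, biphasic 200 µs, 2 mA-like, 400 ms trains (haptic-touch regime)
        "uniform_s1": ProtocolPreset(
            name="uniform_s1", fs=12207.0, stim_hz=200.0, train_ms=400.0,
            pulse_width_us=200.0, mode="biphasic", epoch_ms=1000.0,
            train_start_ms=300.0, n_epochs=10,
        ),
        # two 3 mA pulses then 38 at 1.5 mA, 200 ms total
        "nonuniform": ProtocolPreset(
            name="nonuniform", fs=12207.0, stim_hz=200.0, train_ms=200.0,
            pulse_width_us=200.0, mode="biphasic", epoch_ms=800.0,
            train_start_ms=300.0, n_epochs=10,
            amplitude_pattern=(2.0, 2.0) + (1.0,) * 38,
        ),
        # 1.5 mA, 200 ms trains during self-paced movement
        "button_press": ProtocolPreset(
            name="button_press", fs=12207.0, stim_hz=200.0, train_ms=200.0,
            pulse_width_us=200.0, mode="biphasic", epoch_ms=800.0,
            train_start_ms=300.0, n_epochs=10,
        ),
        # 185 Hz monophasic 60 µs, 500 ms; 15 epochs at each of 4 voltages
        "dbs": ProtocolPreset(
            name="dbs", fs=12207.0, stim_hz=185.0, train_ms=500.0,
            pulse_width_us=60.0, mode="monophasic", epoch_ms=1000.0,
            train_start_ms=300.0, n_epochs=60,
            epoch_levels=(0.5, 2.0 / 3.0, 5.0 / 6.0, 1.0), epochs_per_level=15,
            tau_tail=1e-3, tail_frac=0.3,
        ),
        # 1221 Hz acquisition: 200 µs pulses span < 1 sample → failure regime
        "undersampled": ProtocolPreset(
            name="undersampled", fs=1221.0, stim_hz=100.0, train_ms=400.0,
            pulse_width_us=200.0, mode="biphasic", epoch_ms=1000.0,
            train_start_ms=300.0, n_epochs=10, phase_continuous=True,
        ),
    }


PRESETS = _make_presets()


@dataclass
class SyntheticGroundTruth:
    """Ground truth accompanying a synthetic recording.

    ``observed = clean + artifact`` exactly. ``pulse_onsets[e]`` are the true
    first artifact samples of each pulse in epoch ``e`` (strictly increasing);
    ``shape_ids[e]`` give each pulse's true morphology identity (-1 for
    injected outliers or continuous-phase pulses with no discrete identity).
    """

    clean: np.ndarray
    artifact: np.ndarray
    pulse_onsets: list[np.ndarray]
    shape_ids: list[np.ndarray]
    fs: float
    params: dict = field(default_factory=dict)

    def artifact_recording(self, stim_channels=(0, 1)) -> EpochedRecording:
        return EpochedRecording(self.artifact, fs=self.fs, stim_channels=stim_channels)


# --- continuous-time pulse waveform ----------------------------------------

def _smoothed_step(tau: np.ndarray, t0: float, tau_slew: float) -> np.ndarray:
    x = tau - t0
    return np.where(x > 0, 1.0 - np.exp(-np.maximum(x, 0) / tau_slew), 0.0)


def pulse_waveform(
    tau: np.ndarray,
    amplitude: float,
    width_s: float,
    mode: str = "biphasic",
    tau_slew: float = 20e-6,
    tau_tail: float = 300e-6,
    tail_frac: float = 0.05,
    lobe_ratio: float = 0.85,
    tau_sag: float = 250e-6,
) -> np.ndarray:
    """Evaluate one stimulation-pulse artifact at continuous times ``tau``.

    Rectangular lobes of ``width_s`` convolved with an exponential slew-rate
    kernel (time constant ``tau_slew``), multiplied by a capacitive sag
    ``exp(-tau/tau_sag)``, followed by an exponential recovery tail of
    relative amplitude ``tail_frac`` and time constant ``tau_tail``. ``tau``
    is time since pulse onset, in seconds. The recorded second lobe of a
    biphasic pulse is attenuated by ``lobe_ratio`` (< 1): AC coupling and
    electrode polarization leave the recorded artifact asymmetric even for a
    charge-balanced stimulus, so one lobe dominates the recorded peak, and
    the sag makes that peak sharp rather than a flat plateau.
    """
    tau = np.asarray(tau, dtype=np.float64)
    s = _smoothed_step
    if mode == "biphasic":
        body = s(tau, 0.0, tau_slew) - (1.0 + lobe_ratio) * s(tau, width_s, tau_slew) \
            + lobe_ratio * s(tau, 2.0 * width_s, tau_slew)
        t_end = 2.0 * width_s
        tail_sign = -1.0
    elif mode == "monophasic":
        body = s(tau, 0.0, tau_slew) - s(tau, width_s, tau_slew)
        t_end = width_s
        tail_sign = 1.0
    else:
        raise ValueError(f"unknown pulse mode {mode!r}")
    body = body * np.exp(-np.maximum(tau, 0.0) / tau_sag)
    tail = np.where(
        tau > t_end,
        tail_sign * tail_frac * np.exp(-np.maximum(tau - t_end, 0) / tau_tail),
        0.0,
    )
    return amplitude * (body + tail)


# --- background (neural stand-in) ------------------------------------------

def generate_background(
    t: int,
    c: int,
    e: int,
    fs: float,
    seed: int | np.random.Generator,
    rms: float = 5.0,
    alpha: float = 1.0,
    oscillation_hz: float = 100.0,
    oscillation_amp: float = 0.0,
    common_mode_hz: float = 60.0,
    common_mode_amp: float = 0.0,
) -> np.ndarray:
    """Per-channel 1/f^α noise plus optional band oscillation and common mode.

    A statistical stand-in for neural data: channels are independent pink
    noise of the given RMS (µV), optionally with a narrowband oscillation
    (random phase per channel/epoch) and a shared common-mode sinusoid for
    re-referencing tests.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(t, d=1.0 / fs)
    shape_f = np.zeros_like(freqs)
    shape_f[1:] = freqs[1:] ** (-alpha / 2.0)
    out = np.empty((t, c, e))
    time = np.arange(t) / fs
    for ep in range(e):
        for ch in range(c):
            spec = shape_f * (rng.standard_normal(freqs.size)
                              + 1j * rng.standard_normal(freqs.size))
            x = np.fft.irfft(spec, n=t)
            x *= rms / max(x.std(), 1e-30)
            if oscillation_amp > 0:
                x = x + oscillation_amp * np.sin(
                    2 * np.pi * oscillation_hz * time + rng.uniform(0, 2 * np.pi)
                )
            out[:, ch, ep] = x
        if common_mode_amp > 0:
            cm = common_mode_amp * np.sin(
                2 * np.pi * common_mode_hz * time + rng.uniform(0, 2 * np.pi)
            )
            out[:, :, ep] += cm[:, None]
    return out


def add_evoked(
    clean: np.ndarray,
    pulse_onsets: list[np.ndarray],
    fs: float,
    amplitude: float = 10.0,
    latency_ms: float = 2.0,
    tau_ms: float = 3.0,
    channel_gains: np.ndarray | None = None,
) -> np.ndarray:
    """Add a damped evoked transient after each pulse (rapid-EP regime).

    The transient is an alpha function ``A·(t/τ)·exp(1 − t/τ)`` starting
    ``latency_ms`` after each pulse onset.
    """
    t, c, e = clean.shape
    out = clean.copy()
    lat = int(round(latency_ms * fs / 1000.0))
    support = int(round(8 * tau_ms * fs / 1000.0))
    tt = np.arange(support) / fs / (tau_ms / 1000.0)
    shape = amplitude * tt * np.exp(1.0 - tt)
    gains = np.ones(c) if channel_gains is None else channel_gains
    for ep in range(e):
        for onset in pulse_onsets[ep]:
            lo = onset + lat
            hi = min(t, lo + support)
            if lo >= t:
                continue
            out[lo:hi, :, ep] += shape[: hi - lo, None] * gains[None, :]
    return out


# --- artifact trains --------------------------------------------------------

def channel_gain_profile(
    n_channels: int, stim_channels: tuple[int, int], decay_channels: float = 3.0,
    stim_gain: float = 3.0,
) -> np.ndarray:
    """Artifact gain per channel, decaying with distance from the stim pair.

    The recording channel adjacent to the stimulation pair has gain 1;
    stimulation channels themselves carry ``stim_gain``.
    """
    gains = np.empty(n_channels)
    for ch in range(n_channels):
        if ch in stim_channels:
            gains[ch] = stim_gain
        else:
            d = min(abs(ch - s) for s in stim_channels) - 1
            gains[ch] = np.exp(-d / decay_channels)
    return gains


def generate_artifact_train(
    preset: str | ProtocolPreset,
    seed: int | np.random.Generator,
    n_channels: int = 8,
    stim_channels: tuple[int, int] = (0, 1),
    peak_amplitude: float = 500.0,
    channel_gains: np.ndarray | None = None,
    n_outliers: int = 0,
    n_epochs: int | None = None,
    n_phases: int | None = None,
    tau_slew: float = 20e-6,
    tau_tail: float | None = None,
    tail_frac: float | None = None,
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray], ProtocolPreset]:
    """Simulate the artifact-only signal for one protocol preset.

    Returns ``(artifact, pulse_onsets, shape_ids, preset)`` where ``artifact``
    is (t, c, e) in µV, onsets are true first-artifact-sample indices per
    epoch and shape_ids the true morphology identity per pulse (phase ×
    amplitude-level; -1 for outliers or continuous phases).

    ``peak_amplitude`` is the single-lobe amplitude (µV) at the gain-1
    channel for relative amplitude 1. ``n_outliers`` pulses (drawn across all
    epochs) are replaced by mutually distinct deviant morphologies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            )
        preset = PRESETS[preset]
    if n_epochs is not None:
        preset = replace(preset, n_epochs=n_epochs)
    if n_phases is not None:
        preset = replace(preset, n_phases=n_phases)
    if tau_tail is None:
        tau_tail = preset.tau_tail
    if tail_frac is None:
        tail_frac = preset.tail_frac
    fs = preset.fs
    t = int(round(preset.epoch_ms * fs / 1000.0))
    e = preset.n_epochs
    width_s = preset.pulse_width_us * 1e-6
    n_pulses = preset.n_pulses
    if channel_gains is None:
        channel_gains = channel_gain_profile(n_channels, stim_channels)
    channel_gains = np.asarray(channel_gains, dtype=np.float64)

    # relative amplitude of each pulse in each epoch
    if len(preset.amplitude_pattern) == 1:
        within = np.full(n_pulses, preset.amplitude_pattern[0])
    else:
        if len(preset.amplitude_pattern) != n_pulses:
            raise ValueError("amplitude_pattern length must match pulse count")
        within = np.asarray(preset.amplitude_pattern, dtype=np.float64)
    levels = sorted(set(within))
    if preset.epoch_levels is not None:
        epoch_level = [
            preset.epoch_levels[(ep // preset.epochs_per_level) % len(preset.epoch_levels)]
            for ep in range(e)
        ]
        levels = sorted(set(preset.epoch_levels))
    else:
        epoch_level = [1.0] * e

    # support long enough for the tail to die out
    support = int(round((2 * width_s + 8 * tau_tail) * fs)) + 4

    n_phase_bins = preset.n_phases
    period = 1.0 / fs
    artifact = np.zeros((t, n_channels, e))
    onsets_per_epoch: list[np.ndarray] = []
    shape_ids_per_epoch: list[np.ndarray] = []

    # choose outlier pulses across the whole recording
    all_idx = [(ep, p) for ep in range(e) for p in range(n_pulses)]
    outlier_set: dict[tuple[int, int], int] = {}
    if n_outliers > 0:
        chosen = rng.choice(len(all_idx), size=min(n_outliers, len(all_idx)),
                            replace=False)
        outlier_set = {all_idx[i]: rank for rank, i in enumerate(chosen)}

    for ep in range(e):
        onsets = np.empty(n_pulses, dtype=np.int64)
        sids = np.empty(n_pulses, dtype=np.int64)
        wave = np.zeros(t)
        for p in range(n_pulses):
            t_pulse = preset.train_start_ms / 1000.0 + p / preset.stim_hz
            if preset.phase_continuous:
                phase = rng.uniform(0.0, period)
                sid = -1
            else:
                phase_idx = int(rng.integers(n_phase_bins))
                phase = phase_idx * period / n_phase_bins
                sid = phase_idx + n_phase_bins * _level_index(
                    levels, within[p], epoch_level[ep], preset
                )
            # partially synchronised clocks: each pulse lands on the recording
            # sample grid plus one of a small set of sub-sample phases
            t0 = np.round(t_pulse * fs) / fs + phase
            onset = int(np.floor(t0 * fs)) + 1
            if onset >= t:
                raise ValueError("pulse train does not fit in the epoch")
            hi = min(t, onset + support)
            samples = np.arange(onset, hi)
            tau = samples / fs - t0
            amp = peak_amplitude * within[p] * epoch_level[ep]
            if (ep, p) in outlier_set:
                # deviant pulses are heterogeneous (glitches, connector pops,
                # movement): each is a damped oscillation with its own
                # frequency, phase, decay and polarity, so outliers resemble
                # neither the core clusters nor one another
                # deviant pulse: superposition of random Gabor atoms (random
                # centre, frequency, width, polarity), so outliers resemble
                # neither the core morphologies nor one another even after
                # peak alignment; amplitudes additionally spread over octaves
                rank = outlier_set[(ep, p)]
                amp_o = amp * 1.5 * 2.0 ** (rank % 3)
                glitch = np.zeros_like(tau)
                for _ in range(3):
                    c = rng.uniform(0.0, 1.2e-3)
                    f_o = rng.uniform(800.0, min(2500.0, 0.4 * fs))
                    sigma_o = rng.uniform(0.08e-3, 0.25e-3)
                    glitch += (
                        rng.uniform(0.3, 1.0) * rng.choice([-1.0, 1.0])
                        * np.sin(2 * np.pi * f_o * (tau - c) + rng.uniform(0, 2 * np.pi))
                        * np.exp(-((tau - c) ** 2) / (2 * sigma_o**2))
                    )
                wave[onset:hi] += amp_o * glitch * (tau > 0)
                sid = -1
            else:
                wave[onset:hi] += pulse_waveform(
                    tau, amp, width_s, mode=preset.mode,
                    tau_slew=tau_slew, tau_tail=tau_tail, tail_frac=tail_frac,
                )
            onsets[p] = onset
            sids[p] = sid
        artifact[:, :, ep] = wave[:, None] * channel_gains[None, :]
        onsets_per_epoch.append(onsets)
        shape_ids_per_epoch.append(sids)
    return artifact, onsets_per_epoch, shape_ids_per_epoch, preset


def _level_index(levels, within_amp, epoch_amp, preset: ProtocolPreset) -> int:
    """Index of a pulse's amplitude level within the preset's level set."""
    if preset.epoch_levels is not None:
        return levels.index(min(levels, key=lambda l: abs(l - epoch_amp)))
    return levels.index(min(levels, key=lambda l: abs(l - within_amp)))


def compose(
    clean: np.ndarray,
    artifact: np.ndarray,
    pulse_onsets: list[np.ndarray],
    shape_ids: list[np.ndarray],
    fs: float,
    stim_channels: tuple[int, int] = (0, 1),
    params: dict | None = None,
) -> tuple[EpochedRecording, SyntheticGroundTruth]:
    """Sum clean and artifact signals into the observed recording (additive)."""
    if clean.shape != artifact.shape:
        raise ValueError(
            f"shape mismatch: clean {clean.shape} vs artifact {artifact.shape}"
        )
    observed = clean + artifact
    rec = EpochedRecording(observed, fs=fs, stim_channels=stim_channels)
    truth = SyntheticGroundTruth(
        clean=clean, artifact=artifact, pulse_onsets=pulse_onsets,
        shape_ids=shape_ids, fs=fs, params=params or {},
    )
    return rec, truth


def simulate(
    preset: str | ProtocolPreset = "uniform_s1",
    seed: int = 0,
    n_channels: int = 8,
    stim_channels: tuple[int, int] = (0, 1),
    n_epochs: int | None = None,
    background_rms: float = 5.0,
    artifact_to_neural: float = 100.0,
    oscillation_amp: float = 0.0,
    oscillation_hz: float = 100.0,
    common_mode_amp: float = 0.0,
    evoked_amp: float = 0.0,
    n_outliers: int = 0,
    n_phases: int | None = None,
    channel_gains: np.ndarray | None = None,
) -> tuple[EpochedRecording, SyntheticGroundTruth]:
    """Generate a full synthetic recording plus ground truth for one preset.

    The artifact's single-lobe peak at the strongest recording channel is
    ``artifact_to_neural × background_rms`` µV (default 100:1 — artifacts
    orders of magnitude above the neural stand-in).
    """
    rng = np.random.default_rng(seed)
    artifact, onsets, sids, preset_obj = generate_artifact_train(
        preset, rng, n_channels=n_channels, stim_channels=stim_channels,
        peak_amplitude=artifact_to_neural * background_rms,
        channel_gains=channel_gains, n_outliers=n_outliers, n_epochs=n_epochs,
        n_phases=n_phases,
    )
    t, c, e = artifact.shape
    clean = generate_background(
        t, c, e, preset_obj.fs, rng, rms=background_rms,
        oscillation_hz=oscillation_hz, oscillation_amp=oscillation_amp,
        common_mode_amp=common_mode_amp,
    )
    if evoked_amp > 0:
        clean = add_evoked(clean, onsets, preset_obj.fs, amplitude=evoked_amp)
    params = {
        "preset": preset_obj.name, "seed": seed, "n_channels": n_channels,
        "background_rms": background_rms, "artifact_to_neural": artifact_to_neural,
        "oscillation_amp": oscillation_amp, "oscillation_hz": oscillation_hz,
        "n_outliers": n_outliers,
    }
    return compose(clean, artifact, onsets, sids, preset_obj.fs,
                   stim_channels=stim_channels, params=params)
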