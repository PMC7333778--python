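"""Tunable parameters of the detection and clustering stages.

Defaults are the values that work across the ECoG grid protocols (200 Hz
biphasic trains sampled at 12 207 Hz): a 3rd-order, 7-sample Savitzky-Golay
smoother, an absolute z-score onset threshold of 1.5, a 0.8 ms pre-onset
window, 75% offset-decay cutoffs, 1 ms of post-artifact padding and a
3-sample baseline. Clustering defaults (k=2, n=3, θ=0.9) suit protocols with
a handful of well-separated artifact morphologies; denser datasets may prefer
k=15, n=10, θ=0.95.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class DetectionParams:
    """Parameters of pulse-onset detection and per-pulse window estimation.

    Attributes
    ----------
    sg_order, sg_window : int
        Savitzky-Golay polynomial order and (odd) window length in samples.
    onset_z_threshold : float
        Absolute z-score threshold for pulse-onset detection on the epoched,
        smoothed reference trace.
    pre_window_ms : float
        Time included before each detected onset, ms.
    offset_pct_voltage, offset_pct_derivative : float
        Percentage cutoffs in (0, 100] for artifact-offset estimation on the
        smoothed voltage and its first difference. The artifact is taken to
        end where |z| has decayed below (1 - pct/100) of its in-segment peak,
        so a higher percentage captures a longer artifact (e.g. a slow
        exponential tail); ``offset_mode="percentile"`` instead thresholds at
        the (100 - pct)-th percentile of |z|.
    post_pad_ms : float
        Extra time appended after the estimated artifact end, ms.
    n_baseline_samples : int
        Number of leading window samples whose mean defines the baseline.
    min_interpulse_ms : float or None
        Onset runs closer than this are merged (both lobes of one biphasic
        pulse count as one event). ``None`` → half the nominal inter-pulse
        interval when ``nominal_stim_hz`` is set, else 2 ms.
    nominal_stim_hz : float or None
        Nominal stimulation frequency, used only to derive the default
        ``min_interpulse_ms``.
    fixed_window : bool
        If True, skip dynamic offset estimation and use
        ``fixed_window_ms`` after each onset for every pulse.
    fixed_window_ms : float
        Window duration after onset when ``fixed_window`` is set.
    offset_mode : str
        "peak-fraction" (default) or "percentile"; see above.
    min_run_samples : int
        Supra-threshold runs shorter than this are discarded as noise.
    """

    sg_order: int = 3
    sg_window: int = 7
    onset_z_threshold: float = 1.5
    pre_window_ms: float = 0.8
    offset_pct_voltage: float = 75.0
    offset_pct_derivative: float = 75.0
    post_pad_ms: float = 1.0
    n_baseline_samples: int = 3
    min_interpulse_ms: float | None = None
    nominal_stim_hz: float | None = None
    fixed_window: bool = False
    fixed_window_ms: float = 2.0
    offset_mode: str = "peak-fraction"
    min_run_samples: int = 2

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError(
                "sg_window must be odd and greater than sg_order; "
                f"got window={self.sg_window}, order={self.sg_order}"
            )
        for name in ("pre_window_ms", "post_pad_ms", "fixed_window_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_baseline_samples < 1:
            raise ValueError("n_baseline_samples must be >= 1")
        for name in ("offset_pct_voltage", "offset_pct_derivative"):
            pct = getattr(self, name)
            if not 0 < pct <= 100:
                raise ValueError(f"{name} must lie in (0, 100]")
        if self.onset_z_threshold <= 0:
            raise ValueError("onset_z_threshold must be positive")
        if self.offset_mode not in ("peak-fraction", "percentile"):
            raise ValueError(f"unknown offset_mode {self.offset_mode!r}")

    def min_interpulse_samples(self, fs: float) -> int:
        ms = self.min_interpulse_ms
        if ms is None:
            if self.nominal_stim_hz:
                ms = 0.5 * 1000.0 / self.nominal_stim_hz
            else:
                ms = 2.0
        return max(1, int(round(ms * fs / 1000.0)))


@dataclass
class ClusteringParams:
    """Parameters of density-based template clustering.

    k is the number of neighbours in the core-distance (density) computation,
    n the minimum cluster size, and theta the outlier-score threshold above
    which a pulse is labelled noise. Feature vectors hold
    ``2 * feature_half_width`` samples flanking (and excluding) the pulse's
    absolute-voltage peak.
    """

    k: int = 2
    n: int = 3
    theta: float = 0.9
    feature_half_width: int = 6
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.feature_half_width < 1:
            raise ValueError("feature_half_width must be >= 1")
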