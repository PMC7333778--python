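# Methods

## Model and assumptions

The recovery model treats a recording during a stimulation train as

    observed(t, c, e) = neural(t, c, e) + artifact(t, c, e)

with three working assumptions: (i) artifacts are **additive** — once
estimated they can be subtracted; (ii) amplifiers do not saturate and the
waveform is oversampled, so each pulse's recorded shape is reproducible;
(iii) artifact **timing** is common to all channels (volume conduction is
effectively instantaneous at these scales), so onsets detected on one
reference channel apply array-wide, while artifact *shape and duration* are
estimated per channel and per pulse.

Within one channel, recorded pulse artifacts fall into a small number of
discrete morphologies. The dominant cause is partial synchronisation of the
stimulation and recording clocks: the stimulator emits identical pulses, but
each is sampled at one of a few sub-sample phases, giving a few distinct
sampled waveforms. Amplitude steps within or across trains add further
morphologies. The algorithm therefore learns a per-channel *dictionary* of
templates by unsupervised clustering rather than a single average.

## Pipeline

### Detection

* Savitzky-Golay smoothing (order 3, window 7 samples ≈ 0.57 ms at
  12 207 Hz) suppresses high-frequency noise for detection only; the
  recovered signal is always computed from the raw data.
* The reference channel is the non-stimulation channel with the largest
  median-across-epochs peak-to-peak smoothed amplitude (ties → lowest index).
* Onsets: the smoothed epoch is z-scored against its own mean/std; runs of
  |z| > 1.5 shorter than 2 samples are discarded (single-sample noise blips
  would otherwise drag a merged run's onset earlier), then runs closer than
  half the nominal inter-pulse interval (default 2 ms) are merged so both
  lobes of a biphasic pulse count once. Each run's first sample is an onset.
* Offsets: within each onset-to-next-onset segment (stopped half a smoothing
  window short of the next onset, where the next pulse's smoothed rise
  already leaks), |z| of the smoothed voltage and of its first difference are
  thresholded at `(1 - pct/100) · max|z|`; the later of the two last
  crossings, plus 1 ms of padding, ends the window. With the default
  pct = 75 the artifact ends where it has decayed to 25% of its peak; pct =
  99 tracks a long exponential tail (appropriate for DBS-style artifacts). A
  literal-percentile mode (`offset_mode="percentile"`) is available; the
  peak-fraction reading is the default because it is the one under which a
  higher percentage captures a *longer* artifact, which is the stated intent,
  and under which offsets are monotone non-decreasing in the percentage.
* Windows open 0.8 ms before onset, are clipped to epoch bounds, truncated at
  the next window's start if offset estimation overshoots, baseline-corrected
  by the mean of their first 3 samples, and zero-padded per channel to a
  common length.

### Dictionary learning

Each pulse is represented by 12 features: 6 samples on either side of the
padded pulse's absolute-voltage peak (the peak sample itself excluded;
positions off the window edge are zero-filled). All of a channel's pulses are
clustered together with HDBSCAN (scikit-learn backend) using Euclidean
distance, `min_samples = k` core-distance neighbours and minimum cluster
size `n`. Each pulse receives an outlier score in [0, 1] defined as one minus
its cluster-membership strength (points the hierarchy rejects score 1);
pulses scoring above θ are labelled noise. Defaults k = 2, n = 3, θ = 0.9
suit protocols with a handful of well-separated morphologies; k = 15,
n = 10, θ = 0.95 are appropriate for denser, noisier datasets. Fewer than
`n` pulses, or an all-noise channel, falls back to a single cluster /
grand-mean template (logged).

Templates are the mean of each cluster's padded waveforms **after aligning
members at their absolute peaks** (shift to the cluster's median peak index,
zero-filled). Onset detection is amplitude-dependent at the single-sample
level, so members grouped by peak-relative features can sit ±1–2 samples
apart in the window frame; an unaligned mean smears the template peak, which
measurably degrades subtraction on amplitude-varying trains. Noise-labelled
pulses are excluded from the means but still matched and subtracted.

### Matching and subtraction

For each pulse, every template is first shifted so its (demeaned) absolute
peak coincides with the pulse's, then Pearson-correlated with the pulse's
baseline-corrected waveform over the unpadded pulse extent (correlating over
zero-padding would reward matching pad lengths, not artifact shape;
zero-variance inputs define correlation 0). The argmax template (ties →
lowest id) is scaled by `range(pulse) / range(template)` so its peak-to-peak
range equals the pulse's — the range ratio absorbs deliberate or drifting
changes in stimulation amplitude — and subtracted from the **raw** signal
inside `[start, stop)`. Because the template was built from
baseline-corrected waveforms, subtracting it from the raw trace leaves the
window's local DC in place. No edge blending is applied by default (an
optional linear taper of the subtracted template, `edge_blend`, exists and
is off); windows open and close in near-baseline signal, so plain
subtraction leaves no visible discontinuities, and out-of-window samples are
bit-identical to the input by construction.

The per-pulse ledger records channel, epoch, pulse, window, chosen template,
correlation and scale, and is serialized with the recovered array.

### Run-quality (FAILED) flag

The paper-level failure mode — stimulation waveforms too poorly resolved for
template learning — is detected at run time without ground truth from the
dictionary itself: a run is flagged FAILED when the mean |match correlation|
falls below 0.96 or more than half the pulses are labelled noise. The
boundary sits between the two simulated populations: every well-resolved
protocol yields mean |correlation| ≥ 0.985 (the monophasic DBS regime is the
lowest), while the under-sampled regime stays ≤ 0.94.

### Baselines

* **Interpolation**: monotone piecewise-cubic (PCHIP) through 3 flank
  samples on each side of every window; windows abutting an epoch edge use
  nearest-value fill. Locally plausible in the time domain but erases any
  neural signal inside the windows — its spectral error at a simulated
  oscillation frequency exceeds the dictionary method's.
* **Low-pass**: zero-phase (forward-backward) 4th-order Butterworth across
  the entire train; the only method that modifies out-of-window samples.
* **Epoch-average / global-average template**: unscaled subtraction of the
  mean pulse per epoch (or over all epochs). Adequate for uniform,
  single-morphology trains; fails by construction on non-uniform amplitudes.

### Post-processing

Common-average re-referencing over non-stimulation channels (idempotent;
excluded channels pass through). Time-frequency amplitude uses real
(non-analytic) Morlet kernels — cosine × Gaussian, 7 cycles per frequency,
normalised so a unit tone has unit envelope — with amplitude taken as the
magnitude of the band-passed signal's analytic envelope, averaged into 10 ms
bins over a 5–300 Hz, 1 Hz-step grid by default. Bins within half a kernel
length of the epoch edges are flagged invalid (the 7-cycle choice and the
flag matter mostly below ~20 Hz). Z-scoring is per frequency band against a
pre-stimulus baseline window (e.g. 800 ms to 5 ms before onset) or, for
paradigms without a consistent baseline, against the whole trial;
zero-variance bands map to 0.

## Synthetic study conditions

The generator is the package's validation instrument; its defaults encode
the recording regimes the method targets.

| preset | fs (Hz) | train | pulse | amplitudes | epochs |
|---|---|---|---|---|---|
| `uniform_s1` | 12 207 | 200 Hz × 400 ms (80 pulses) | biphasic 200 µs | constant | 10 |
| `nonuniform` | 12 207 | 200 Hz × 200 ms (40 pulses) | biphasic 200 µs | 2 high (2×) + 38 low | 10 |
| `button_press` | 12 207 | 200 Hz × 200 ms | biphasic 200 µs | constant | 10 |
| `dbs` | 12 207 | 185 Hz × 500 ms (92 pulses) | monophasic 60 µs | 4 levels × 15 epochs | 60 |
| `undersampled` | 1 221 | 100 Hz × 400 ms | biphasic 200 µs | constant | 10 |

Pulse artifacts are rectangular lobes passed through an exponential
slew-rate kernel (τ = 20 µs), multiplied by a capacitive sag
(τ = 250 µs) and followed by an exponential recovery tail (5% of peak,
τ = 300 µs; the DBS preset uses 30% and τ = 1 ms to reproduce slow
recovery). The recorded second lobe of a biphasic pulse is attenuated
(×0.85): amplifier coupling and electrode polarization leave recorded
artifacts asymmetric, which also gives each waveform a sharp, unambiguous
absolute peak. Each pulse lands on the recording sample grid plus one of
S = 4 discrete sub-sample phases (partial clock synchronisation) — these
phases *are* the morphology clusters; the under-sampled preset draws phases
continuously so no discrete clusters exist, reproducing the failure regime.
Artifact gain decays across channels as `exp(-d/3)` in units of
channel distance from the stimulation pair; stimulation channels carry 3×.
The single-lobe peak at the strongest recording channel defaults to 100× the
background RMS ("orders of magnitude" regime; configurable).

The neural stand-in is per-channel 1/f (pink) noise of 5 µV RMS, optionally
with a narrowband oscillation (100 Hz default; used at 5 µV in the
method-comparison benchmarks), a shared common-mode sinusoid for
re-referencing tests, and an alpha-function evoked transient 2 ms after each
pulse for the rapid-evoked-potential regime. Injected outlier pulses are
superpositions of three random Gabor atoms (random centre, frequency
0.8–2.5 kHz, width, polarity) with amplitudes spread over octaves: deviant
events in real recordings (glitches, pops, movement) resemble neither the
core artifact nor one another, and any three mutually-similar deviants would
correctly be discovered as a cluster by a density-based method rather than
labelled noise.

What the generator does **not** emulate: non-stationary artifact drift
within a recording, train-onset/offset capacitive transients, saturation,
correlated neural activity across channels, and non-Gaussian within-cluster
variability. Passing tests therefore demonstrate the algorithm's contracts
(detection accuracy, cluster recovery, subtraction fidelity, failure
flagging) under controlled conditions, not performance on any particular
real dataset.

## Numerical choices and degenerate inputs

* float64 throughout; all indices 0-based, windows half-open.
* Onset/offset z-scores use the epoch's (respectively segment's) own
  mean/std; flat traces yield no detections rather than errors.
* Reference-channel ties break to the lowest index; template-match ties to
  the lowest template id (both logged).
* Zero-variance pulses or templates define correlation 0; zero-range
  templates are subtracted unscaled (scale 1).
* Identical-feature degenerate inputs short-circuit to a single cluster with
  zero noise (HDBSCAN is undefined on zero spread).
* Problem sizes in the tests and the acceptance script (6–8 channels, 5–10
  epochs) were chosen as the smallest arrays that exercise every contract —
  channel-distance gain decay, multi-epoch clustering, per-level DBS
  amplitudes — with comfortable statistical margins.

## Known limitations

Single-pulse artifacts only: consistent train-onset/offset transients pass
through unmodified. Clustering inherits density-based caveats — very rare
morphologies (fewer than `n` instances) are labelled noise and recovered
only via the range-scaled best match; raising the feature count increases
the sampling density HDBSCAN needs. The FAILED flag is a heuristic on
dictionary quality, not a proof of recovery fidelity.
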