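"""Model/results interface over the recovery pipeline.

``StimulationArtifactModel`` is built from an :class:`EpochedRecording`;
``fit()`` runs detection, learns the per-channel dictionary of artifact
templates and subtracts the matched, scaled template from every pulse,
returning an :class:`ArtifactRecoveryFit` that carries the recovered
recording, the learned dictionary, the subtraction ledger and run
diagnostics. Baseline methods are available through ``fit(method=...)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import baselines
from .containers import (
    LEDGER_COLUMNS,
    EpochedRecording,
    PulseSet,
    RecoveryResult,
    TemplateDictionary,
)
from .detect import detect_all
from .dictionary import build_dictionary
from .params import ClusteringParams, DetectionParams
from .subtract import subtract_all

METHODS = ("dictionary", "epoch-average", "global-average", "interpolate", "lowpass")


class StimulationArtifactModel:
    """Dictionary-learning artifact-removal model for one epoched recording.

    Parameters
    ----------
    recording : EpochedRecording
        Observed (t, c, e) voltages, in microvolts.
    detection, clustering : parameter bundles
        Stage parameters; defaults are the standard ECoG-train settings.
    """

    def __init__(
        self,
        recording: EpochedRecording,
        detection: DetectionParams | None = None,
        clustering: ClusteringParams | None = None,
    ):
        self.recording = recording
        self.detection = detection or DetectionParams()
        self.clustering = clustering or ClusteringParams()
        self._pulses: PulseSet | None = None
        self._onsets: list[np.ndarray] | None = None
        self._reference_channel: int | None = None

    @classmethod
    def from_file(cls, path, **kwargs) -> "StimulationArtifactModel":
        from .io import read_recording

        return cls(read_recording(path), **kwargs)

    def detect(self) -> PulseSet:
        """Run (and cache) the detection stage."""
        if self._pulses is None:
            self._pulses, self._onsets, self._reference_channel = detect_all(
                self.recording, self.detection
            )
        return self._pulses

    @property
    def onsets_per_epoch(self) -> list[np.ndarray]:
        self.detect()
        return self._onsets

    @property
    def reference_channel(self) -> int:
        self.detect()
        return self._reference_channel

    def fit(self, method: str = "dictionary", lowpass_hz: float = 25.0
            ) -> "ArtifactRecoveryFit":
        """Recover the neural signal with the chosen method."""
        if method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}; got {method!r}")
        if method == "lowpass":
            recovered = baselines.lowpass_filter(self.recording, lowpass_hz)
            result = RecoveryResult(
                recovered=recovered,
                ledger=pd.DataFrame(columns=LEDGER_COLUMNS),
                method="lowpass",
            )
            return ArtifactRecoveryFit(self, result, dictionary=None)

        pulses = self.detect()
        dictionary = None
        if len(pulses) == 0:
            result = RecoveryResult(
                recovered=self.recording.copy(),
                ledger=pd.DataFrame(columns=LEDGER_COLUMNS),
                method=method,
            )
        elif method == "dictionary":
            dictionary = build_dictionary(pulses, self.clustering)
            result = subtract_all(self.recording, pulses, dictionary)
        elif method in ("epoch-average", "global-average"):
            result = baselines.epoch_average_template_subtract(
                self.recording, pulses,
                mode="epoch" if method == "epoch-average" else "global",
            )
        else:  # interpolate
            result = baselines.interpolate_artifact(self.recording, pulses)
        result.diagnostics.setdefault("reference_channel", self._reference_channel)
        return ArtifactRecoveryFit(self, result, dictionary=dictionary)


class ArtifactRecoveryFit:
    """Results of a recovery run: recovered signal, dictionary, diagnostics."""

    def __init__(
        self,
        model: StimulationArtifactModel,
        result: RecoveryResult,
        dictionary: TemplateDictionary | None,
    ):
        self.model = model
        self.result = result
        self.dictionary = dictionary

    @property
    def recovered(self) -> EpochedRecording:
        return self.result.recovered

    @property
    def ledger(self) -> pd.DataFrame:
        return self.result.ledger

    @property
    def failed(self) -> bool:
        return self.result.failed

    @property
    def method(self) -> str:
        return self.result.method

    def summary(self) -> str:
        lines = [self.result.summary()]
        if self.dictionary is not None:
            lines.append("")
            lines.append("templates per channel: "
                         + str(self.dictionary.n_templates_per_channel))
        diag = self.result.diagnostics
        if diag:
            lines.append("diagnostics:")
            for key, value in diag.items():
                if key == "n_templates_per_channel":
                    continue
                lines.append(f"  {key}: {value}")
        return "\n".join(lines)

    def save(self, path) -> None:
        from .io import write_result

        write_result(self.result, path)

    def summary_dict(self) -> dict:
        """Machine-readable per-run summary (JSON-friendly)."""
        diag = self.result.diagnostics
        per_channel = {}
        if len(self.ledger):
            for chan, grp in self.ledger.groupby("channel"):
                per_channel[int(chan)] = {
                    "n_pulses": int(len(grp)),
                    "mean_abs_correlation": float(np.mean(np.abs(grp["correlation"])))
                    if grp["correlation"].notna().any() else None,
                }
        return {
            "method": self.method,
            "failed": bool(self.failed),
            "n_pulses": int(len(self.ledger)),
            "per_channel": per_channel,
            "diagnostics": {k: v for k, v in diag.items()
                            if k != "n_templates_per_channel"},
        }
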