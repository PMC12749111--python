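"""Core data model for DBS-EMG motor evoked potential (mEP) analysis.

A *trial* is one stimulation setting delivered as a low-frequency pulse
train (typically 10 Hz for 12 s) while surface EMG is recorded from up to
eight facial and limb muscles.  The types here carry the raw multi-channel
recording, the pulse-triggered averages derived from it, per-channel
detection outcomes, and the per-setting aggregate mEP score.

All signal values are in microvolts (μV) unless a type says otherwise;
time within an epoch is milliseconds relative to pulse onset, half-open
``[0, 1000 / frequency_hz)``; sample indices are 0-based.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "ValidationError",
    "ChannelMismatchError",
    "PulseTrainError",
    "ContactConfigError",
    "DegenerateBaselineError",
    "StimSetting",
    "MuscleChannel",
    "RawRecording",
    "AnnotationSet",
    "AveragedTrace",
    "ZScoredTrace",
    "ChannelDetection",
    "SettingScore",
    "FACIAL",
    "LIMB",
]

FACIAL = "facial"
LIMB = "limb"

#: Geometric contact grammar: levels 1 (ventral) – 4 (dorsal), optional
#: segment A (anterior) / M (postero-medial) / L (postero-lateral);
#: bipolar configurations join two contacts with "-", e.g. "3A-2A".
_CONTACT_RE = re.compile(r"^[1-4][AML]?(-[1-4][AML]?)?$")


class ValidationError(ValueError):
    """An input object violates one of the documented type invariants."""


class ChannelMismatchError(ValidationError):
    """Channel metadata does not match the signal matrix."""


class PulseTrainError(ValidationError):
    """Pulse onsets are non-monotonic, out of range, or irregular."""


class ContactConfigError(ValidationError):
    """Contact configuration string does not parse against the grammar."""


class DegenerateBaselineError(ValidationError):
    """Baseline window has zero variance; channel cannot be z-scored."""


@dataclass(frozen=True)
class StimSetting:
    """One stimulation setting: current, pulse shape, train and contact.

    Parameters
    ----------
    amplitude_mA : float
        Stimulation current amplitude of the first (high) phase, mA.
    pulse_width_us : float
        First-phase pulse width, μs.
    frequency_hz : float
        Pulse train frequency; low-frequency probing uses 10 Hz so the
        full mEP waveform fits inside one inter-pulse interval.
    duration_s : float
        Stimulation train duration (12 s standard).
    contact_config : str
        Geometric contact name (levels 1–4 ventral→dorsal, segments
        A/M/L), e.g. ``"1"``, ``"2L"``, ``"3A-2A"`` for bipolar.
    setting_id : str
        Opaque identifier of this trial.
    """

    amplitude_mA: float
    pulse_width_us: float = 60.0
    frequency_hz: float = 10.0
    duration_s: float = 12.0
    contact_config: str = "1"
    setting_id: str = ""

    def __post_init__(self) -> None:
        if self.amplitude_mA <= 0:
            raise ValidationError(f"amplitude_mA must be > 0, got {self.amplitude_mA}")
        if self.pulse_width_us <= 0:
            raise ValidationError("pulse_width_us must be > 0")
        if self.frequency_hz <= 0 or self.duration_s <= 0:
            raise ValidationError("frequency_hz and duration_s must be > 0")
        if self.frequency_hz * self.duration_s < 1:
            raise ValidationError("train must contain at least one pulse")
        if not _CONTACT_RE.match(self.contact_config):
            raise ContactConfigError(
                f"contact_config {self.contact_config!r} does not parse "
                "(expected e.g. '1', '2L', '3A-2A')"
            )

    @property
    def n_pulses(self) -> int:
        return int(math.floor(self.frequency_hz * self.duration_s))

    @property
    def epoch_ms(self) -> float:
        """Inter-pulse interval = epoch duration, ms."""
        return 1000.0 / self.frequency_hz


@dataclass(frozen=True)
class MuscleChannel:
    """An EMG channel and the muscle it records.

    ``group`` ('facial' or 'limb') selects the default detection
    threshold (z = 4 facial, z = 7 limb) and the artifact-rejection
    route; ``detection_window_ms`` is the muscle-specific peak latency
    window.
    """

    label: str
    group: str
    laterality: str = "CL"
    detection_window_ms: tuple[float, float] = (5.0, 18.0)

    def __post_init__(self) -> None:
        if self.group not in (FACIAL, LIMB):
            raise ValidationError(f"group must be 'facial' or 'limb', got {self.group!r}")
        if self.laterality not in ("CL", "IL"):
            raise ValidationError(f"laterality must be 'CL' or 'IL', got {self.laterality!r}")
        lo, hi = self.detection_window_ms
        if not (0 < lo < hi):
            raise ValidationError(
                f"detection window must satisfy 0 < low < high, got {self.detection_window_ms}"
            )


@dataclass
class RawRecording:
    """One multi-channel EMG recording for a single stimulation setting."""

    signal: np.ndarray  # [n_channels, n_samples], μV
    fs_hz: float
    pulse_onsets: np.ndarray  # strictly increasing sample indices
    channels: list[MuscleChannel]
    setting: StimSetting
    lead_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.pulse_onsets = np.asarray(self.pulse_onsets, dtype=np.int64)
        self.validate()

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def validate(self) -> None:
        if self.signal.ndim != 2:
            raise ValidationError("signal must be a 2-D [n_channels, n_samples] matrix")
        if self.n_channels != len(self.channels):
            raise ChannelMismatchError(
                f"signal has {self.n_channels} channels but metadata lists {len(self.channels)}"
            )
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz must be > 0")
        on = self.pulse_onsets
        if on.size == 0:
            raise PulseTrainError("pulse_onsets is empty")
        if np.any(on < 0) or np.any(on >= self.n_samples):
            raise PulseTrainError("pulse onsets outside [0, n_samples)")
        if np.any(np.diff(on) <= 0):
            raise PulseTrainError("pulse onsets must be strictly increasing")
        if on.size >= 2:
            expected = self.fs_hz / self.setting.frequency_hz
            spacing = np.diff(on)
            if np.any(np.abs(spacing - expected) > 0.01 * expected):
                raise PulseTrainError(
                    "pulse onset spacing deviates more than 1% from "
                    f"fs/frequency = {expected:.1f} samples"
                )

    def channel_index(self, label: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.label == label:
                return i
        raise KeyError(f"no channel labelled {label!r}")


@dataclass
class AnnotationSet:
    """Ground-truth map (setting_id, channel label) -> mEP present."""

    annotations: dict[tuple[str, str], bool] = field(default_factory=dict)

    def __getitem__(self, key: tuple[str, str]) -> bool:
        return self.annotations[key]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.annotations

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.annotations)

    def get(self, key: tuple[str, str], default: bool | None = None) -> bool | None:
        return self.annotations.get(key, default)

    def update(self, other: Mapping[tuple[str, str], bool]) -> None:
        self.annotations.update(other)


@dataclass
class AveragedTrace:
    """Pulse-triggered average of one channel, μV, t = 0 at pulse onset."""

    values: np.ndarray
    fs_hz: float
    channel: MuscleChannel
    n_pulses_averaged: int
    #: Edge region (ms at each end) zeroed out by filtering, invalid for
    #: detection; 0 when no zero-phase filter was applied.
    edge_trim_ms: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("AveragedTrace values must be 1-D")
        if self.n_pulses_averaged < 1:
            raise ValidationError("n_pulses_averaged must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def epoch_ms(self) -> float:
        return 1000.0 * self.n_samples / self.fs_hz

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.fs_hz

    def copy_with(self, values: np.ndarray, edge_trim_ms: float | None = None) -> "AveragedTrace":
        return AveragedTrace(
            values=np.asarray(values, dtype=float),
            fs_hz=self.fs_hz,
            channel=self.channel,
            n_pulses_averaged=self.n_pulses_averaged,
            edge_trim_ms=self.edge_trim_ms if edge_trim_ms is None else edge_trim_ms,
        )


@dataclass
class ZScoredTrace:
    """Baseline-normalized averaged trace, dimensionless z units.

    ``values * baseline_sd_uv + baseline_median_uv`` recovers the source
    trace to floating precision.
    """

    values: np.ndarray
    baseline_median_uv: float
    baseline_sd_uv: float
    source: AveragedTrace

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.baseline_sd_uv <= 0:
            raise DegenerateBaselineError(
                f"baseline SD must be > 0, got {self.baseline_sd_uv}"
            )

    @property
    def fs_hz(self) -> float:
        return self.source.fs_hz

    @property
    def channel(self) -> MuscleChannel:
        return self.source.channel

    @property
    def times_ms(self) -> np.ndarray:
        return self.source.times_ms


# Detection statuses
EXCLUDED = "excluded"
NO_RESPONSE = "no_response"
RESPONSE = "response"


@dataclass
class ChannelDetection:
    """Per-muscle detection outcome for one stimulation setting.

    For ``status == 'response'`` the peak fields describe the greatest
    rectified peak of the z-scored average inside the muscle's latency
    window; otherwise they are zero / NaN.
    """

    label: str
    group: str
    status: str
    peak_z: float = 0.0
    peak_uv: float = 0.0
    latency_ms: float = float("nan")
    width_ms: float = float("nan")
    threshold_used: float = float("nan")

    def __post_init__(self) -> None:
        if self.status not in (EXCLUDED, NO_RESPONSE, RESPONSE):
            raise ValidationError(f"invalid status {self.status!r}")
        if self.group not in (FACIAL, LIMB):
            raise ValidationError(f"invalid group {self.group!r}")
        if self.status == RESPONSE:
            if not (self.peak_z >= self.threshold_used):
                raise ValidationError("response peak_z must be >= threshold_used")
        elif self.peak_z != 0.0:
            raise ValidationError("non-response detections must have peak_z == 0")


@dataclass
class SettingScore:
    """Aggregate mEP score for one stimulation setting.

    ``missing`` is True when every channel was excluded, in which case
    ``mep_score`` is NaN rather than 0 (0 means "clean recording, no
    capsular response"; missing means "nothing usable was recorded").
    """

    setting_id: str
    mep_score: float
    detections: list[ChannelDetection]
    n_included: int
    n_responding: int
    missing: bool = False
    normalization: object | None = None
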