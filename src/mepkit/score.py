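"""Cross-muscle amplitude normalization and the aggregate mEP score.

Different muscles have systematically different mEP amplitude
distributions (facial responses are smaller, most distributions are
heavily right-skewed), so raw peak amplitudes cannot be averaged
directly.  Each detected amplitude is therefore mapped onto a common
scale::

    normalized = (peak_z - group_threshold) * iqr_scale + 7

i.e. excess over the muscle's own detection threshold (z = 4 facial,
z = 7 limb), rescaled so the muscle's interquartile range matches the
pooled all-muscle IQR, then shifted by the limb threshold so the
minimum detectable response lands at a common floor.  Non-responding
channels contribute 0, excluded channels leave the average entirely,
and the mean is compressed with log2(1 + mean) to tame outliers:

* 0  — no muscle responded,
* ~1 — a single minimal response among eight muscles,
* ~6 — every muscle strongly recruited.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    EXCLUDED,
    FACIAL,
    RESPONSE,
    ChannelDetection,
    SettingScore,
    ValidationError,
)

__all__ = [
    "NormalizationTable",
    "calibrate_normalization",
    "normalize_amplitude",
    "mep_score",
    "ADD_BACK_Z",
]

#: Constant added back after threshold subtraction and IQR scaling — the
#: limb detection threshold, giving every muscle a common response floor.
ADD_BACK_Z = 7.0


@dataclass
class NormalizationTable:
    """Per-muscle IQR scaling factors plus group thresholds.

    ``iqr_scale[label]`` is pooled-IQR / muscle-IQR of detected peak
    amplitudes (z units).  Muscles absent from the table fall back to a
    scale of 1 with a warning.  The default (uncalibrated) table is the
    identity.
    """

    iqr_scale: dict[str, float] = field(default_factory=dict)
    threshold_facial: float = 4.0
    threshold_limb: float = 7.0
    add_back: float = ADD_BACK_Z
    pooled_iqr: float = float("nan")

    def scale_for(self, label: str) -> float:
        if label not in self.iqr_scale:
            if self.iqr_scale:  # calibrated table missing this muscle
                warnings.warn(f"no IQR scale for muscle {label!r}; using 1.0")
            return 1.0
        return self.iqr_scale[label]

    def threshold_for(self, group: str) -> float:
        return self.threshold_facial if group == FACIAL else self.threshold_limb

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "iqr_scale": self.iqr_scale,
                    "threshold_facial": self.threshold_facial,
                    "threshold_limb": self.threshold_limb,
                    "add_back": self.add_back,
                    "pooled_iqr": self.pooled_iqr,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationTable":
        d = json.loads(Path(path).read_text())
        return cls(
            iqr_scale={k: float(v) for k, v in d["iqr_scale"].items()},
            threshold_facial=d["threshold_facial"],
            threshold_limb=d["threshold_limb"],
            add_back=d["add_back"],
            pooled_iqr=d["pooled_iqr"],
        )


def _iqr(values: np.ndarray) -> float:
    return float(np.percentile(values, 75) - np.percentile(values, 25))


def calibrate_normalization(
    peak_z_by_muscle: dict[str, list[float]],
    threshold_facial: float = 4.0,
    threshold_limb: float = 7.0,
    min_responses: int = 4,
) -> NormalizationTable:
    """Compute per-muscle IQR scaling factors from a detection corpus.

    ``peak_z_by_muscle`` maps muscle label to the detected (response
    status) peak amplitudes in z units, pooled across settings and
    subjects.  The pooled IQR is computed on all values combined; each
    muscle's scale is pooled-IQR / muscle-IQR, so that after scaling
    every muscle's amplitude IQR equals the pooled IQR.

    Muscles with fewer than ``min_responses`` detections, or a
    degenerate zero IQR, get scale 1 with a warning.
    """
    if not peak_z_by_muscle:
        raise ValidationError("calibration corpus is empty")
    pooled = np.concatenate(
        [np.asarray(v, dtype=float) for v in peak_z_by_muscle.values() if len(v)]
    )
    if pooled.size == 0:
        raise ValidationError("calibration corpus contains no detected responses")
    pooled_iqr = _iqr(pooled)
    scales: dict[str, float] = {}
    for label, vals in peak_z_by_muscle.items():
        v = np.asarray(vals, dtype=float)
        if v.size < min_responses:
            warnings.warn(
                f"{label}: only {v.size} detected responses; scale left at 1.0"
            )
            scales[label] = 1.0
            continue
        miqr = _iqr(v)
        if miqr <= 0.0:
            warnings.warn(f"{label}: zero amplitude IQR; scale left at 1.0")
            scales[label] = 1.0
            continue
        scales[label] = pooled_iqr / miqr
    return NormalizationTable(
        iqr_scale=scales,
        threshold_facial=threshold_facial,
        threshold_limb=threshold_limb,
        pooled_iqr=pooled_iqr,
    )


def normalize_amplitude(
    detection: ChannelDetection, table: NormalizationTable | None = None
) -> float:
    """Map a detected response amplitude onto the common cross-muscle scale.

    ``(peak_z - group_threshold) * iqr_scale + 7``, floored at 0.  The
    floor cannot trigger for detections at or above their threshold but
    guards custom-threshold configurations.
    """
    if table is None:
        table = NormalizationTable()
    if detection.status != RESPONSE:
        raise ValidationError("normalize_amplitude requires a response detection")
    thr = table.threshold_for(detection.group)
    value = (detection.peak_z - thr) * table.scale_for(detection.label) + table.add_back
    return max(0.0, value)


def mep_score(
    detections: list[ChannelDetection],
    table: NormalizationTable | None = None,
    setting_id: str = "",
) -> SettingScore:
    """Aggregate per-channel detections into a single mEP score.

    Excluded channels leave the denominator; responding channels
    contribute their normalized amplitude, non-responding channels 0;
    the mean is log-compressed: ``score = log2(1 + mean)`` (0 when no
    channel responded).  When *every* channel is excluded the score is
    flagged missing (NaN) rather than 0 — nothing usable was measured.
    """
    if not detections:
        raise ValidationError("at least one channel detection is required")
    if table is None:
        table = NormalizationTable()
    included = [d for d in detections if d.status != EXCLUDED]
    responding = [d for d in included if d.status == RESPONSE]
    if not included:
        return SettingScore(
            setting_id=setting_id,
            mep_score=float("nan"),
            detections=detections,
            n_included=0,
            n_responding=0,
            missing=True,
            normalization=table,
        )
    total = sum(normalize_amplitude(d, table) for d in responding)
    mean = total / len(included)
    score = 0.0 if mean == 0.0 else math.log2(1.0 + mean)
    return SettingScore(
        setting_id=setting_id,
        mep_score=score,
        detections=detections,
        n_included=len(included),
        n_responding=len(responding),
        missing=False,
        normalization=table,
    )
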