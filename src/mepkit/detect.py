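"""Latency-windowed peak detection on the rectified z-scored average.

A channel "responds" when the rectified z-scored pulse average contains
a local maximum that (a) clears the muscle-group threshold (z = 4
facial, z = 7 limb), (b) peaks inside the muscle's latency window, and
(c) has a half-height width between 1 and 15 ms — the characteristic
temporal footprint of a compound muscle action potential.  The width
gate is what separates genuine mEP from single-sample noise spikes and
slow baseline wander.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .core import (
    EXCLUDED,
    FACIAL,
    LIMB,
    NO_RESPONSE,
    RESPONSE,
    ChannelDetection,
    MuscleChannel,
    ValidationError,
    ZScoredTrace,
)

__all__ = [
    "DetectionConfig",
    "detect_mep",
    "derive_latency_windows",
    "DEFAULT_WINDOWS_MS",
    "WIDE_WINDOWS_MS",
]

#: Muscle-specific peak latency windows (ms after pulse onset) shipped
#: as canonical defaults.  Latencies grow with conduction path length:
#: facial muscles respond at ~5-18 ms, the biceps earliest of the arm
#: muscles and the first dorsal interosseous (index finger) latest.
DEFAULT_WINDOWS_MS: dict[str, tuple[float, float]] = {
    "CL_ECR": (16.5, 30.5),
    "CL_FCR": (14.5, 29.5),
    "CL_FDI": (21.0, 30.0),
    "CL_Bicep": (11.0, 29.0),
    "CL_Nasalis": (5.0, 18.0),
    "IL_Nasalis": (5.0, 18.0),
    "CL_Genioglossus": (5.0, 18.0),
    "IL_Genioglossus": (5.0, 18.0),
    "CL_OrbOris": (5.0, 18.5),
    "IL_OrbOris": (5.0, 18.5),
}

#: Wide exploratory windows per muscle group, used before muscle-specific
#: windows have been derived from data.
WIDE_WINDOWS_MS: dict[str, tuple[float, float]] = {
    FACIAL: (4.0, 25.0),
    LIMB: (10.0, 40.0),
}


@dataclass
class DetectionConfig:
    """Thresholds, latency windows and width bounds for peak detection."""

    threshold_facial: float = 4.0
    threshold_limb: float = 7.0
    windows_ms: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS_MS)
    )
    wide_windows_ms: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(WIDE_WINDOWS_MS)
    )
    width_bounds_ms: tuple[float, float] = (1.0, 15.0)

    def __post_init__(self) -> None:
        if self.threshold_facial <= 0 or self.threshold_limb <= 0:
            raise ValidationError("thresholds must be > 0")
        lo, hi = self.width_bounds_ms
        if not (0 < lo < hi):
            raise ValidationError("width bounds must satisfy 0 < low < high")

    def threshold_for(self, group: str) -> float:
        return self.threshold_facial if group == FACIAL else self.threshold_limb

    def window_for(self, muscle: MuscleChannel) -> tuple[float, float]:
        if muscle.label in self.windows_ms:
            return self.windows_ms[muscle.label]
        return muscle.detection_window_ms

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "threshold_facial": self.threshold_facial,
            "threshold_limb": self.threshold_limb,
            "windows_ms": {k: list(v) for k, v in self.windows_ms.items()},
            "wide_windows_ms": {k: list(v) for k, v in self.wide_windows_ms.items()},
            "width_bounds_ms": list(self.width_bounds_ms),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DetectionConfig":
        d = json.loads(Path(path).read_text())
        return cls(
            threshold_facial=d["threshold_facial"],
            threshold_limb=d["threshold_limb"],
            windows_ms={k: tuple(v) for k, v in d["windows_ms"].items()},
            wide_windows_ms={k: tuple(v) for k, v in d["wide_windows_ms"].items()},
            width_bounds_ms=tuple(d["width_bounds_ms"]),
        )


def _half_height_width_ms(
    r: np.ndarray, peak_idx: int, fs_hz: float
) -> float:
    """Width of the peak at half of its own height, by linear interpolation.

    Measured on the rectified z trace relative to 0 (the baseline median
    maps to 0 after z-scoring).
    """
    half = r[peak_idx] / 2.0
    # walk left
    i = peak_idx
    while i > 0 and r[i] > half:
        i -= 1
    if r[i] > half:
        left = float(i)
    else:
        left = i + (half - r[i]) / (r[i + 1] - r[i])
    # walk right
    j = peak_idx
    n = r.size
    while j < n - 1 and r[j] > half:
        j += 1
    if r[j] > half:
        right = float(j)
    else:
        right = j - (half - r[j]) / (r[j - 1] - r[j])
    return (right - left) * 1000.0 / fs_hz


def detect_mep(
    trace: ZScoredTrace,
    muscle: MuscleChannel | None = None,
    cfg: DetectionConfig | None = None,
    window_ms: tuple[float, float] | None = None,
) -> ChannelDetection:
    """Detect an mEP response on a z-scored averaged trace.

    The trace is rectified; local maxima at or above the group threshold
    whose peak sample lies inside the muscle's latency window and whose
    half-height width is within the characteristic 1-15 ms range qualify
    as responses.  The greatest-height qualifying peak (earliest on
    ties) defines the reported amplitude, latency and width.  Plateaus
    count as a single peak at their centre.

    ``window_ms`` overrides the configured window (used for the wide
    exploratory pass when deriving windows from data).
    """
    if cfg is None:
        cfg = DetectionConfig()
    if muscle is None:
        muscle = trace.channel
    lo_ms, hi_ms = window_ms if window_ms is not None else cfg.window_for(muscle)
    fs = trace.fs_hz
    r = np.abs(np.asarray(trace.values, dtype=float))
    n = r.size
    lo = int(np.ceil(lo_ms * fs / 1000.0))
    hi = int(np.floor(hi_ms * fs / 1000.0))
    if lo >= n or hi <= 0 or lo >= hi:
        raise ValidationError(
            f"latency window [{lo_ms}, {hi_ms}] ms lies outside the epoch"
        )
    threshold = cfg.threshold_for(muscle.group)

    peaks, props = sps.find_peaks(r, height=threshold, plateau_size=(1, None))
    # plateau handling: find_peaks already reports the centre sample of
    # flat-topped peaks when plateau_size is requested
    best: tuple[float, float, float] | None = None  # (height, latency, width)
    for p in peaks:
        if not (lo <= p <= hi):
            continue
        w = _half_height_width_ms(r, int(p), fs)
        if not (cfg.width_bounds_ms[0] <= w <= cfg.width_bounds_ms[1]):
            continue
        h = float(r[p])
        lat = p * 1000.0 / fs
        if best is None or h > best[0] or (h == best[0] and lat < best[1]):
            best = (h, lat, w)

    if best is None:
        return ChannelDetection(
            label=muscle.label,
            group=muscle.group,
            status=NO_RESPONSE,
            threshold_used=threshold,
        )
    h, lat, w = best
    return ChannelDetection(
        label=muscle.label,
        group=muscle.group,
        status=RESPONSE,
        peak_z=h,
        peak_uv=h * trace.baseline_sd_uv,
        latency_ms=lat,
        width_ms=w,
        threshold_used=threshold,
    )


def derive_latency_windows(
    detections_by_muscle: dict[str, list[ChannelDetection]],
    cfg: DetectionConfig | None = None,
    min_responses: int = 20,
) -> dict[str, tuple[float, float]]:
    """Derive per-muscle latency windows from wide-window detections.

    For each muscle with at least ``min_responses`` detected responses
    the window is ``[P1 - 0.5 ms, P99 + 0.5 ms]`` of the detected peak
    latencies, rounded to 0.5 ms and clipped to the group's wide
    exploratory window.  Muscles with too few responses keep the wide
    window (with a warning) — a prospective window should not be pinned
    to a handful of latencies.
    """
    if cfg is None:
        cfg = DetectionConfig()
    out: dict[str, tuple[float, float]] = {}
    for label, dets in detections_by_muscle.items():
        resp = [d for d in dets if d.status == RESPONSE]
        if not resp:
            continue
        group = resp[0].group
        wide = cfg.wide_windows_ms[group]
        if len(resp) < min_responses:
            warnings.warn(
                f"{label}: only {len(resp)} responses; keeping wide window {wide}"
            )
            out[label] = wide
            continue
        lats = np.array([d.latency_ms for d in resp])
        lo = np.percentile(lats, 1) - 0.5
        hi = np.percentile(lats, 99) + 0.5
        lo = max(wide[0], round(lo * 2.0) / 2.0)
        hi = min(wide[1], round(hi * 2.0) / 2.0)
        out[label] = (lo, hi)
    return out
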