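"""Readers and writers: recordings (EDF / CSV + JSON) and result files.

A recording travels as a signal container plus a JSON metadata sidecar:

* signal — an EDF/EDF+ file (read through :mod:`mne`) or a plain CSV
  matrix with one row per channel, values in μV;
* metadata — JSON carrying the sampling rate, channel descriptions
  (muscle label, group, laterality, detection window), the stimulation
  setting, and either explicit pulse onset sample indices or the name
  of a stimulus-sync channel from which onsets are detected by
  threshold crossing.

EDF files are written with a minimal single-record EDF writer (16-bit,
per-channel physical scaling): nothing installed alongside this package
exports EDF, and round-tripping through the container is needed for
testing the reader.  Results are written as a per-channel CSV plus a
per-setting JSON summary with a deterministic column order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AnnotationSet,
    ChannelDetection,
    ChannelMismatchError,
    MuscleChannel,
    RawRecording,
    SettingScore,
    StimSetting,
    ValidationError,
)

__all__ = [
    "read_recording",
    "write_recording",
    "write_results",
    "read_results",
    "detect_onsets_from_sync",
    "write_annotations",
    "read_annotations",
]

RESULT_COLUMNS = [
    "setting_id",
    "label",
    "group",
    "status",
    "peak_z",
    "peak_uv",
    "latency_ms",
    "width_ms",
    "threshold_used",
]


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def _channel_to_dict(ch: MuscleChannel) -> dict:
    return {
        "label": ch.label,
        "group": ch.group,
        "laterality": ch.laterality,
        "detection_window_ms": list(ch.detection_window_ms),
    }


def _channel_from_dict(d: dict) -> MuscleChannel:
    return MuscleChannel(
        label=d["label"],
        group=d["group"],
        laterality=d.get("laterality", "CL"),
        detection_window_ms=tuple(d["detection_window_ms"]),
    )


def _setting_to_dict(s: StimSetting) -> dict:
    return {
        "amplitude_mA": s.amplitude_mA,
        "pulse_width_us": s.pulse_width_us,
        "frequency_hz": s.frequency_hz,
        "duration_s": s.duration_s,
        "contact_config": s.contact_config,
        "setting_id": s.setting_id,
    }


def _setting_from_dict(d: dict) -> StimSetting:
    return StimSetting(**d)


def recording_metadata(rec: RawRecording, include_onsets: bool = True) -> dict:
    meta = {
        "fs_hz": rec.fs_hz,
        "channels": [_channel_to_dict(c) for c in rec.channels],
        "setting": _setting_to_dict(rec.setting),
        "subject_id": rec.subject_id,
        "lead_id": rec.lead_id,
    }
    if include_onsets:
        meta["pulse_onsets"] = [int(x) for x in rec.pulse_onsets]
    return meta


# ---------------------------------------------------------------------------
# sync-channel onset detection
# ---------------------------------------------------------------------------

def detect_onsets_from_sync(
    sync: np.ndarray, fs_hz: float, frequency_hz: float, threshold: float | None = None
) -> np.ndarray:
    """Detect pulse onsets on a stimulus-sync channel.

    Absolute-threshold crossing (default: half the channel's peak
    magnitude) with a refractory period of half the inter-pulse
    interval, so ringing within a pulse never yields duplicates.
    """
    sync = np.abs(np.asarray(sync, dtype=float))
    if threshold is None:
        threshold = 0.5 * float(np.max(sync))
    if threshold <= 0:
        raise ValidationError("sync channel is silent; cannot detect onsets")
    refractory = int(round(0.5 * fs_hz / frequency_hz))
    above = sync >= threshold
    onsets = []
    last = -refractory - 1
    for i in np.flatnonzero(above):
        if i - last > refractory:
            onsets.append(i)
        last = i
    if not onsets:
        raise ValidationError("no threshold crossings found on sync channel")
    return np.asarray(onsets, dtype=np.int64)


# ---------------------------------------------------------------------------
# minimal EDF writer / reader glue
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValidationError(f"EDF header field too long: {value!r}")
    return b.ljust(width)


def _write_edf(path: Path, rec: RawRecording) -> None:
    """Single-data-record 16-bit EDF with per-channel physical scaling."""
    ns = rec.n_channels
    n_samp = rec.n_samples
    dig_min, dig_max = -32767, 32767
    phys_mins, phys_maxs, digital = [], [], []
    for row in rec.signal:
        peak = float(np.max(np.abs(row)))
        peak = peak if peak > 0 else 1.0
        phys_mins.append(-peak)
        phys_maxs.append(peak)
        scaled = np.clip(np.round(row / peak * dig_max), dig_min, dig_max)
        digital.append(scaled.astype("<i2"))

    record_duration = n_samp / rec.fs_hz
    header_bytes = 256 + ns * 256
    with open(path, "wb") as f:
        f.write(_edf_field("0", 8))
        f.write(_edf_field("X X X X", 80))  # patient id (anonymous)
        f.write(_edf_field("Startdate X X X X", 80))
        f.write(_edf_field("01.01.00", 8))
        f.write(_edf_field("00.00.00", 8))
        f.write(_edf_field(str(header_bytes), 8))
        f.write(_edf_field("", 44))
        f.write(_edf_field("1", 8))  # one data record
        f.write(_edf_field(f"{record_duration:.6g}"[:8], 8))
        f.write(_edf_field(str(ns), 4))
        for ch in rec.channels:
            f.write(_edf_field(ch.label[:16], 16))
        for _ in range(ns):
            f.write(_edf_field("", 80))  # transducer
        for _ in range(ns):
            f.write(_edf_field("uV", 8))
        for pm in phys_mins:
            f.write(_edf_field(f"{pm:.6g}"[:8], 8))
        for pm in phys_maxs:
            f.write(_edf_field(f"{pm:.6g}"[:8], 8))
        for _ in range(ns):
            f.write(_edf_field(str(dig_min), 8))
        for _ in range(ns):
            f.write(_edf_field(str(dig_max), 8))
        for _ in range(ns):
            f.write(_edf_field("", 80))  # prefiltering
        for _ in range(ns):
            f.write(_edf_field(str(n_samp), 8))
        for _ in range(ns):
            f.write(_edf_field("", 32))
        for d in digital:
            f.write(d.tobytes())


def _read_edf_signal(path: Path) -> tuple[np.ndarray, float, list[str]]:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> μV
    return np.asarray(data, dtype=float), float(raw.info["sfreq"]), list(raw.ch_names)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def write_recording(
    rec: RawRecording, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write a recording as `.edf` or `.csv` plus a JSON metadata sidecar."""
    path = Path(path)
    meta_path = Path(metadata_path) if metadata_path else path.with_suffix(".json")
    if path.suffix.lower() == ".edf":
        _write_edf(path, rec)
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, rec.signal, delimiter=",", fmt="%.17g")
    else:
        raise ValidationError(f"unsupported recording format {path.suffix!r}")
    meta_path.write_text(json.dumps(recording_metadata(rec), indent=2))


def read_recording(
    path: str | Path, metadata_path: str | Path | None = None
) -> RawRecording:
    """Read an EDF or CSV recording, validated against its JSON metadata.

    Pulse onsets come from the metadata's explicit ``pulse_onsets``
    list; alternatively the metadata may name a ``sync_channel`` present
    in the signal file, in which case onsets are detected from it by
    threshold crossing and the sync row is dropped from the returned
    recording.
    """
    path = Path(path)
    meta_path = Path(metadata_path) if metadata_path else path.with_suffix(".json")
    if not meta_path.exists():
        raise ValidationError(f"metadata file {meta_path} not found")
    meta = json.loads(meta_path.read_text())

    labels: list[str] | None = None
    if path.suffix.lower() == ".edf":
        signal, fs, labels = _read_edf_signal(path)
        if abs(fs - meta["fs_hz"]) > 1e-6 * meta["fs_hz"]:
            raise ValidationError(
                f"EDF sampling rate {fs} disagrees with metadata {meta['fs_hz']}"
            )
    elif path.suffix.lower() == ".csv":
        signal = np.loadtxt(path, delimiter=",", ndmin=2)
        fs = float(meta["fs_hz"])
    else:
        raise ValidationError(f"unsupported recording format {path.suffix!r}")

    channels = [_channel_from_dict(d) for d in meta["channels"]]
    setting = _setting_from_dict(meta["setting"])

    sync_name = meta.get("sync_channel")
    sync_row = None
    if sync_name is not None:
        if labels is not None and sync_name in labels:
            sync_idx = labels.index(sync_name)
        elif "sync_row" in meta:
            sync_idx = int(meta["sync_row"])
        else:
            raise ValidationError(
                f"sync channel {sync_name!r} not found in signal file"
            )
        sync_row = signal[sync_idx]
        signal = np.delete(signal, sync_idx, axis=0)
        if labels is not None:
            labels = [l for i, l in enumerate(labels) if i != sync_idx]

    if signal.shape[0] != len(channels):
        raise ChannelMismatchError(
            f"signal file has {signal.shape[0]} channels, metadata lists {len(channels)}"
        )
    if labels is not None:
        # match EDF channels to metadata by label where labels are present
        order = []
        for ch in channels:
            if ch.label in labels:
                order.append(labels.index(ch.label))
            else:
                raise ChannelMismatchError(
                    f"channel {ch.label!r} missing from EDF file"
                )
        signal = signal[order]

    if "pulse_onsets" in meta:
        onsets = np.asarray(meta["pulse_onsets"], dtype=np.int64)
    elif sync_row is not None:
        onsets = detect_onsets_from_sync(sync_row, fs, setting.frequency_hz)
    else:
        raise ValidationError("metadata provides neither pulse_onsets nor sync_channel")

    return RawRecording(
        signal=signal,
        fs_hz=fs,
        pulse_onsets=onsets,
        channels=channels,
        setting=setting,
        subject_id=meta.get("subject_id", ""),
        lead_id=meta.get("lead_id", ""),
    )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_results(
    results: list[SettingScore], csv_path: str | Path, json_path: str | Path | None = None
) -> None:
    """Write per-channel detections (CSV) and per-setting scores (JSON)."""
    if not results:
        raise ValidationError("results list is empty")
    csv_path = Path(csv_path)
    rows = []
    for res in results:
        for det in res.detections:
            rows.append(
                {
                    "setting_id": res.setting_id,
                    "label": det.label,
                    "group": det.group,
                    "status": det.status,
                    "peak_z": det.peak_z,
                    "peak_uv": det.peak_uv,
                    "latency_ms": det.latency_ms,
                    "width_ms": det.width_ms,
                    "threshold_used": det.threshold_used,
                }
            )
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(csv_path, index=False)
    summary = [
        {
            "setting_id": res.setting_id,
            "mep_score": None if res.missing else res.mep_score,
            "missing": res.missing,
            "n_included": res.n_included,
            "n_responding": res.n_responding,
        }
        for res in results
    ]
    jp = Path(json_path) if json_path else csv_path.with_suffix(".json")
    jp.write_text(json.dumps(summary, indent=2))


def read_results(
    csv_path: str | Path, json_path: str | Path | None = None
) -> list[SettingScore]:
    """Inverse of :func:`write_results` (normalization metadata is not
    persisted and comes back as None)."""
    csv_path = Path(csv_path)
    jp = Path(json_path) if json_path else csv_path.with_suffix(".json")
    df = pd.read_csv(csv_path)
    summary = json.loads(jp.read_text())
    by_setting: dict[str, list[ChannelDetection]] = {}
    for _, r in df.iterrows():
        by_setting.setdefault(r["setting_id"], []).append(
            ChannelDetection(
                label=r["label"],
                group=r["group"],
                status=r["status"],
                peak_z=float(r["peak_z"]),
                peak_uv=float(r["peak_uv"]),
                latency_ms=float(r["latency_ms"]),
                width_ms=float(r["width_ms"]),
                threshold_used=float(r["threshold_used"]),
            )
        )
    out = []
    for s in summary:
        out.append(
            SettingScore(
                setting_id=s["setting_id"],
                mep_score=float("nan") if s["missing"] else float(s["mep_score"]),
                detections=by_setting.get(s["setting_id"], []),
                n_included=int(s["n_included"]),
                n_responding=int(s["n_responding"]),
                missing=bool(s["missing"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    payload = [
        {"setting_id": k[0], "label": k[1], "mep_present": v}
        for k, v in sorted(ann.annotations.items())
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_annotations(path: str | Path) -> AnnotationSet:
    payload = json.loads(Path(path).read_text())
    return AnnotationSet(
        {(d["setting_id"], d["label"]): bool(d["mep_present"]) for d in payload}
    )
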