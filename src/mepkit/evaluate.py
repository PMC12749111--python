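"""Evaluation against ground-truth annotations and corpus summaries.

Accuracy is the per-muscle proportion of stimulation settings where the
binary detection decision matches the annotation (excluded channels are
removed from both sides).  Threshold selection uses the F1 score, which
balances precision against recall on heavily imbalanced corpora where
most settings evoke nothing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import (
    EXCLUDED,
    RESPONSE,
    AnnotationSet,
    ChannelDetection,
    ValidationError,
)

__all__ = [
    "detection_accuracy",
    "f1_threshold_sweep",
    "waveform_correlation_analysis",
    "duration_sweep",
    "corpus_feature_summary",
]

DetectionRecord = tuple[str, ChannelDetection]  # (setting_id, detection)


def _records_frame(
    records: list[DetectionRecord], annotations: AnnotationSet
) -> pd.DataFrame:
    rows = []
    for setting_id, det in records:
        key = (setting_id, det.label)
        if key not in annotations:
            raise ValidationError(f"no annotation for {key}")
        rows.append(
            {
                "setting_id": setting_id,
                "label": det.label,
                "group": det.group,
                "status": det.status,
                "predicted": det.status == RESPONSE,
                "annotated": bool(annotations[key]),
                "peak_z": det.peak_z,
                "peak_uv": det.peak_uv,
                "latency_ms": det.latency_ms,
            }
        )
    return pd.DataFrame(rows)


def detection_accuracy(
    records: list[DetectionRecord], annotations: AnnotationSet
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-muscle detection accuracy plus median / worst-case summary.

    Excluded channels are dropped before comparison.  Returns a frame
    indexed by muscle label with ``n`` and ``accuracy`` columns, and an
    aggregate dict with the median and minimum accuracy across muscles
    and the overall (pooled) accuracy.
    """
    df = _records_frame(records, annotations)
    df = df[df["status"] != EXCLUDED]
    if df.empty:
        raise ValidationError("no non-excluded records overlap the annotations")
    df["correct"] = df["predicted"] == df["annotated"]
    per = df.groupby("label").agg(n=("correct", "size"), accuracy=("correct", "mean"))
    summary = {
        "median": float(per["accuracy"].median()),
        "min": float(per["accuracy"].min()),
        "overall": float(df["correct"].mean()),
    }
    return per, summary


def _prf(predicted: np.ndarray, annotated: np.ndarray, geometric: bool) -> tuple[float, float, float]:
    tp = int(np.sum(predicted & annotated))
    fp = int(np.sum(predicted & ~annotated))
    fn = int(np.sum(~predicted & annotated))
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    if geometric:
        f1 = float(np.sqrt(p * r))
    else:
        f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def f1_threshold_sweep(
    traces_by_group: dict[str, list[tuple[str, object, bool]]],
    thresholds: list[float],
    geometric: bool = False,
) -> pd.DataFrame:
    """Precision / recall / F1 per muscle group across detection thresholds.

    ``traces_by_group`` maps group -> list of (setting_id, z-scored
    trace, annotated) tuples; detection is re-run at each threshold.
    F1 is the standard harmonic mean 2PR/(P+R); ``geometric=True``
    switches to sqrt(P*R).  The per-group argmax threshold is available
    from the returned table.
    """
    from .detect import DetectionConfig, detect_mep

    if any(t <= 0 for t in thresholds):
        raise ValidationError("thresholds must be positive")
    rows = []
    for group, items in traces_by_group.items():
        ann = np.array([bool(a) for _, _, a in items])
        for thr in thresholds:
            cfg = DetectionConfig(threshold_facial=thr, threshold_limb=thr)
            pred = np.array(
                [detect_mep(tr, cfg=cfg).status == RESPONSE for _, tr, _ in items]
            )
            p, r, f1 = _prf(pred, ann, geometric)
            rows.append(
                {"group": group, "threshold": thr, "precision": p, "recall": r, "f1": f1}
            )
    return pd.DataFrame(rows)


def waveform_correlation_analysis(
    traces: list[tuple[str, str, object]],
    window_ms_by_muscle: dict[str, tuple[float, float]] | None = None,
    rank_sum: bool = False,
) -> dict[str, object]:
    """Pairwise waveform similarity of responding traces.

    ``traces`` holds (subject_id, muscle label, averaged or z-scored
    trace) for responding settings.  Each trace is cropped to its
    muscle's detection window and all pairwise Pearson correlations of
    same-muscle traces are computed; pairs are split into within-subject
    and across-subject groups and each group's median is reported.
    Constant traces make r undefined and those pairs are skipped.
    """
    if len(traces) < 2:
        raise ValidationError("need at least 2 responding traces")
    vectors: list[tuple[str, str, np.ndarray]] = []
    for subj, label, tr in traces:
        win = (
            window_ms_by_muscle[label]
            if window_ms_by_muscle and label in window_ms_by_muscle
            else tr.channel.detection_window_ms
        )
        fs = tr.fs_hz
        lo = int(round(win[0] * fs / 1000.0))
        hi = int(round(win[1] * fs / 1000.0))
        vectors.append((subj, label, np.asarray(tr.values[lo:hi], dtype=float)))

    n = len(vectors)
    corr = np.full((n, n), np.nan)
    within, across = [], []
    for i in range(n):
        corr[i, i] = 1.0
        for j in range(i + 1, n):
            si, li, vi = vectors[i]
            sj, lj, vj = vectors[j]
            if li != lj or vi.size != vj.size:
                continue
            if np.ptp(vi) == 0.0 or np.ptp(vj) == 0.0:
                continue  # undefined correlation
            r = float(np.corrcoef(vi, vj)[0, 1])
            corr[i, j] = corr[j, i] = r
            (within if si == sj else across).append(r)

    out: dict[str, object] = {
        "corr_matrix": corr,
        "median_within": float(np.median(within)) if within else float("nan"),
        "median_across": float(np.median(across)) if across else float("nan"),
        "n_within": len(within),
        "n_across": len(across),
    }
    if rank_sum and within and across:
        stat, p = sstats.ranksums(within, across)
        out["ranksum_p"] = float(p)
    return out


def duration_sweep(
    corpus,
    durations_s: list[float],
    pipeline_config=None,
    library=None,
) -> pd.DataFrame:
    """Detection accuracy as a function of stimulation duration.

    Reruns the full pipeline on each recording with pulse averaging
    restricted to the first ``d`` seconds, for each duration, and
    tabulates the overall and per-group accuracy.  A duration equal to
    the full recording reproduces the plain accuracy result.
    """
    from .pipeline import PipelineConfig, run_pipeline

    cfg = pipeline_config if pipeline_config is not None else PipelineConfig()
    rows = []
    for d in durations_s:
        records: list[DetectionRecord] = []
        annotations = AnnotationSet()
        for rec, ann in corpus:
            if d > rec.setting.duration_s:
                raise ValidationError(
                    f"duration {d}s exceeds recording duration {rec.setting.duration_s}s"
                )
            cfg_d = cfg.with_max_duration(d)
            result = run_pipeline([rec], cfg_d, library)[0]
            records.extend((rec.setting.setting_id, det) for det in result.detections)
            annotations.update(ann.annotations)
        _, summary = detection_accuracy(records, annotations)
        rows.append({"duration_s": d, **summary})
    return pd.DataFrame(rows)


def corpus_feature_summary(
    records: list[DetectionRecord],
    normalization=None,
) -> pd.DataFrame:
    """Descriptive per-muscle response statistics for a detection corpus.

    Reports, per muscle: response frequency (percentage of stimulation
    settings with a detected response, out of settings where at least
    one muscle responded), latency quartiles, and amplitude quartiles in
    z units — plus normalized-amplitude quartiles when a calibration
    table is supplied.  Purely descriptive; no inferential statistics.
    """
    from .score import normalize_amplitude

    rows = []
    for setting_id, det in records:
        rows.append(
            {
                "setting_id": setting_id,
                "label": det.label,
                "status": det.status,
                "response": det.status == RESPONSE,
                "latency_ms": det.latency_ms,
                "peak_z": det.peak_z,
                "norm_amp": (
                    normalize_amplitude(det, normalization)
                    if det.status == RESPONSE and normalization is not None
                    else np.nan
                ),
            }
        )
    df = pd.DataFrame(rows)
    responding_settings = set(df.loc[df["response"], "setting_id"])
    if not responding_settings:
        raise ValidationError("no setting has a detected response")
    base = df[df["setting_id"].isin(responding_settings) & (df["status"] != EXCLUDED)]

    def q(series, p):
        s = series.dropna()
        return float(np.percentile(s, p)) if len(s) else float("nan")

    out = []
    for label, g in base.groupby("label"):
        resp = g[g["response"]]
        out.append(
            {
                "label": label,
                "n_settings": len(g),
                "response_pct": 100.0 * len(resp) / len(g),
                "latency_p25": q(resp["latency_ms"], 25),
                "latency_p50": q(resp["latency_ms"], 50),
                "latency_p75": q(resp["latency_ms"], 75),
                "amp_z_p25": q(resp["peak_z"], 25),
                "amp_z_p50": q(resp["peak_z"], 50),
                "amp_z_p75": q(resp["peak_z"], 75),
                "norm_amp_p25": q(resp["norm_amp"], 25),
                "norm_amp_p50": q(resp["norm_amp"], 50),
                "norm_amp_p75": q(resp["norm_amp"], 75),
            }
        )
    return pd.DataFrame(out).set_index("label")
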