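"""Stimulation-artifact rejection for facial EMG channels.

The post-pulse amplifier-recovery artifact is an exponentially damped
sinusoid that overlaps facial mEP latencies (2-20 ms) and shares their
frequency content, so it cannot be filtered out spectrally.  Three
data-driven removal strategies are provided:

* **template rejection** — match the trace against a pre-saved library
  of pure-artifact waveforms (best Pearson correlation), fit the
  matched template's amplitude robustly (median-scaling) and subtract;
* **PCA rejection** — estimate the artifact as the first principal
  component across simultaneously recorded channels (the artifact is
  near-identical across facial channels, the mEP is not) and subtract a
  per-channel scaled copy;
* **template-PCA** — append replicated copies of the best-matching
  library template to the channel matrix before PCA, anchoring the
  first component to a known artifact shape while keeping the estimate
  trial-specific.

All three touch the trace only inside the artifact window (2-20 ms
after the pulse), with a short cosine taper at the window edges to
avoid step discontinuities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

from .core import FACIAL, AveragedTrace, ValidationError
from .filters import median_scale_fit

__all__ = [
    "ArtifactTemplateLibrary",
    "build_template_library",
    "template_reject",
    "pca_reject",
    "template_pca_reject",
    "ARTIFACT_WINDOW_MS",
]

#: Window (ms after pulse onset) over which the artifact is estimated
#: and removed.
ARTIFACT_WINDOW_MS: tuple[float, float] = (2.0, 20.0)

#: Savitzky-Golay smoothing applied to library templates: 2nd-order
#: polynomial over a 51-sample window at 22 kHz (~2.3 ms); the window is
#: rescaled to the same duration at other sampling rates.
_SAVGOL_ORDER = 2
_SAVGOL_SAMPLES_AT_22K = 51

#: Cosine taper length at each edge of the subtraction window.
_TAPER_MS = 0.5


def _window_slice(fs_hz: float, n_samples: int) -> slice:
    lo = int(round(ARTIFACT_WINDOW_MS[0] * fs_hz / 1000.0))
    hi = int(round(ARTIFACT_WINDOW_MS[1] * fs_hz / 1000.0))
    if hi > n_samples:
        raise ValidationError("trace shorter than the 20 ms artifact window")
    return slice(lo, hi)


def _edge_taper(n: int, fs_hz: float) -> np.ndarray:
    """Unit window with raised-cosine ramps at both ends."""
    ramp = int(round(_TAPER_MS * fs_hz / 1000.0))
    w = np.ones(n)
    if ramp > 0 and 2 * ramp < n:
        ramp_shape = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        w[:ramp] = ramp_shape
        w[-ramp:] = ramp_shape[::-1]
    return w


@dataclass
class ArtifactTemplateLibrary:
    """Pre-saved pure-artifact waveforms restricted to the 2-20 ms window.

    Every template's negation is also present (detection matching uses a
    plain max over Pearson r, so sign coverage must come from the
    library itself), making ``n_templates`` even.
    """

    templates: np.ndarray  # [n_templates, n_window_samples]
    fs_hz: float
    window_ms: tuple[float, float] = ARTIFACT_WINDOW_MS
    provenance: list[str] | None = None

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        if self.templates.ndim != 2 or self.templates.shape[0] == 0:
            raise ValidationError("templates must be a non-empty 2-D matrix")
        if self.templates.shape[0] % 2 != 0:
            raise ValidationError("template count must be even (negation-augmented)")

    @property
    def n_templates(self) -> int:
        return self.templates.shape[0]

    # -- persistence: CSV matrix + JSON header -------------------------
    def save(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        csv_path = Path(csv_path)
        np.savetxt(csv_path, self.templates, delimiter=",")
        header = {
            "fs_hz": self.fs_hz,
            "window_ms": list(self.window_ms),
            "n_templates": self.n_templates,
            "provenance": self.provenance or [],
        }
        jp = Path(json_path) if json_path else csv_path.with_suffix(".json")
        jp.write_text(json.dumps(header, indent=2))

    @classmethod
    def load(
        cls, csv_path: str | Path, json_path: str | Path | None = None
    ) -> "ArtifactTemplateLibrary":
        csv_path = Path(csv_path)
        jp = Path(json_path) if json_path else csv_path.with_suffix(".json")
        header = json.loads(jp.read_text())
        mat = np.loadtxt(csv_path, delimiter=",", ndmin=2)
        return cls(
            templates=mat,
            fs_hz=header["fs_hz"],
            window_ms=tuple(header["window_ms"]),
            provenance=header.get("provenance") or None,
        )


def build_template_library(
    pure_artifact_traces: list[AveragedTrace],
    provenance: list[str] | None = None,
) -> ArtifactTemplateLibrary:
    """Construct a template library from artifact-only averaged traces.

    Each input trace (which must contain stimulation artifact but no
    mEP — the caller's responsibility) is baseline-corrected by
    subtracting its end-of-epoch baseline median, Savitzky-Golay
    smoothed to strip high-frequency noise, and cropped to the 2-20 ms
    artifact window.  The stack is then concatenated with its negated
    copy, so the output holds ``2 x len(input)`` templates.
    """
    if not pure_artifact_traces:
        raise ValidationError("at least one pure-artifact trace is required")
    fs = pure_artifact_traces[0].fs_hz
    rows = []
    for tr in pure_artifact_traces:
        if tr.epoch_ms < ARTIFACT_WINDOW_MS[1]:
            raise ValidationError(
                f"trace of {tr.epoch_ms:.1f} ms shorter than the artifact window"
            )
        n = tr.n_samples
        base = tr.values[int(round(n * 0.9)) :]
        x = tr.values - float(np.median(base))
        win = int(round(_SAVGOL_SAMPLES_AT_22K * tr.fs_hz / 22000.0))
        win = max(_SAVGOL_ORDER + 1, win)
        if win % 2 == 0:
            win += 1
        x = savgol_filter(x, window_length=win, polyorder=_SAVGOL_ORDER)
        rows.append(x[_window_slice(tr.fs_hz, n)])
    mat = np.asarray(rows)
    mat = np.vstack([mat, -mat])
    return ArtifactTemplateLibrary(templates=mat, fs_hz=fs, provenance=provenance)


def _pearson_r_matrix(x: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """Pearson r between vector ``x`` and every row of ``mat``."""
    xc = x - x.mean()
    mc = mat - mat.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(xc) * np.linalg.norm(mc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc @ xc) / denom
    return np.where(np.isfinite(r), r, -np.inf)


def template_reject(
    trace: AveragedTrace, lib: ArtifactTemplateLibrary
) -> AveragedTrace:
    """Subtract the best-matching library template from a trace.

    The template with the highest Pearson correlation to the trace's
    2-20 ms window is selected (plain max — negated copies in the
    library cover sign), its amplitude fitted by median-scaling (robust
    to a temporally sparse mEP riding on the artifact) and the scaled
    template subtracted inside the window only.
    """
    sl = _window_slice(trace.fs_hz, trace.n_samples)
    x = trace.values[sl]
    if np.ptp(x) == 0.0:
        raise ValidationError("artifact window is constant; nothing to match")
    # templates are baseline-corrected, so correct the target the same
    # way (subtract the end-of-epoch baseline median) before fitting;
    # the offset itself stays in the trace and is handled by z-scoring
    base_med = float(np.median(trace.values[int(round(trace.n_samples * 0.9)) :]))
    r = _pearson_r_matrix(x, lib.templates)
    best = lib.templates[int(np.argmax(r))]
    try:
        scale = median_scale_fit(x - base_med, best)
    except ValidationError:
        return trace.copy_with(trace.values.copy())
    out = trace.values.copy()
    out[sl] = x - scale * best * _edge_taper(x.size, trace.fs_hz)
    return trace.copy_with(out)


def pca_reject(
    traces: list[AveragedTrace],
    channel_subset: str = "facial_only",
    scaling: str = "median_scaling",
    extra_rows: np.ndarray | None = None,
    _subset_override: list[int] | None = None,
) -> list[AveragedTrace]:
    """Remove the cross-channel first principal component of the artifact.

    The [channels x window-samples] matrix of the chosen subset
    (``facial_only``, ``all_emg``, or ``emg_plus_lfp`` — the latter
    accepts additional rows via ``extra_rows``) is row-mean-centered and
    decomposed; the first principal component's time course serves as
    the artifact template.  Per channel the template is scaled by:

    * ``remove_pc1`` — the channel's own PC1 projection (exact rank-1
      removal; for row-centered data this coincides with the
      least-squares fit),
    * ``euclidean_fit`` — least-squares amplitude fit, or
    * ``median_scaling`` — robust ratio-median fit, the default; least
      influenced by an mEP waveform overlapping the artifact window,

    and subtracted inside the 2-20 ms window only.  Non-subset channels
    pass through unchanged.  With fewer than two usable rows the input
    is returned unchanged with a warning.
    """
    if channel_subset not in ("facial_only", "all_emg", "emg_plus_lfp"):
        raise ValidationError(f"unknown channel_subset {channel_subset!r}")
    if scaling not in ("remove_pc1", "euclidean_fit", "median_scaling"):
        raise ValidationError(f"unknown scaling {scaling!r}")
    if _subset_override is not None:
        subset = list(_subset_override)
    elif channel_subset == "facial_only":
        subset = [i for i, t in enumerate(traces) if t.channel.group == FACIAL]
    else:
        subset = list(range(len(traces)))
    if not traces:
        return traces
    sl = _window_slice(traces[0].fs_hz, traces[0].n_samples)

    rows = [traces[i].values[sl] for i in subset]
    if extra_rows is not None:
        rows.extend(np.atleast_2d(extra_rows))
    mat = np.asarray(rows)
    if mat.shape[0] < 2:
        warnings.warn("fewer than 2 usable channels for PCA rejection; skipping")
        return [t.copy_with(t.values.copy()) for t in traces]

    centered = mat - mat.mean(axis=1, keepdims=True)
    # first right-singular vector of the centered matrix = PC1 time course
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = vt[0]

    taper = _edge_taper(pc1.size, traces[0].fs_hz)
    out = []
    for i, t in enumerate(traces):
        if i not in subset:
            out.append(t.copy_with(t.values.copy()))
            continue
        xw = t.values[sl]
        xc = xw - xw.mean()
        if scaling in ("remove_pc1", "euclidean_fit"):
            scale = float(xc @ pc1)  # pc1 is unit norm
        else:
            try:
                scale = median_scale_fit(xc, pc1)
            except ValidationError:
                scale = 0.0
        v = t.values.copy()
        v[sl] = xw - scale * pc1 * taper
        out.append(t.copy_with(v))
    return out


def template_pca_reject(
    traces: list[AveragedTrace],
    lib: ArtifactTemplateLibrary,
    scaling: str = "median_scaling",
) -> list[AveragedTrace]:
    """Hybrid rejection: PCA on a template-augmented channel matrix.

    The library template with the highest mean Pearson correlation
    across the facial channels is replicated until the row count of the
    facial channel matrix doubles, PCA rejection runs on the augmented
    matrix, and the subtraction is applied to the original channels
    only.  The anchor rows bias PC1 toward a known artifact shape,
    reducing the risk that a large mEP leaks into the component.
    """
    facial = [i for i, t in enumerate(traces) if t.channel.group == FACIAL]
    if not facial:
        return [t.copy_with(t.values.copy()) for t in traces]
    sl = _window_slice(traces[0].fs_hz, traces[0].n_samples)
    mat = np.asarray([traces[i].values[sl] for i in facial])
    mean_r = np.zeros(lib.n_templates)
    for row in mat:
        if np.ptp(row) == 0.0:
            continue
        mean_r += _pearson_r_matrix(row, lib.templates)
    best = lib.templates[int(np.argmax(mean_r))]
    # scale the anchor rows to the typical channel magnitude so they
    # carry comparable variance into the decomposition
    rms_data = float(np.sqrt(np.mean(mat**2)))
    rms_t = float(np.sqrt(np.mean(best**2)))
    anchor = best * (rms_data / rms_t if rms_t > 0 else 1.0)
    n_extra = len(facial)  # double the row count
    extra = np.tile(anchor, (n_extra, 1))
    return pca_reject(
        traces,
        channel_subset="facial_only",
        scaling=scaling,
        extra_rows=extra,
        _subset_override=facial,
    )
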