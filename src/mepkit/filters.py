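"""Zero-phase band filtering and the subtractive 60 Hz notch.

The subtractive notch exists because a conventional IIR notch rings on
transients: a short biphasic mEP partially overlapping 60 Hz line noise
gets smeared by convolution-based filtering.  Fitting a single sinusoid
(phase from the Fourier coefficient at the line frequency, amplitude by
a robust median of element-wise ratios) and subtracting it removes the
line component while leaving a temporally sparse response untouched.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import AveragedTrace, ValidationError, ZScoredTrace

__all__ = [
    "butter_zero_phase",
    "median_scale_fit",
    "subtractive_notch",
    "EDGE_TRIM_MS",
]

#: Data excluded at each end of the epoch before Butterworth filtering,
#: to avoid the stimulation pulse and filter edge transients.
EDGE_TRIM_MS = 2.0

#: Relative magnitude below which a template sample is considered a
#: near-zero divisor and left out of the ratio median.
_DIVISOR_EPS = 1e-3

_Trace = AveragedTrace | ZScoredTrace


def _apply_to_trace(trace: _Trace, values: np.ndarray, edge_trim_ms: float) -> _Trace:
    if isinstance(trace, ZScoredTrace):
        return ZScoredTrace(
            values=values,
            baseline_median_uv=trace.baseline_median_uv,
            baseline_sd_uv=trace.baseline_sd_uv,
            source=trace.source,
        )
    return trace.copy_with(values, edge_trim_ms=edge_trim_ms)


def butter_zero_phase(
    trace: _Trace,
    band: tuple[float | None, float | None],
) -> _Trace:
    """Second-order Butterworth, applied forward-backward (zero phase).

    ``band = (low, high)`` selects band-pass; ``(low, None)`` high-pass;
    ``(None, high)`` low-pass.  2 ms at each end of the epoch is trimmed
    before filtering and restored as zeros afterwards (those samples are
    invalid for detection; ``edge_trim_ms`` on the output trace records
    this).  Forward-backward application squares the magnitude response,
    so the effective roll-off is that of a 4th-order filter with no
    phase distortion — peak latencies are preserved.
    """
    fs = trace.fs_hz if isinstance(trace, ZScoredTrace) else trace.fs_hz
    low, high = band
    nyq = fs / 2.0
    for edge in (low, high):
        if edge is not None and not (0.0 < edge < nyq):
            raise ValidationError(f"band edge {edge} Hz outside (0, fs/2)")
    if low is not None and high is not None:
        if low >= high:
            raise ValidationError("band low edge must be below high edge")
        sos = sps.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    elif low is not None:
        sos = sps.butter(2, low, btype="highpass", fs=fs, output="sos")
    elif high is not None:
        sos = sps.butter(2, high, btype="lowpass", fs=fs, output="sos")
    else:
        raise ValidationError("at least one band edge required")

    x = np.asarray(trace.values, dtype=float)
    trim = int(round(EDGE_TRIM_MS * fs / 1000.0))
    if x.size - 2 * trim < 15:  # sosfiltfilt needs some padding room
        raise ValidationError("epoch too short for edge-trimmed filtering")
    out = np.zeros_like(x)
    out[trim : x.size - trim] = sps.sosfiltfilt(sos, x[trim : x.size - trim])
    return _apply_to_trace(trace, out, edge_trim_ms=EDGE_TRIM_MS)


def median_scale_fit(target: np.ndarray, template: np.ndarray) -> float:
    """Robust amplitude fit of ``template`` to ``target``.

    Returns the median of the element-wise ratio ``target / template``,
    excluding samples where ``|template|`` is below 1e-3 of its maximum
    (near-zero divisors).  Because the median ignores a sparse minority
    of samples, a short transient (an mEP) riding on the target does not
    bias the fitted scale — the property the subtractive notch and
    template-based artifact rejection both rely on.

    Raises
    ------
    ValidationError
        If the template is identically zero or fewer than 8 samples
        survive the near-zero-divisor exclusion.
    """
    target = np.asarray(target, dtype=float)
    template = np.asarray(template, dtype=float)
    if target.shape != template.shape:
        raise ValidationError("target and template must have equal length")
    peak = np.max(np.abs(template))
    if peak == 0.0:
        raise ValidationError("template is identically zero")
    mask = np.abs(template) >= _DIVISOR_EPS * peak
    if int(mask.sum()) < 8:
        raise ValidationError("fewer than 8 valid samples for the ratio median")
    return float(np.median(target[mask] / template[mask]))


def _sine_phase(x: np.ndarray, fs: float, f0: float) -> float:
    """Phase of the f0 component, via the Fourier coefficient at f0.

    For epochs where f0 falls exactly on the FFT grid (the standard
    100 ms epoch puts 60 Hz on bin 6) this equals the FFT-bin phase; for
    any other epoch length the same single-frequency projection
    (Goertzel-style) is evaluated directly at f0 so the estimate does
    not leak to a neighbouring bin.
    """
    n = x.size
    t = np.arange(n) / fs
    c = np.sum(x * np.exp(-2j * np.pi * f0 * t))
    # x = A sin(wt + phi)  =>  c ≈ (n A / 2) e^{i(phi - pi/2)}
    return float(np.angle(c) + np.pi / 2.0)


def subtractive_notch(trace: _Trace, f0_hz: float = 60.0) -> _Trace:
    """Fit and subtract a single sinusoid at ``f0_hz`` (default 60 Hz).

    Builds a unit-amplitude sine at the phase of the epoch's Fourier
    component at ``f0_hz``, fits its amplitude with
    :func:`median_scale_fit`, and subtracts the scaled sine from the
    whole epoch.  Only the fundamental is removed; line harmonics are
    short and low-magnitude relative to mEP and are deliberately left
    alone.
    """
    fs = trace.fs_hz
    x = np.asarray(trace.values, dtype=float)
    if x.size < fs / f0_hz:
        raise ValidationError("epoch shorter than one period of the notch frequency")
    t = np.arange(x.size) / fs
    phase = _sine_phase(x, fs, f0_hz)
    sine = np.sin(2.0 * np.pi * f0_hz * t + phase)
    # the ratio median assumes a zero-mean target: a DC/drift offset
    # divided by a sinusoid has a heavy-tailed, offset-dependent ratio
    # distribution that can badly bias the fitted scale, so fit on the
    # median-corrected signal (the offset itself is left in the trace)
    scale = median_scale_fit(x - float(np.median(x)), sine)
    return _apply_to_trace(
        trace,
        x - scale * sine,
        edge_trim_ms=getattr(trace, "edge_trim_ms", 0.0),
    )
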