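"""Synthetic DBS-EMG generator with known ground truth.

Emulates the statistical structure the detector must survive, channel
by channel:

* an mEP waveform after each pulse — a smooth biphasic bump with a
  muscle-specific latency, fixed in shape per (subject, muscle) to
  reproduce within-subject waveform stereotypy, and recruited
  monotonically above a per-channel stimulation-amplitude threshold;
* a post-pulse amplifier-recovery artifact shaped like an exponentially
  damped sinusoid persisting ~20 ms, optionally sharing one shape
  across facial channels (it rides through pulse averaging unattenuated
  because it is pulse-locked);
* 60 Hz line noise with a random phase per recording (at 10 Hz
  stimulation the line is pulse-locked too — exactly 6 cycles per
  100 ms epoch — which is why a notch is needed at all);
* a slow (< 2 Hz) random-walk drift and white Gaussian noise, both of
  which average down across pulses.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .core import (
    FACIAL,
    LIMB,
    AnnotationSet,
    MuscleChannel,
    RawRecording,
    StimSetting,
    ValidationError,
)
from .detect import DEFAULT_WINDOWS_MS

__all__ = [
    "SimChannelSpec",
    "ArtifactSpec",
    "make_mep_kernel",
    "damped_sinusoid",
    "stimulus_waveform",
    "simulate_recording",
    "simulate_corpus",
    "simulate_artifact_corpus",
    "simulate_benchmark_corpus",
    "default_channels",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


def default_channels() -> list[MuscleChannel]:
    """The standard eight-muscle montage: four contralateral arm muscles
    and four facial muscles (bilateral nasalis and orbicularis oris)."""
    spec = [
        ("CL_ECR", LIMB, "CL"),
        ("CL_FCR", LIMB, "CL"),
        ("CL_FDI", LIMB, "CL"),
        ("CL_Bicep", LIMB, "CL"),
        ("CL_Nasalis", FACIAL, "CL"),
        ("CL_OrbOris", FACIAL, "CL"),
        ("IL_Nasalis", FACIAL, "IL"),
        ("IL_OrbOris", FACIAL, "IL"),
    ]
    return [
        MuscleChannel(
            label=lbl,
            group=grp,
            laterality=lat,
            detection_window_ms=DEFAULT_WINDOWS_MS[lbl],
        )
        for lbl, grp, lat in spec
    ]


@dataclass(frozen=True)
class SimChannelSpec:
    """Generative parameters for one simulated EMG channel.

    The effective mEP amplitude at stimulation amplitude ``A`` (mA) is::

        amp_eff = mep_amplitude_uv + recruitment_gain_uv_per_mA * (A - thr)   if A > thr
                  0                                                           otherwise

    so ``mep_amplitude_uv`` is the response amplitude just above the
    recruitment threshold and the gain adds the threshold-monotonic
    recruitment slope; either term may be zero.  A channel is annotated
    as a true response exactly when ``amp_eff > 0``.
    """

    muscle: MuscleChannel
    mep_latency_ms: float = 10.0
    mep_amplitude_uv: float = 0.0
    mep_width_ms: float = 4.0
    recruitment_threshold_mA: float = 2.0
    recruitment_gain_uv_per_mA: float = 0.0
    artifact_scale: float = 0.0
    noise_sd_uv: float = 8.0
    line_noise_uv: float = 0.0
    drift_uv: float = 0.0
    waveform_seed: int = 0

    def __post_init__(self) -> None:
        if not (1.0 <= self.mep_width_ms <= 15.0):
            raise ValidationError("mep_width_ms must be in [1, 15]")
        for name in (
            "mep_amplitude_uv",
            "recruitment_gain_uv_per_mA",
            "artifact_scale",
            "noise_sd_uv",
            "line_noise_uv",
            "drift_uv",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.recruitment_threshold_mA <= 0:
            raise ValidationError("recruitment_threshold_mA must be > 0")
        lo, hi = self.muscle.detection_window_ms
        if (self.mep_amplitude_uv > 0 or self.recruitment_gain_uv_per_mA > 0) and not (
            lo <= self.mep_latency_ms <= hi
        ):
            raise ValidationError(
                f"mep_latency_ms {self.mep_latency_ms} outside detection window {lo}-{hi}"
            )

    def effective_amplitude_uv(self, amplitude_mA: float) -> float:
        if amplitude_mA <= self.recruitment_threshold_mA:
            return 0.0
        return self.mep_amplitude_uv + self.recruitment_gain_uv_per_mA * (
            amplitude_mA - self.recruitment_threshold_mA
        )


@dataclass(frozen=True)
class ArtifactSpec:
    """Amplifier-recovery artifact: exponentially damped sinusoid."""

    peak_uv: float = 0.0
    decay_ms: float = 4.0
    osc_freq_hz: float = 300.0
    duration_ms: float = 20.0
    shared_shape: bool = True

    def __post_init__(self) -> None:
        if self.peak_uv < 0 or self.decay_ms <= 0 or self.osc_freq_hz <= 0:
            raise ValidationError("artifact parameters out of range")


def make_mep_kernel(
    latency_ms: float,
    amplitude_uv: float,
    width_ms: float,
    waveform_seed: int,
    fs_hz: float = 22000.0,
    epoch_ms: float = 100.0,
) -> np.ndarray:
    """Build an epoch-length mEP waveform kernel.

    The kernel is a randomized mixture of 2-3 Gaussian-derived lobes
    (one dominant lobe, 1-2 opposite-sign side lobes) fully determined
    by ``waveform_seed``: the same seed always yields the same shape, so
    a (subject, muscle) pair keeps a stereotyped waveform across
    stimulation settings.  The largest absolute excursion equals
    ``amplitude_uv`` at ``latency_ms``, the dominant lobe's half-height
    width equals ``width_ms`` (within a few percent), and the kernel is
    identically zero outside ``[latency - 2*width, latency + 3*width]``.
    """
    n = int(round(fs_hz * epoch_ms / 1000.0))
    if amplitude_uv == 0.0:
        return np.zeros(n)
    if amplitude_uv < 0 or width_ms <= 0:
        raise ValidationError("amplitude and width must be positive")
    if not (0.0 <= latency_ms - 2 * width_ms) or latency_ms + 3 * width_ms > epoch_ms:
        raise ValidationError(
            f"kernel support [{latency_ms - 2 * width_ms:.1f}, "
            f"{latency_ms + 3 * width_ms:.1f}] ms does not fit the epoch"
        )

    rng = np.random.default_rng(waveform_seed)
    t = np.arange(n) * 1000.0 / fs_hz
    sigma = width_ms / _FWHM_PER_SIGMA
    k = np.exp(-0.5 * ((t - latency_ms) / sigma) ** 2)

    # opposite-sign side lobes placed well clear of the dominant lobe's
    # half-height points so they do not distort its measured width
    n_side = int(rng.integers(1, 3))
    offsets = [-rng.uniform(1.5, 1.9) * width_ms]
    if n_side == 2:
        offsets.append(rng.uniform(1.6, 2.2) * width_ms)
    for off in offsets:
        frac = rng.uniform(0.3, 0.6)
        s_sigma = sigma * rng.uniform(0.8, 1.2)
        k -= frac * np.exp(-0.5 * ((t - latency_ms - off) / s_sigma) ** 2)

    support = (t >= latency_ms - 2 * width_ms) & (t <= latency_ms + 3 * width_ms)
    k = np.where(support, k, 0.0)
    k *= amplitude_uv / np.max(np.abs(k))
    if rng.random() < 0.5:  # biphasic polarity is arbitrary
        k = -k
    return k


def damped_sinusoid(
    spec: ArtifactSpec, fs_hz: float, phase: float = 0.0
) -> np.ndarray:
    """Render the artifact waveform, normalized so max |value| = peak_uv."""
    n = int(round(spec.duration_ms * fs_hz / 1000.0))
    t = np.arange(n) * 1000.0 / fs_hz  # ms
    w = np.exp(-t / spec.decay_ms) * np.sin(
        2.0 * np.pi * spec.osc_freq_hz * t / 1000.0 + phase
    )
    peak = np.max(np.abs(w))
    if peak > 0 and spec.peak_uv > 0:
        w = w * (spec.peak_uv / peak)
    else:
        w = np.zeros(n)
    return w


def stimulus_waveform(setting: StimSetting, fs_hz: float) -> np.ndarray:
    """Asymmetric biphasic stimulus pulse for an optional sync channel.

    First phase: ``pulse_width_us`` at unit amplitude; 70 μs inter-phase
    gap; second (charge-balancing) phase 8x longer at 1/8 amplitude,
    with its duration capped at 480 μs (amplitude rescaled to keep the
    phases charge-balanced) for pulse widths above 60 μs.
    """
    pw1 = setting.pulse_width_us
    pw2 = min(8.0 * pw1, 480.0)
    amp2 = pw1 / pw2  # charge balance: amp2 * pw2 == 1 * pw1
    gap = 70.0

    def n_us(us: float) -> int:
        return max(1, int(round(us * fs_hz / 1e6)))

    parts = [
        np.full(n_us(pw1), 1.0),
        np.zeros(n_us(gap)),
        np.full(n_us(pw2), -amp2),
    ]
    return np.concatenate(parts)


def _lowpass_drift(walk: np.ndarray, fs_hz: float, rms_uv: float) -> np.ndarray:
    sos = sps.butter(2, 2.0, btype="lowpass", fs=fs_hz, output="sos")
    d = sps.sosfiltfilt(sos, walk)
    rms = np.sqrt(np.mean(d**2))
    if rms > 0:
        d = d * (rms_uv / rms)
    return d


def simulate_recording(
    specs: list[SimChannelSpec],
    artifact: ArtifactSpec,
    setting: StimSetting,
    fs_hz: float = 22000.0,
    seed: int = 0,
) -> tuple[RawRecording, AnnotationSet]:
    """Simulate one multi-channel recording for one stimulation setting.

    Per channel the signal is the sum of the recruited mEP kernel after
    each pulse, the damped-sinusoid artifact after each pulse (scaled by
    the channel's ``artifact_scale``; identical shape across channels
    when ``artifact.shared_shape``), a 60 Hz sinusoid with a
    recording-wide random phase, low-passed random-walk drift, and white
    Gaussian noise.  The annotation for a channel is True exactly when
    its recruited amplitude is positive.
    """
    if fs_hz < 2000.0:
        raise ValidationError("fs_hz must be >= 2 kHz")
    n_pulses = setting.n_pulses
    period = fs_hz / setting.frequency_hz
    onsets = np.round(np.arange(n_pulses) * period).astype(np.int64)
    n_samples = int(round(setting.duration_s * fs_hz))
    epoch_ms = setting.epoch_ms

    ss = np.random.SeedSequence(entropy=(seed, 0x5E1D))
    rec_rng = np.random.default_rng(ss.spawn(1)[0])
    line_phase = rec_rng.uniform(0, 2 * np.pi)
    shared_art_phase = rec_rng.uniform(0, 2 * np.pi) if not artifact.shared_shape else 0.0
    ch_seeds = ss.spawn(len(specs))

    t_s = np.arange(n_samples) / fs_hz
    signal = np.zeros((len(specs), n_samples))
    ann: dict[tuple[str, str], bool] = {}

    art_shared = damped_sinusoid(artifact, fs_hz)

    for i, (spec, cs) in enumerate(zip(specs, ch_seeds)):
        rng = np.random.default_rng(cs)
        x = np.zeros(n_samples)

        # pulse-locked components: mEP kernel and artifact
        amp_eff = spec.effective_amplitude_uv(setting.amplitude_mA)
        kernel = make_mep_kernel(
            spec.mep_latency_ms,
            amp_eff,
            spec.mep_width_ms,
            spec.waveform_seed,
            fs_hz=fs_hz,
            epoch_ms=epoch_ms,
        )
        if artifact.shared_shape:
            art = art_shared * spec.artifact_scale
        else:
            art = damped_sinusoid(artifact, fs_hz, phase=rng.uniform(0, 2 * np.pi))
            art = art * spec.artifact_scale
        pulse_locked = np.zeros(n_samples)
        for on in onsets:
            end_k = min(on + kernel.size, n_samples)
            pulse_locked[on:end_k] += kernel[: end_k - on]
            end_a = min(on + art.size, n_samples)
            pulse_locked[on:end_a] += art[: end_a - on]
        x += pulse_locked

        if spec.line_noise_uv > 0:
            x += spec.line_noise_uv * np.sin(2 * np.pi * 60.0 * t_s + line_phase)
        if spec.drift_uv > 0:
            x += _lowpass_drift(np.cumsum(rng.standard_normal(n_samples)), fs_hz, spec.drift_uv)
        if spec.noise_sd_uv > 0:
            x += spec.noise_sd_uv * rng.standard_normal(n_samples)

        signal[i] = x
        ann[(setting.setting_id, spec.muscle.label)] = bool(amp_eff > 0)

    rec = RawRecording(
        signal=signal,
        fs_hz=fs_hz,
        pulse_onsets=onsets,
        channels=[s.muscle for s in specs],
        setting=setting,
    )
    return rec, AnnotationSet(ann)


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

#: Parameter ranges for the standard synthetic corpus.  Chosen to mirror
#: the intraoperative recording conditions the detector targets:
#: clearly supra-noise responses once recruited, facial channels carrying
#: a pulse-locked recovery artifact large enough to fool naive detection,
#: and line noise concentrated on (longer-lead) limb channels.
STANDARD_RANGES: dict[str, tuple[float, float]] = {
    "amplitude_mA": (0.5, 5.0),
    "recruitment_threshold_mA": (1.5, 3.5),
    "recruitment_gain_uv_per_mA": (4.0, 8.0),
    "mep_amplitude_uv": (4.0, 8.0),
    "mep_width_ms_facial": (2.0, 3.5),
    "mep_width_ms_limb": (3.0, 6.0),
    "noise_sd_uv": (6.0, 10.0),
    "line_noise_uv_limb": (1.0, 5.0),
    "line_noise_uv_facial": (0.0, 0.5),
    "drift_uv": (5.0, 20.0),
    "artifact_peak_uv": (2.0, 10.0),
    "artifact_decay_ms": (3.0, 8.0),
    "artifact_freq_hz": (150.0, 300.0),
}


def _draw(rng: np.random.Generator, ranges: dict, key: str) -> float:
    lo, hi = ranges[key]
    return float(rng.uniform(lo, hi))


def _latency_in_window(rng: np.random.Generator, muscle: MuscleChannel, width: float) -> float:
    lo, hi = muscle.detection_window_ms
    # keep the peak clear of the window edges and the kernel support
    # inside the epoch and past the stimulation pulse
    lo_eff = max(lo + 1.0, 2.0 * width)
    hi_eff = hi - 1.0
    if hi_eff <= lo_eff:
        return (lo + hi) / 2.0
    return float(rng.uniform(lo_eff, hi_eff))


def simulate_corpus(
    n_subjects: int,
    settings_per_subject: int,
    ranges: dict | None = None,
    seed: int = 0,
    fs_hz: float = 22000.0,
    duration_s: float = 12.0,
    channels: list[MuscleChannel] | None = None,
    responding_fraction: float = 0.6,
    bad_channel_prob: float = 0.03,
    subject_offset: int = 0,
) -> list[tuple[RawRecording, AnnotationSet]]:
    """Simulate a multi-subject corpus with within-subject stereotypy.

    Each subject gets fixed per-muscle waveform seeds and latencies (so
    waveform shape is stereotyped within subject, variable across
    subjects), per-channel recruitment thresholds and gains, and
    per-subject artifact and noise levels drawn from ``ranges``
    (defaults: :data:`STANDARD_RANGES`).  About ``responding_fraction``
    of channels are recruitable at all; stimulation amplitudes vary per
    setting, so recruitable channels respond only on settings above
    their threshold.  ``bad_channel_prob`` injects occasional grossly
    noisy channels that the exclusion rules should catch.

    Fully deterministic for a given ``seed``.
    """
    if n_subjects < 1 or settings_per_subject < 1:
        raise ValidationError("counts must be >= 1")
    ranges = {**STANDARD_RANGES, **(ranges or {})}
    base_channels = channels if channels is not None else default_channels()
    root = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0xC0)))
    out: list[tuple[RawRecording, AnnotationSet]] = []
    contact_pool = ["1", "2", "3", "4", "2A", "2M", "2L", "3A", "3M", "3L"]

    for si in range(n_subjects):
        srng = np.random.default_rng(root.integers(2**31))
        subj = f"S{si + subject_offset:03d}"
        art_spec = ArtifactSpec(
            peak_uv=_draw(srng, ranges, "artifact_peak_uv"),
            decay_ms=_draw(srng, ranges, "artifact_decay_ms"),
            osc_freq_hz=_draw(srng, ranges, "artifact_freq_hz"),
            shared_shape=True,
        )
        noise_sd = _draw(srng, ranges, "noise_sd_uv")
        subj_specs: list[SimChannelSpec] = []
        for ch in base_channels:
            wkey = "mep_width_ms_facial" if ch.group == FACIAL else "mep_width_ms_limb"
            width = _draw(srng, ranges, wkey)
            recruitable = srng.random() < responding_fraction
            lnkey = "line_noise_uv_facial" if ch.group == FACIAL else "line_noise_uv_limb"
            subj_specs.append(
                SimChannelSpec(
                    muscle=ch,
                    mep_latency_ms=_latency_in_window(srng, ch, width),
                    mep_amplitude_uv=_draw(srng, ranges, "mep_amplitude_uv"),
                    mep_width_ms=width,
                    recruitment_threshold_mA=_draw(srng, ranges, "recruitment_threshold_mA"),
                    recruitment_gain_uv_per_mA=(
                        _draw(srng, ranges, "recruitment_gain_uv_per_mA") if recruitable else 0.0
                    ),
                    artifact_scale=(1.0 if ch.group == FACIAL else 0.05) * srng.uniform(0.7, 1.3),
                    noise_sd_uv=noise_sd,
                    line_noise_uv=_draw(srng, ranges, lnkey),
                    drift_uv=_draw(srng, ranges, "drift_uv"),
                    waveform_seed=int(srng.integers(2**31)),
                )
            )
            if not recruitable:
                # non-recruitable channel: zero out the response entirely
                subj_specs[-1] = replace(
                    subj_specs[-1], mep_amplitude_uv=0.0, recruitment_gain_uv_per_mA=0.0
                )

        for ti in range(settings_per_subject):
            setting = StimSetting(
                amplitude_mA=_draw(srng, ranges, "amplitude_mA"),
                pulse_width_us=float(srng.choice([30.0, 60.0, 90.0, 120.0])),
                duration_s=duration_s,
                contact_config=str(srng.choice(contact_pool)),
                setting_id=f"{subj}_T{ti:03d}",
            )
            trial_specs = list(subj_specs)
            for ci in range(len(trial_specs)):
                if srng.random() < bad_channel_prob:
                    trial_specs[ci] = replace(
                        trial_specs[ci], noise_sd_uv=400.0, drift_uv=600.0
                    )
            rec, ann = simulate_recording(
                trial_specs,
                art_spec,
                setting,
                fs_hz=fs_hz,
                seed=int(srng.integers(2**31)),
            )
            rec.subject_id = subj
            rec.lead_id = subj
            out.append((rec, ann))
    return out


def simulate_artifact_corpus(
    n_examples: int,
    ranges: dict | None = None,
    seed: int = 0,
    fs_hz: float = 22000.0,
    duration_s: float = 12.0,
    channel: MuscleChannel | None = None,
):
    """Simulate averaged pure-artifact traces for template-library building.

    Emulates the held-out identification of stimulation settings with a
    clearly visible recovery artifact and no physiological response:
    each example is a facial channel with the mEP disabled, artifact and
    noise drawn from ``ranges``, pulse-averaged and returned as an
    :class:`~mepkit.core.AveragedTrace`.  Deterministic under ``seed``.
    """
    from .preprocess import epoch_average

    ranges = {**STANDARD_RANGES, **(ranges or {})}
    ch = channel if channel is not None else default_channels()[4]  # CL_Nasalis
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0xA2)))
    out = []
    for i in range(n_examples):
        art = ArtifactSpec(
            peak_uv=_draw(rng, ranges, "artifact_peak_uv"),
            decay_ms=_draw(rng, ranges, "artifact_decay_ms"),
            osc_freq_hz=_draw(rng, ranges, "artifact_freq_hz"),
        )
        spec = SimChannelSpec(
            muscle=ch,
            mep_amplitude_uv=0.0,
            artifact_scale=1.0,
            noise_sd_uv=_draw(rng, ranges, "noise_sd_uv"),
            line_noise_uv=_draw(rng, ranges, "line_noise_uv_facial"),
            drift_uv=_draw(rng, ranges, "drift_uv"),
            waveform_seed=0,
        )
        setting = StimSetting(
            amplitude_mA=3.0, duration_s=duration_s, setting_id=f"ART{i:04d}"
        )
        rec, _ = simulate_recording(
            [spec], art, setting, fs_hz=fs_hz, seed=int(rng.integers(2**31))
        )
        out.append(epoch_average(rec)[0])
    return out


def simulate_benchmark_corpus(
    n_subjects: int = 20,
    settings_per_subject: int = 20,
    z_levels: tuple[float, ...] = (0.0, 1.5, 3.0),
    ranges: dict | None = None,
    seed: int = 0,
    fs_hz: float = 22000.0,
    duration_s: float = 12.0,
    subject_offset: int = 0,
) -> tuple[list[tuple[RawRecording, AnnotationSet]], dict[tuple[str, str], float]]:
    """Corpus with controlled detection difficulty for benchmarking.

    For every (setting, channel) a target peak height is drawn from
    ``z_levels`` expressed as multiples of the channel group's detection
    threshold (z = 4 facial, z = 7 limb); the injected bump amplitude in
    μV is ``z * noise_sd / sqrt(n_pulses)`` — the expected peak height
    after pulse averaging and baseline z-scoring.  Artifact (facial) and
    line noise (limb) are enabled per :data:`STANDARD_RANGES`; waveform
    seeds and latencies stay fixed per (subject, muscle).

    Returns the corpus and a map (setting_id, label) -> target z
    multiple, to let recall be evaluated per difficulty level.
    """
    ranges = {**STANDARD_RANGES, **(ranges or {})}
    thresholds = {FACIAL: 4.0, LIMB: 7.0}
    base_channels = default_channels()
    root = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0xB3)))
    noise_sd = 8.0
    corpus: list[tuple[RawRecording, AnnotationSet]] = []
    level_map: dict[tuple[str, str], float] = {}

    for si in range(n_subjects):
        srng = np.random.default_rng(root.integers(2**31))
        subj = f"B{si + subject_offset:03d}"
        art_spec = ArtifactSpec(
            peak_uv=_draw(srng, ranges, "artifact_peak_uv"),
            decay_ms=_draw(srng, ranges, "artifact_decay_ms"),
            osc_freq_hz=_draw(srng, ranges, "artifact_freq_hz"),
            shared_shape=True,
        )
        subj_shape: list[tuple[MuscleChannel, float, float, int, float]] = []
        for ch in base_channels:
            wkey = "mep_width_ms_facial" if ch.group == FACIAL else "mep_width_ms_limb"
            width = _draw(srng, ranges, wkey)
            lnkey = "line_noise_uv_facial" if ch.group == FACIAL else "line_noise_uv_limb"
            subj_shape.append(
                (
                    ch,
                    _latency_in_window(srng, ch, width),
                    width,
                    int(srng.integers(2**31)),
                    _draw(srng, ranges, lnkey),
                )
            )
        n_pulses = int(np.floor(10.0 * duration_s))
        avg_sd = noise_sd / np.sqrt(n_pulses)
        for ti in range(settings_per_subject):
            setting = StimSetting(
                amplitude_mA=3.0,
                duration_s=duration_s,
                contact_config="2",
                setting_id=f"{subj}_T{ti:03d}",
            )
            specs = []
            for ch, lat, width, wseed, line_uv in subj_shape:
                level = float(srng.choice(z_levels))
                amp_uv = level * thresholds[ch.group] * avg_sd
                level_map[(setting.setting_id, ch.label)] = level
                specs.append(
                    SimChannelSpec(
                        muscle=ch,
                        mep_latency_ms=lat,
                        mep_amplitude_uv=amp_uv,
                        mep_width_ms=width,
                        recruitment_threshold_mA=0.5,
                        recruitment_gain_uv_per_mA=0.0,
                        artifact_scale=(1.0 if ch.group == FACIAL else 0.05),
                        noise_sd_uv=noise_sd,
                        line_noise_uv=line_uv,
                        drift_uv=_draw(srng, ranges, "drift_uv"),
                        waveform_seed=wseed,
                    )
                )
            rec, ann = simulate_recording(
                specs, art_spec, setting, fs_hz=fs_hz, seed=int(srng.integers(2**31))
            )
            rec.subject_id = subj
            rec.lead_id = subj
            corpus.append((rec, ann))
    return corpus, level_map
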