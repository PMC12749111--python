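# Methods

This note documents the models, parameter choices, and numerical
decisions behind `mepkit`, and what the synthetic validation does and
does not establish about real recordings.

## Measurement model

A stimulation *setting* delivers a 10 Hz train of asymmetric biphasic
pulses for 12 s (120 pulses) while up to eight muscles are recorded at
22 kHz. The analysis treats each post-pulse epoch — the half-open
100 ms interval starting at pulse onset — as one realization of

    x(t) = mEP(t) + artifact(t) + line(t) + drift(t) + noise(t)

where the mEP and the amplifier-recovery artifact are pulse-locked
(identical in every epoch), the 60 Hz line is *also* pulse-locked at
10 Hz stimulation (exactly 6 cycles per epoch), and drift and white
noise are not. Averaging the epochs therefore attenuates noise by
√120 ≈ 11× while passing the first three terms unchanged: this is why
artifact rejection and the notch must act on the averaged trace, and
why they act before baseline z-scoring.

Processing order per setting: epoch averaging → signal-quality
exclusion → facial artifact rejection / limb subtractive notch →
baseline z-scoring → rectified peak detection → normalization and
aggregation into the mEP score. No step after simulation consumes
randomness; reruns are byte-identical.

## Key parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| Stimulation frequency / duration | 10 Hz / 12 s | — | One inter-pulse interval (100 ms) comfortably contains the longest limb mEP latency plus an inert tail. |
| Baseline window | final 10% of epoch (10 ms) | — | Latest-latency responses end tens of ms earlier; the tail estimates noise median/SD untouched by mEP or artifact. |
| Exclusion rules | late-window variance > 150 μV²; mean abs > 25 μV | μV², μV | Flags channels whose supposedly inert tail still churns (movement, cable artifact) or that carry gross offsets. The variance threshold is stated in μV in its source although variance carries μV²; it is applied as 150 μV² and deliberately not reinterpreted as an SD. |
| Detection thresholds | z = 4 facial, z = 7 limb | z units | Group-specific operating points balancing precision/recall on annotated data; limb channels need a higher bar because their windows admit more residual line noise. |
| Peak width gate | 1–15 ms at half height | ms | The temporal footprint of a compound muscle action potential; rejects single-sample noise spikes (too narrow) and baseline wander (too wide). |
| Latency windows | per muscle (e.g. nasalis 5–18 ms, ECR 16.5–30.5 ms, FDI 21–30 ms) | ms | Conduction-path-ordered defaults shipped with the package; `derive_latency_windows` re-derives them from wide exploratory windows (facial 4–25, limb 10–40 ms) as P1−0.5 … P99+0.5 ms of detected latencies, needing ≥ 20 responses per muscle. The percentile rule is this package's concrete choice for an otherwise loosely specified "examine the distribution" step. |
| Artifact window | 2–20 ms | ms | Where the recovery artifact lives; all rejection methods modify the trace only here. |
| Savitzky–Golay smoothing of templates | order 2, 51 samples at 22 kHz (≈2.3 ms; rescaled at other rates) | — | Strips averaged-noise residue from library templates without distorting artifact oscillations in the 150–300 Hz band. |
| Normalization | scale = pooled IQR / muscle IQR; add-back 7 | z units | IQR matching equalizes skewed per-muscle amplitude distributions without parametric assumptions; adding the limb threshold (7) puts every muscle's minimum detectable response at a common floor of 7 (so one minimal response among eight muscles yields a score near 1). The shipped default table is the identity until calibrated. |

## The subtractive notch

A conventional IIR notch rings on transients, smearing an mEP that
overlaps line noise. Instead the phase of the 60 Hz component is taken
from the Fourier coefficient at 60 Hz (for the standard 100 ms epoch
this is exactly FFT bin 6; for other epoch lengths the same projection
is evaluated directly at 60 Hz so the estimate cannot leak to a
neighbouring bin), a unit sine at that phase is amplitude-fitted by the
*ratio median* (`median_scale_fit`), and the scaled sine is subtracted.
Because the median ignores a sparse minority of samples, an mEP
occupying ≲20% of the epoch does not bias the fit. Only the
fundamental is removed; harmonics are short and small relative to mEP.

Two guards in `median_scale_fit` are this package's own: samples where
the template magnitude falls below 10⁻³ of its peak are excluded from
the median (element-wise division by ≈0 is meaningless), and the target
is offset-corrected before fitting (in the notch, by its epoch median;
in template rejection, by its baseline median). The second guard
matters in practice: pulse-averaged traces carry DC-scale drift
residues, and a constant divided by a sinusoid has a heavy-tailed,
offset-dependent ratio distribution that otherwise biases — even
sign-flips — the fitted scale.

## Artifact rejection

Template rejection matches the averaged trace's 2–20 ms window against
a library of baseline-corrected, smoothed pure-artifact waveforms by
Pearson correlation (plain max: the library contains a negated copy of
every template, so sign coverage is the library's job), fits the
best match by median-scaling and subtracts it inside the window only,
with a 0.5 ms raised-cosine taper at the window edges to avoid step
discontinuities (the taper is an implementation choice; any residual it
leaves sits at 2–2.5 ms, outside every facial detection window).

PCA rejection mean-centers each channel's window and uses the first
right-singular vector of the facial channel matrix as the artifact
template. Scaling options: `remove_pc1` (subtract each channel's own
PC1 projection — for row-centered data this is algebraically identical
to the per-channel least-squares fit, so `euclidean_fit` coincides with
it), or `median_scaling` (default). The median variant is preferred
because a least-squares scale is inflated by an mEP that temporally
overlaps the artifact, which oversubtracts and distorts the response;
the ratio median ignores the bump samples.

Template-PCA appends replicated copies of the best-matching library
template (highest mean r across facial channels) to the channel matrix
until the row count doubles, anchoring PC1 to a known artifact shape
before subtraction; only the original channels are modified. With an
odd or single facial channel the augmented matrix still has ≥ 2 rows
and the method degrades gracefully.

## The synthetic generator

`mepkit.simulate` emulates exactly the structure the detector assumes:

* **mEP kernel** — a mixture of one dominant Gaussian lobe (FWHM =
  requested width) and 1–2 opposite-sign side lobes placed 1.5–2.2
  widths away, fully determined by a waveform seed, zero outside
  [latency − 2·width, latency + 3·width]. Side-lobe placement keeps the
  dominant lobe's measured FWHM within a few percent of nominal. The
  family is an invention: real mEPs constrain only latency, width and
  within-subject stereotypy, which the kernel reproduces by fixing the
  seed per (subject, muscle).
* **Recruitment** — effective amplitude
  `amp(A) = amp₀ + gain·(A − thr)` for stimulation amplitude `A > thr`,
  else 0; `amp₀` is the response just above threshold (default draw
  4–8 μV) and `gain` (4–8 μV/mA) the recruitment slope. A channel is
  annotated responding iff its effective amplitude is positive.
* **Artifact** — damped sinusoid `exp(−t/τ)·sin(2πft)` with τ = 3–8 ms,
  f = 150–300 Hz, peak 2–10 μV, shared in shape across facial channels
  (per-channel gain varies) and 20× smaller on limb channels. The
  amplitude range is calibrated so that naive facial detection (no
  rejection) produces false positives while template rejection leaves
  residuals below the facial threshold — the failure mode the rejection
  stage exists to fix must actually occur in the fixture.
* **Line noise** — a 60 Hz sinusoid with one random phase per
  recording; amplitudes 1–5 μV on limb channels, ≤ 0.5 μV facial,
  reflecting that line pickup grows with lead length and that notch
  filtering is configured off for facial channels by default (it was
  found not to help facial detection).
* **Drift and noise** — low-passed (< 2 Hz) random-walk drift (5–20 μV
  RMS) and white noise (6–10 μV SD).

What the generator does **not** model: volume conduction and
cross-talk between muscles, anatomy-dependent contact→threshold
structure, non-stationary noise (movement bursts beyond the occasional
injected "bad channel"), line-frequency wander, harmonics (off by
default), and real artifact shape families beyond damped sinusoids.
Passing the synthetic benchmarks therefore demonstrates the
correctness and internal consistency of the algorithms under their
stated assumptions — not clinical-grade accuracy on patient data,
whose artifact diversity is broader than the simulated family.

## Benchmark problem sizes

The controlled-SNR detection benchmark uses 20 subjects × 20 settings
× 8 channels at 22 kHz/12 s with injected peak heights of 0, 1.5× and
3× the group threshold (the 1.5× level probes the margin just above
the operating point), processed subject-by-subject so memory stays
flat. The stereotypy and duration analyses use the standard
recruitment-based corpus at 8 subjects × 10 settings. These sizes give
a few hundred negative and positive decisions per analysis — enough to
resolve the ≤ 5% false-positive and ≥ 95% recall margins tested.

## Degenerate inputs and tie-breaks

* A channel whose baseline SD is zero cannot be z-scored and is
  auto-excluded rather than failing the whole setting; an identically
  zero recording therefore yields a missing (all-excluded) score, while
  any physically plausible recording with nonzero noise yields 0.
* Equal-height detection peaks: the earliest latency wins. Plateaus
  count once, at their centre sample.
* Muscles absent from a calibration table, with fewer than 4 detected
  responses, or with zero amplitude IQR keep scale 1 with a warning.
* All-excluded settings are flagged `missing` (NaN), never scored 0:
  0 is a measurement ("no capsular response"), missing is the absence
  of one.
* Butterworth filtering trims 2 ms at each epoch edge and restores the
  trimmed samples as zeros, recorded via `edge_trim_ms`; every shipped
  latency window starts after 4 ms, so detection never reads them.

## Known limitations

* F1 here is the standard harmonic mean 2PR/(P+R); a √(P·R) variant is
  available behind a flag for comparison with texts that describe F1
  as a geometric mean.
* The score's claimed independence from montage size is approximate:
  step 5 averages over included muscles, so the same single minimal
  response yields slightly different scores for different channel
  counts. The formula is implemented exactly as specified and the
  inconsistency is noted rather than resolved.
* EDF support targets plain continuous EDF; the bundled writer emits a
  minimal single-record file (16-bit, per-channel physical scaling)
  sufficient for round-tripping, not a general-purpose exporter.
* Per-epoch (single-trial) detection, harmonic comb filtering and
  learning-based artifact models are out of scope.
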