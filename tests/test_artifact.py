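"""Template library construction and the three artifact-rejection routes."""

import numpy as np
import pytest

from mepkit.artifact import (
    ARTIFACT_WINDOW_MS,
    ArtifactTemplateLibrary,
    build_template_library,
    pca_reject,
    template_pca_reject,
    template_reject,
)
from mepkit.core import ValidationError
from mepkit.detect import detect_mep
from mepkit.preprocess import baseline_zscore
from mepkit.simulate import ArtifactSpec, damped_sinusoid, default_channels

from conftest import EPOCH_SAMPLES, FS, gaussian_bump

WIN = slice(int(2e-3 * FS), int(20e-3 * FS))  # 2-20 ms


def _artifact_trace(make_trace, peak=8.0, decay=5.0, freq=220.0, noise=0.0, seed=0,
                    channel=None, extra=None):
    art = damped_sinusoid(ArtifactSpec(peak_uv=peak, decay_ms=decay, osc_freq_hz=freq), FS)
    vals = np.zeros(EPOCH_SAMPLES)
    vals[: art.size] += art
    if noise:
        vals += np.random.default_rng(seed).normal(0, noise, EPOCH_SAMPLES)
    if extra is not None:
        vals += extra
    return make_trace(vals, channel=channel)


@pytest.fixture
def library(make_trace):
    traces = [
        _artifact_trace(make_trace, peak=p, decay=d, freq=f, noise=0.2, seed=i)
        for i, (p, d, f) in enumerate(
            (p, d, f)
            for p in (4.0, 8.0)
            for d in (3.0, 5.0, 7.0)
            for f in (170.0, 220.0, 270.0)
        )
    ]
    return build_template_library(traces)


class TestBuildTemplateLibrary:
    def test_negation_augmentation_doubles_count(self, make_trace):
        traces = [_artifact_trace(make_trace, seed=i, noise=0.3) for i in range(5)]
        lib = build_template_library(traces)
        assert lib.n_templates == 10
        n = lib.n_templates // 2
        np.testing.assert_allclose(lib.templates[n:], -lib.templates[:n])

    def test_single_trace_yields_template_and_negation(self, make_trace):
        lib = build_template_library([_artifact_trace(make_trace)])
        assert lib.n_templates == 2
        np.testing.assert_allclose(lib.templates[1], -lib.templates[0])

    def test_window_cropped_to_2_20_ms(self, make_trace):
        lib = build_template_library([_artifact_trace(make_trace)])
        assert lib.templates.shape[1] == WIN.stop - WIN.start

    def test_smoothing_removes_high_frequency_power(self, make_trace):
        # white-noise input: power above 2 kHz must drop by >= 90%
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 5.0, EPOCH_SAMPLES)
        lib = build_template_library([make_trace(vals)])
        raw_win = vals[WIN] - np.median(vals[-220:])
        freqs = np.fft.rfftfreq(raw_win.size, 1 / FS)
        hf = freqs > 2000.0
        p_raw = np.sum(np.abs(np.fft.rfft(raw_win))[hf] ** 2)
        p_smooth = np.sum(np.abs(np.fft.rfft(lib.templates[0]))[hf] ** 2)
        assert p_smooth < 0.10 * p_raw

    def test_short_trace_rejected(self, make_trace, facial_channel):
        from mepkit.core import AveragedTrace

        short = AveragedTrace(
            values=np.zeros(220), fs_hz=FS, channel=facial_channel,
            n_pulses_averaged=10,
        )
        with pytest.raises(ValidationError):
            build_template_library([short])

    def test_round_trip_through_csv_and_json(self, library, tmp_path):
        library.save(tmp_path / "lib.csv")
        back = ArtifactTemplateLibrary.load(tmp_path / "lib.csv")
        np.testing.assert_allclose(back.templates, library.templates, rtol=1e-12)
        assert back.fs_hz == library.fs_hz


class TestTemplateReject:
    def test_scaled_library_artifact_removed_below_threshold(self, make_trace, library):
        # trace = 2.5x a library shape, no mEP: residual z must stay
        # below the facial detection threshold
        tr = _artifact_trace(make_trace, peak=2.5 * 8.0, decay=5.0, freq=220.0,
                             noise=0.5, seed=42)
        out = template_reject(tr, library)
        det = detect_mep(baseline_zscore(out))
        assert det.status == "no_response"

    def test_zero_trace_passes_through(self, make_trace, library):
        rng = np.random.default_rng(1)
        vals = 0.3 * rng.normal(size=EPOCH_SAMPLES)
        out = template_reject(make_trace(vals), library)
        # scale fits ~0: trace essentially unchanged
        assert np.max(np.abs(out.values - vals)) < 0.5

    def test_overlapping_mep_survives_rejection(self, make_trace, library, times_ms):
        bump = gaussian_bump(times_ms, 9.0, 3.0, 40.0)
        tr = _artifact_trace(make_trace, peak=10.0, decay=5.0, freq=220.0,
                             noise=0.5, seed=3, extra=bump)
        out = template_reject(tr, library)
        peak = np.max(np.abs(out.values[int(7e-3 * FS) : int(11e-3 * FS)]))
        assert peak == pytest.approx(40.0, rel=0.25)
        det = detect_mep(baseline_zscore(out))
        assert det.status == "response"

    def test_only_the_artifact_window_is_modified(self, make_trace, library):
        tr = _artifact_trace(make_trace, noise=0.5, seed=9)
        out = template_reject(tr, library)
        unchanged = np.ones(EPOCH_SAMPLES, dtype=bool)
        unchanged[WIN] = False
        np.testing.assert_array_equal(out.values[unchanged], tr.values[unchanged])

    def test_matched_template_scale_removed(self, make_trace, library):
        # adding c x template_k to a trace and re-rejecting removes
        # nearly all of the added component
        rng = np.random.default_rng(5)
        base_vals = 0.3 * rng.normal(size=EPOCH_SAMPLES)
        k, c = 4, 6.0
        tmpl = library.templates[k]
        spiked = base_vals.copy()
        spiked[WIN] += c * tmpl
        out_spiked = template_reject(make_trace(spiked), library)
        out_base = template_reject(make_trace(base_vals), library)
        diff = out_spiked.values[WIN] - out_base.values[WIN]
        rms = lambda v: np.sqrt(np.mean(v**2))
        assert rms(diff) <= 0.15 * abs(c) * rms(tmpl)


def _multichannel(make_trace, bump_channel=None, bump=None, art_peak=8.0, noise=0.3):
    """Four facial channels sharing one artifact shape with varied gain."""
    chs = [c for c in default_channels() if c.group == "facial"]
    art = damped_sinusoid(
        ArtifactSpec(peak_uv=art_peak, decay_ms=5.0, osc_freq_hz=220.0), FS
    )
    traces = []
    rng = np.random.default_rng(0)
    for i, ch in enumerate(chs):
        vals = np.zeros(EPOCH_SAMPLES)
        vals[: art.size] += art * (0.7 + 0.2 * i)
        if noise:
            vals += rng.normal(0, noise, EPOCH_SAMPLES)
        if bump is not None and ch.label == bump_channel:
            vals += bump
        traces.append(make_trace(vals, channel=ch))
    return traces


class TestPcaReject:
    def test_shared_artifact_removed(self, make_trace):
        traces = _multichannel(make_trace, noise=0.0)
        out = pca_reject(traces)
        # interior of the window, clear of the 0.5 ms edge tapers
        interior = slice(WIN.start + 11, WIN.stop - 11)
        for before, after in zip(traces, out):
            rms_in = np.sqrt(np.mean(before.values[interior] ** 2))
            # compare fluctuation around the window mean (PCA works on
            # centered rows; the mean offset is z-scoring's job)
            resid = after.values[interior] - np.mean(after.values[interior])
            assert np.sqrt(np.mean(resid**2)) < 0.05 * rms_in

    def test_uncorrelated_bump_survives(self, make_trace, times_ms):
        # bump well below the artifact's energy, so PC1 stays the artifact
        bump = gaussian_bump(times_ms, 12.0, 3.0, 12.0)
        traces = _multichannel(
            make_trace, bump_channel="CL_Nasalis", bump=bump, art_peak=20.0
        )
        out = pca_reject(traces)
        peak = np.max(np.abs(out[0].values[int(10e-3 * FS) : int(14e-3 * FS)]))
        assert peak == pytest.approx(12.0, rel=0.25)

    def test_remove_pc1_distorts_overlapping_mep_more_than_median_scaling(
        self, make_trace, times_ms
    ):
        # an mEP overlapping the artifact inflates the least-squares
        # projection, so rank-1 removal oversubtracts; the ratio-median
        # fit ignores the temporally sparse bump samples
        amp = 12.0
        bump = gaussian_bump(times_ms, 6.0, 2.5, amp)
        traces = _multichannel(
            make_trace, bump_channel="CL_Nasalis", bump=bump, art_peak=20.0
        )
        sl = slice(int(4e-3 * FS), int(8e-3 * FS))
        peak_med = np.max(np.abs(pca_reject(traces, scaling="median_scaling")[0].values[sl]))
        peak_pc1 = np.max(np.abs(pca_reject(traces, scaling="remove_pc1")[0].values[sl]))
        assert abs(peak_pc1 - amp) > abs(peak_med - amp)

    def test_single_channel_returns_unchanged_with_warning(self, make_trace):
        tr = _artifact_trace(make_trace, channel=default_channels()[4])
        with pytest.warns(UserWarning):
            out = pca_reject([tr])
        np.testing.assert_array_equal(out[0].values, tr.values)

    def test_limb_channels_untouched_by_facial_only_subset(self, make_trace):
        chs = default_channels()
        traces = _multichannel(make_trace)
        limb = _artifact_trace(make_trace, channel=chs[0], noise=0.5, seed=2)
        out = pca_reject(traces + [limb])
        np.testing.assert_array_equal(out[-1].values, limb.values)


class TestTemplatePcaReject:
    def test_anchored_rejection_not_worse_than_plain_pca(self, make_trace, library):
        traces = _multichannel(make_trace, art_peak=8.0)
        out_pca = pca_reject(traces)
        out_tp = template_pca_reject(traces, library)
        def resid(outs):
            tot = 0.0
            for t in outs:
                w = t.values[WIN]
                tot += np.sqrt(np.mean((w - w.mean()) ** 2))
            return tot
        assert resid(out_tp) <= 1.5 * resid(out_pca)

    def test_single_facial_channel_still_runs(self, make_trace, library):
        tr = _artifact_trace(make_trace, channel=default_channels()[4], noise=0.3)
        out = template_pca_reject([tr], library)
        # augmented matrix has 2 rows, so rejection actually happened
        assert not np.allclose(out[0].values[WIN], tr.values[WIN])

    def test_window_confinement(self, make_trace, library):
        traces = _multichannel(make_trace)
        out = template_pca_reject(traces, library)
        unchanged = np.ones(EPOCH_SAMPLES, dtype=bool)
        unchanged[WIN] = False
        for before, after in zip(traces, out):
            np.testing.assert_array_equal(
                after.values[unchanged], before.values[unchanged]
            )
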