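"""Accuracy, F1 sweeps, waveform correlation, and corpus summaries."""

import numpy as np
import pytest

from mepkit.core import AnnotationSet, AveragedTrace, ChannelDetection, ZScoredTrace
from mepkit.evaluate import (
    corpus_feature_summary,
    detection_accuracy,
    duration_sweep,
    f1_threshold_sweep,
    waveform_correlation_analysis,
)
from mepkit.score import calibrate_normalization

from conftest import EPOCH_SAMPLES, FS, gaussian_bump


def det(label, status, group="facial", peak_z=6.0, lat=10.0):
    if status != "response":
        return ChannelDetection(label=label, group=group, status=status)
    return ChannelDetection(
        label=label, group=group, status=status, peak_z=peak_z, peak_uv=peak_z,
        latency_ms=lat, width_ms=3.0, threshold_used=4.0,
    )


class TestDetectionAccuracy:
    def _records(self, pattern):
        """pattern: list of (setting, label, predicted, annotated)."""
        records, ann = [], {}
        for sid, label, pred, true in pattern:
            records.append(
                (sid, det(label, "response" if pred else "no_response"))
            )
            ann[(sid, label)] = true
        return records, AnnotationSet(ann)

    def test_perfect_predictions_score_one(self):
        pattern = [(f"s{i}", "m", bool(i % 2), bool(i % 2)) for i in range(10)]
        per, summary = detection_accuracy(*self._records(pattern))
        assert summary == {"median": 1.0, "min": 1.0, "overall": 1.0}

    def test_inverted_predictions_score_zero(self):
        pattern = [(f"s{i}", "m", bool(i % 2), not (i % 2)) for i in range(10)]
        _, summary = detection_accuracy(*self._records(pattern))
        assert summary["overall"] == 0.0

    def test_counted_example(self):
        # 3 TP + 5 TN correct out of 10 -> 0.8
        pattern = (
            [(f"tp{i}", "m", True, True) for i in range(3)]
            + [("fp0", "m", True, False)]
            + [(f"tn{i}", "m", False, False) for i in range(5)]
            + [("fn0", "m", False, True)]
        )
        _, summary = detection_accuracy(*self._records(pattern))
        assert summary["overall"] == pytest.approx(0.8)

    def test_excluded_channels_dropped(self):
        records = [("s0", det("m", "excluded")), ("s1", det("m", "response"))]
        ann = AnnotationSet({("s0", "m"): True, ("s1", "m"): True})
        per, summary = detection_accuracy(records, ann)
        assert per.loc["m", "n"] == 1
        assert summary["overall"] == 1.0

    def test_per_muscle_median_and_min(self):
        pattern = [(f"s{i}", "good", True, True) for i in range(4)] + [
            ("s0", "bad", True, False),
            ("s1", "bad", False, False),
        ]
        per, summary = detection_accuracy(*self._records(pattern))
        assert summary["median"] == pytest.approx(0.75)
        assert summary["min"] == pytest.approx(0.5)


class TestF1Sweep:
    def _trace(self, peak_z, channel):
        t = np.arange(EPOCH_SAMPLES) * 1000.0 / FS
        vals = gaussian_bump(t, 10.0, 3.0, peak_z)
        tr = AveragedTrace(
            values=vals, fs_hz=FS, channel=channel, n_pulses_averaged=120
        )
        return ZScoredTrace(
            values=vals, baseline_median_uv=0.0, baseline_sd_uv=1.0, source=tr
        )

    def test_perfect_detector_has_unit_f1_at_all_thresholds(self, facial_channel):
        items = [
            (f"s{i}", self._trace(10.0 if i % 2 else 0.0, facial_channel), bool(i % 2))
            for i in range(10)
        ]
        table = f1_threshold_sweep({"facial": items}, thresholds=[2.0, 4.0, 6.0])
        assert np.allclose(table["f1"], 1.0)

    def test_f1_formula_on_known_confusion(self, facial_channel):
        # detector fires on everything: P = 0.5, R = 1 -> F1 = 2/3
        items = [
            (f"s{i}", self._trace(10.0, facial_channel), i < 5) for i in range(10)
        ]
        table = f1_threshold_sweep({"facial": items}, thresholds=[4.0])
        row = table.iloc[0]
        assert row["precision"] == pytest.approx(0.5)
        assert row["recall"] == pytest.approx(1.0)
        assert row["f1"] == pytest.approx(2 / 3)

    def test_geometric_variant(self, facial_channel):
        items = [
            (f"s{i}", self._trace(10.0, facial_channel), i < 5) for i in range(10)
        ]
        table = f1_threshold_sweep({"facial": items}, thresholds=[4.0], geometric=True)
        assert table.iloc[0]["f1"] == pytest.approx(np.sqrt(0.5))

    def test_optimal_threshold_recovered_between_noise_and_signal(self, facial_channel):
        # bumps at z ~ 5, noise peaks at z ~ 2: best threshold in between
        rng = np.random.default_rng(0)
        items = []
        for i in range(40):
            responding = i % 2 == 0
            height = rng.normal(5.0, 0.3) if responding else rng.normal(2.0, 0.3)
            items.append((f"s{i}", self._trace(height, facial_channel), responding))
        thresholds = [1.0, 2.0, 3.0, 4.0, 6.0, 8.0]
        table = f1_threshold_sweep({"facial": items}, thresholds=thresholds)
        best = table.loc[table["f1"].idxmax(), "threshold"]
        assert 3.0 <= best <= 4.0

    def test_f1_bounded_by_max_of_precision_recall(self, facial_channel):
        rng = np.random.default_rng(1)
        items = [
            (f"s{i}", self._trace(rng.uniform(0, 8), facial_channel), bool(rng.random() < 0.4))
            for i in range(30)
        ]
        table = f1_threshold_sweep({"facial": items}, thresholds=[2.0, 4.0, 6.0])
        assert (table["f1"] <= np.maximum(table["precision"], table["recall"]) + 1e-12).all()


class TestWaveformCorrelation:
    def _trace(self, vals, channel):
        return AveragedTrace(values=vals, fs_hz=FS, channel=channel, n_pulses_averaged=120)

    def test_identical_waveforms_correlate_perfectly(self, facial_channel, times_ms):
        v = gaussian_bump(times_ms, 10.0, 3.0, 5.0) + 0.01 * np.sin(times_ms)
        out = waveform_correlation_analysis(
            [("p1", "m", self._trace(v, facial_channel)),
             ("p1", "m", self._trace(v.copy(), facial_channel))]
        )
        assert out["median_within"] == pytest.approx(1.0)

    def test_negated_waveform_correlates_minus_one(self, facial_channel, times_ms):
        v = gaussian_bump(times_ms, 10.0, 3.0, 5.0) + 0.01 * np.sin(times_ms)
        out = waveform_correlation_analysis(
            [("p1", "m", self._trace(v, facial_channel)),
             ("p2", "m", self._trace(-v, facial_channel))]
        )
        assert out["median_across"] == pytest.approx(-1.0)

    def test_constant_trace_pairs_skipped(self, facial_channel, times_ms):
        v = gaussian_bump(times_ms, 10.0, 3.0, 5.0)
        out = waveform_correlation_analysis(
            [("p1", "m", self._trace(v, facial_channel)),
             ("p1", "m", self._trace(np.zeros(EPOCH_SAMPLES), facial_channel))]
        )
        assert out["n_within"] == 0

    def test_within_subject_exceeds_across_with_fixed_kernels(
        self, facial_channel, times_ms
    ):
        rng = np.random.default_rng(2)
        traces = []
        for subj in range(4):
            kernel = gaussian_bump(
                times_ms, rng.uniform(8, 14), rng.uniform(2, 4), 6.0
            ) * rng.choice([-1, 1])
            for _ in range(4):
                noisy = kernel + 0.5 * rng.normal(size=EPOCH_SAMPLES)
                traces.append((f"p{subj}", "m", self._trace(noisy, facial_channel)))
        out = waveform_correlation_analysis(traces)
        assert out["median_within"] > out["median_across"] + 0.3


class TestDurationSweep:
    def test_full_duration_matches_plain_accuracy(self):
        from mepkit.pipeline import PipelineConfig, run_pipeline
        from mepkit.simulate import simulate_corpus

        corpus = simulate_corpus(2, 3, seed=9, fs_hz=4400.0, duration_s=4.0)
        cfg = PipelineConfig(rejection_method="pca")
        table = duration_sweep(corpus, durations_s=[2.0, 4.0], pipeline_config=cfg)
        records, ann = [], AnnotationSet()
        for rec, a in corpus:
            (res,) = run_pipeline([rec], cfg)
            records.extend((res.setting_id, d) for d in res.detections)
            ann.update(a.annotations)
        _, summary = detection_accuracy(records, ann)
        full = table.loc[table["duration_s"] == 4.0, "overall"].iloc[0]
        assert full == pytest.approx(summary["overall"])

    def test_duration_beyond_recording_rejected(self):
        from mepkit.core import ValidationError
        from mepkit.simulate import simulate_corpus

        corpus = simulate_corpus(1, 1, seed=9, fs_hz=4400.0, duration_s=2.0)
        with pytest.raises(ValidationError):
            duration_sweep(corpus, durations_s=[5.0])


class TestCorpusFeatureSummary:
    def test_single_responding_muscle_frequency(self):
        records = []
        for i in range(5):
            records.append((f"s{i}", det("always", "response")))
            records.append((f"s{i}", det("never", "no_response")))
        table = corpus_feature_summary(records)
        assert table.loc["always", "response_pct"] == 100.0
        assert table.loc["never", "response_pct"] == 0.0

    def test_denominator_counts_only_settings_with_any_response(self):
        records = [
            ("s0", det("a", "response")), ("s0", det("b", "no_response")),
            ("s1", det("a", "no_response")), ("s1", det("b", "no_response")),
            ("s2", det("a", "response")), ("s2", det("b", "response")),
        ]
        table = corpus_feature_summary(records)
        # s1 has no responses and drops from every denominator
        assert table.loc["a", "n_settings"] == 2
        assert table.loc["a", "response_pct"] == 100.0
        assert table.loc["b", "response_pct"] == 50.0

    def test_normalized_amplitude_iqrs_align_after_calibration(self):
        rng = np.random.default_rng(3)
        zs = {"a": 4 + rng.lognormal(1, 0.5, 60), "b": 7 + rng.lognormal(2, 0.7, 60)}
        table = calibrate_normalization({k: list(v) for k, v in zs.items()})
        records = []
        for i, z in enumerate(zs["a"]):
            records.append((f"s{i}", det("a", "response", peak_z=float(z))))
        for i, z in enumerate(zs["b"]):
            records.append((f"s{i}", det("b", "response", group="limb", peak_z=float(z))))
        summary = corpus_feature_summary(records, normalization=table)
        iqr_a = summary.loc["a", "norm_amp_p75"] - summary.loc["a", "norm_amp_p25"]
        iqr_b = summary.loc["b", "norm_amp_p75"] - summary.loc["b", "norm_amp_p25"]
        assert iqr_a == pytest.approx(iqr_b, abs=1e-9)
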