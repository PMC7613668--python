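"""ROC, latency, overlap and response-map evaluation."""
import numpy as np
import pytest

from lfpdetect import evaluate as ev
from lfpdetect import filterchain as fc
from lfpdetect import mlp as ml
from lfpdetect.recording import Annotation, ClassifierTrace


def _trace(labels, dt=1.0, scores=None, hop=1):
    labels = np.asarray(labels, dtype=bool)
    n = len(labels)
    times = (np.arange(n) + 1) * dt
    scores = labels.astype(float) if scores is None else np.asarray(scores)
    return ClassifierTrace(times, scores, labels, hop)


class TestROC:
    def test_perfect_scores_give_auroc_one(self):
        truth = np.array([0, 1, 0, 1, 1, 0])
        roc = ev.roc_curve(truth.astype(float), truth)
        assert roc.auroc == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 10_000)
        roc = ev.roc_curve(rng.uniform(0, 1, 10_000), truth)
        assert roc.auroc == pytest.approx(0.5, abs=0.03)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 2, 500)
        scores = rng.normal(size=500) + truth
        a = ev.roc_curve(scores, truth).auroc
        b = ev.roc_curve(-scores, truth).auroc
        assert a + b == pytest.approx(1.0, abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        truth = rng.integers(0, 2, 400)
        scores = rng.normal(size=400) + 0.8 * truth
        a = ev.roc_curve(scores, truth).auroc
        b = ev.roc_curve(np.exp(scores), truth).auroc
        assert a == pytest.approx(b, abs=1e-12)

    def test_endpoints_and_monotone_rates(self):
        rng = np.random.default_rng(3)
        truth = rng.integers(0, 2, 300)
        roc = ev.roc_curve(rng.normal(size=300) + truth, truth)
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            ev.roc_curve(np.array([0.1, 0.9]), np.array([1, 1]))


class TestLatency:
    def test_detection_at_onset_gives_zero(self):
        trace = _trace([0, 0, 0, 1, 1, 1, 0, 0], dt=1.0)
        res = ev.onset_latency(trace, [Annotation(4.0, 6.0)], search_window_s=5.0)
        assert res.latencies_s[0] == pytest.approx(0.0)
        assert res.n_missed == 0

    def test_mlp_latency_quantized_to_window_hops(self, quantized_model, test_recording):
        """Window-end timestamps force latencies onto the 78.125 ms grid."""
        trace = ml.classify_windows(quantized_model, test_recording, threshold=0.2)
        res = ev.onset_latency(trace, test_recording.annotations)
        hop_s = 20 / 256.0
        for lat, ann in zip(res.latencies_s, test_recording.annotations):
            # detection time is a multiple of the hop; latency = k*hop - onset
            k = (lat + ann.onset_s) / hop_s
            assert k == pytest.approx(round(k), abs=1e-9)

    def test_all_negative_trace_misses_everything(self):
        trace = _trace(np.zeros(20))
        res = ev.onset_latency(trace, [Annotation(2.0, 5.0), Annotation(10.0, 12.0)])
        assert res.n_missed == 2 and res.mean_latency_s is None

    def test_early_positive_is_not_negative_latency(self):
        trace = _trace([1, 1, 0, 0, 1, 1, 1, 0])
        res = ev.onset_latency(trace, [Annotation(4.0, 7.0)], search_window_s=3.0)
        assert res.latencies_s[0] >= 0.0

    def test_empty_annotations_warns(self):
        with pytest.warns(UserWarning, match="no annotations"):
            res = ev.onset_latency(_trace([0, 1]), [])
        assert res.n_detected == 0


class TestOverlap:
    def test_full_coverage_is_100(self):
        trace = _trace(np.ones(10))
        res = ev.overlap_percent(trace, [Annotation(2.0, 6.0)])
        assert res.percents[0] == pytest.approx(100.0)

    def test_no_coverage_is_0(self):
        trace = _trace(np.zeros(10))
        res = ev.overlap_percent(trace, [Annotation(2.0, 6.0)])
        assert res.percents[0] == pytest.approx(0.0)

    def test_half_coverage_is_50(self):
        labels = np.zeros(12)
        labels[4:6] = 1  # covers (3,5] of a 4 s event starting at 3
        res = ev.overlap_percent(_trace(labels), [Annotation(3.0, 7.0)])
        assert res.percents[0] == pytest.approx(50.0)

    def test_zero_overlap_event_is_missed_event(self, quantized_model, test_recording):
        """Overlap 0 implies missed in onset_latency when the search window
        spans the event."""
        trace = ml.classify_windows(quantized_model, test_recording, threshold=0.9)
        ovl = ev.overlap_percent(trace, test_recording.annotations)
        for ann, pct in zip(test_recording.annotations, ovl.percents):
            res = ev.onset_latency(trace, [ann], search_window_s=ann.duration_s)
            if pct == 0.0:
                assert res.n_missed == 1


class TestThresholdAtFPR:
    def test_achieves_target_rate(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=20_000)
        truth = np.zeros(20_000, dtype=bool)
        thr = ev.threshold_at_fpr(scores, truth, 0.05)
        assert np.mean(scores >= thr) == pytest.approx(0.05, abs=0.005)


class TestResponseMap:
    def test_shape_and_range(self, chain_config):
        scorer = ev.filter_chain_scorer(chain_config, norm_uV=2 * 20 / np.pi)
        rm = ev.response_map(scorer, [10.0, 50.0], [5.0, 20.0], repeats=3, seed=0)
        assert rm.mean_output.shape == (2, 2)
        assert np.all((rm.mean_output >= 0) & (rm.mean_output <= 1))

    def test_filter_map_prefers_in_band(self, chain_config):
        """High-amplitude 14 Hz tone drives the chain harder than 50 Hz."""
        scorer = ev.filter_chain_scorer(chain_config, norm_uV=2 * 30 / np.pi)
        rm = ev.response_map(scorer, [14.0, 50.0], [30.0], repeats=5, seed=1)
        assert rm.mean_output[0, 0] > rm.mean_output[1, 0]

    def test_filter_response_monotone_in_amplitude(self, chain_config):
        scorer = ev.filter_chain_scorer(chain_config, norm_uV=2 * 40 / np.pi)
        rm = ev.response_map(scorer, [14.0], [5.0, 10.0, 20.0, 40.0], repeats=5, seed=2)
        col = rm.mean_output[0]
        assert np.all(np.diff(col) >= -0.02)  # Monte-Carlo slack

    def test_super_nyquist_frequency_rejected(self, chain_config):
        scorer = ev.filter_chain_scorer(chain_config, norm_uV=1.0)
        with pytest.raises(ValueError, match="Nyquist"):
            ev.response_map(scorer, [200.0], [5.0], repeats=1, seed=0)

    def test_seeded_map_reproducible(self, quantized_model):
        scorer = ev.mlp_scorer(quantized_model)
        a = ev.response_map(scorer, [10.0], [10.0], repeats=4, seed=7)
        b = ev.response_map(scorer, [10.0], [10.0], repeats=4, seed=7)
        np.testing.assert_array_equal(a.mean_output, b.mean_output)
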