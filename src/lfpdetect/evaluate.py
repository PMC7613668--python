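"""Evaluation battery: ROC, onset latency, label overlap, response maps.

Classifier traces are compared against the interval annotations on the
classifier's own output time base: truth at an output timestamp is
whether that instant falls inside an annotated event, latency is the
delay from clinician onset to the first positive output, overlap is the
fraction of an event's duration covered by positive output, and the
response map probes the trained classifier with 1 s sinusoidal test
tones swept over frequency and amplitude.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn import metrics

from .filterchain import FilterChainConfig, classify_filter
from .mlp import classify_windows
from .recording import Annotation, ClassifierTrace, Recording
from .synth import generate_test_tone

__all__ = [
    "ROCCurve",
    "LatencyResult",
    "OverlapResult",
    "ResponseMap",
    "roc_curve",
    "truth_at_times",
    "threshold_at_fpr",
    "onset_latency",
    "overlap_percent",
    "response_map",
    "filter_chain_scorer",
    "mlp_scorer",
]


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float


@dataclass
class LatencyResult:
    """Per-event detection latency; mean over detected events only."""

    latencies_s: np.ndarray
    n_missed: int

    @property
    def n_detected(self) -> int:
        return len(self.latencies_s)

    @property
    def mean_latency_s(self) -> float | None:
        if len(self.latencies_s) == 0:
            return None
        return float(np.mean(self.latencies_s))


@dataclass
class OverlapResult:
    percents: np.ndarray  # one value in [0, 100] per event
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    @property
    def mean_percent(self) -> float | None:
        return float(np.mean(self.percents)) if len(self.percents) else None


@dataclass
class ResponseMap:
    test_freqs_hz: np.ndarray
    test_amps_uV: np.ndarray
    mean_output: np.ndarray  # (n_freqs, n_amps) in [0, 1]
    repeats: int


def roc_curve(scores: Sequence[float], truth_labels: Sequence[int]) -> ROCCurve:
    """Threshold-sweep ROC with trapezoidal AUROC (scikit-learn backend)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth_labels).astype(int)
    if len(scores) != len(truth):
        raise ValueError("scores and truth must have equal length")
    if len(np.unique(truth)) < 2:
        raise ValueError("truth contains a single class; AUROC undefined")
    fpr, tpr, thr = metrics.roc_curve(truth, scores, drop_intermediate=False)
    return ROCCurve(thr, tpr, fpr, float(metrics.auc(fpr, tpr)))


def truth_at_times(annotations: Sequence[Annotation], times_s: np.ndarray) -> np.ndarray:
    """True where a timestamp falls inside any annotated [onset, offset)."""
    t = np.asarray(times_s, dtype=float)
    truth = np.zeros(len(t), dtype=bool)
    for ann in annotations:
        truth |= (t >= ann.onset_s) & (t < ann.offset_s)
    return truth


def threshold_at_fpr(
    scores: np.ndarray, truth: np.ndarray, target_fpr: float
) -> float:
    """Score threshold whose ``score >= θ`` rule yields ≈ the target FPR."""
    neg = np.asarray(scores, dtype=float)[~np.asarray(truth, dtype=bool)]
    if len(neg) == 0:
        raise ValueError("no negative timesteps to calibrate against")
    return float(np.quantile(neg, 1.0 - target_fpr, method="higher"))


def matched_fpr_latency(
    trace: ClassifierTrace,
    annotations: Sequence[Annotation],
    target_fpr: float = 0.05,
    search_window_s: float = 10.0,
) -> tuple[float, "LatencyResult"]:
    """Re-threshold a trace to a target per-timestep FPR, then measure latency.

    The common operating-point normalization for comparing detectors with
    different score scales: the threshold is the (1 − FPR) quantile of the
    scores at non-event timesteps.
    """
    truth = truth_at_times(annotations, trace.times_s)
    thr = threshold_at_fpr(trace.scores, truth, target_fpr)
    return thr, onset_latency(trace.with_threshold(thr), annotations, search_window_s)


def onset_latency(
    trace: ClassifierTrace,
    annotations: Sequence[Annotation],
    search_window_s: float = 10.0,
) -> LatencyResult:
    """First-positive delay per event within [onset, onset + search window].

    Events with no positive output inside their search window count as
    missed; earlier positives are false positives, not negative latency.
    """
    if len(annotations) == 0:
        warnings.warn("no annotations: empty latency result")
        return LatencyResult(np.empty(0), 0)
    lat, missed = [], 0
    for ann in annotations:
        sel = (
            (trace.times_s >= ann.onset_s)
            & (trace.times_s <= ann.onset_s + search_window_s)
            & trace.labels
        )
        hits = np.flatnonzero(sel)
        if len(hits) == 0:
            missed += 1
        else:
            lat.append(float(trace.times_s[hits[0]] - ann.onset_s))
    return LatencyResult(np.array(lat), missed)


def overlap_percent(
    trace: ClassifierTrace, annotations: Sequence[Annotation], fs: float | None = None
) -> OverlapResult:
    """Percent of each event's duration covered by positive classifier output.

    Labels are held piecewise-constant over the ``hop_samples`` interval
    preceding each output timestamp.
    """
    if len(trace) == 0:
        zeros = np.zeros(len(annotations))
        return OverlapResult(zeros, *_hist(zeros))
    hop_dt = float(np.median(np.diff(trace.times_s))) if len(trace) > 1 else 0.0
    starts = trace.times_s - hop_dt
    percents = []
    for ann in annotations:
        if ann.duration_s <= 0:
            warnings.warn(f"zero-duration event at {ann.onset_s}s excluded")
            continue
        ov = np.clip(
            np.minimum(trace.times_s, ann.offset_s) - np.maximum(starts, ann.onset_s),
            0.0,
            None,
        )
        covered = float(np.sum(ov[trace.labels]))
        percents.append(100.0 * covered / ann.duration_s)
    percents = np.clip(np.array(percents), 0.0, 100.0)
    return OverlapResult(percents, *_hist(percents))


def _hist(percents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    counts, edges = np.histogram(percents, bins=np.linspace(0.0, 100.0, 11))
    return counts, edges


def response_map(
    scorer: Callable[[Recording], float],
    freqs: Sequence[float],
    amps: Sequence[float],
    repeats: int = 10,
    seed: int = 0,
    fs: float = 256.0,
    duration_s: float = 1.0,
    background_rms_uV: float = 1.0,
) -> ResponseMap:
    """Mean classifier output for sinusoidal test tones over a (f, A) grid.

    Each cell averages ``repeats`` tones with fresh random phase and
    background-noise realization.
    """
    freqs = np.asarray(freqs, dtype=float)
    amps = np.asarray(amps, dtype=float)
    if np.any(freqs >= fs / 2):
        raise ValueError("all test frequencies must lie below Nyquist")
    rng = np.random.default_rng(seed)
    out = np.empty((len(freqs), len(amps)))
    for i, f in enumerate(freqs):
        for j, a in enumerate(amps):
            vals = [
                scorer(
                    generate_test_tone(
                        f, a, duration_s, fs,
                        phase=float(rng.uniform(0, 2 * np.pi)),
                        background_rms_uV=background_rms_uV,
                        seed=int(rng.integers(0, 2**31)),
                    )
                )
                for _ in range(repeats)
            ]
            out[i, j] = float(np.mean(vals))
    return ResponseMap(freqs, amps, np.clip(out, 0.0, 1.0), repeats)


def filter_chain_scorer(
    config: FilterChainConfig, norm_uV: float, arithmetic: str = "float"
) -> Callable[[Recording], float]:
    """Score = max envelope during the tone ÷ a full-scale reference envelope.

    ``norm_uV`` should be the steady-state envelope of a full-scale
    in-band tone (2·A_max/π for peak amplitude A_max), mapping the
    detector output onto [0, 1] alongside the network's scores.
    """

    def score(rec: Recording) -> float:
        trace = classify_filter(rec, config, arithmetic=arithmetic)
        return float(min(1.0, np.max(trace.scores) / norm_uV))

    return score


def mlp_scorer(model, threshold: float = 0.5, consensus: int = 3) -> Callable[[Recording], float]:
    """Mean consensus-adjusted network score over the stimulus recording."""

    def score(rec: Recording) -> float:
        trace = classify_windows(model, rec, threshold, consensus)
        return float(np.mean(trace.scores)) if len(trace) else 0.0

    return score
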