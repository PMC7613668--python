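"""Core containers: annotated single-channel recordings and classifier traces.

Amplitudes are microvolts throughout; times are seconds from record start;
annotation intervals are half-open ``[onset_s, offset_s)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Annotation", "Recording", "ClassifierTrace"]


@dataclass(frozen=True, order=True)
class Annotation:
    """A labeled interval, e.g. a clinician-marked seizure event."""

    onset_s: float
    offset_s: float
    label: str = "seizure"

    def __post_init__(self) -> None:
        if not 0.0 <= self.onset_s < self.offset_s:
            raise ValueError(
                f"annotation requires 0 <= onset < offset, got [{self.onset_s}, {self.offset_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class Recording:
    """A uniformly sampled single-channel signal with optional annotations.

    Parameters
    ----------
    samples
        Amplitude sequence in microvolts.
    fs
        Sampling rate in Hz, > 0.
    annotations
        Non-overlapping, onset-sorted intervals within the record duration.
    """

    samples: np.ndarray
    fs: float
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.annotations = sorted(self.annotations)
        dur = self.duration_s
        prev_off = 0.0
        for ann in self.annotations:
            if ann.onset_s < prev_off:
                raise ValueError(f"annotations overlap at onset {ann.onset_s}")
            # half-sample slack absorbs rounding of offsets computed from indices
            if ann.offset_s > dur + 0.5 / self.fs:
                raise ValueError(
                    f"annotation offset {ann.offset_s}s exceeds duration {dur}s"
                )
            prev_off = ann.offset_s

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def annotation_mask(self) -> np.ndarray:
        """Boolean per-sample mask, True inside any annotated interval."""
        mask = np.zeros(self.n_samples, dtype=bool)
        for ann in self.annotations:
            i0 = int(round(ann.onset_s * self.fs))
            i1 = int(round(ann.offset_s * self.fs))
            mask[i0:i1] = True
        return mask


@dataclass
class ClassifierTrace:
    """Time-aligned classifier scores and binary decisions.

    ``times_s`` mark the instant each output becomes available (the end of
    the sample or window that produced it); labels are held piecewise
    constant over the preceding ``hop_samples`` interval.
    """

    times_s: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    hop_samples: int = 1

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if not (len(self.times_s) == len(self.scores) == len(self.labels)):
            raise ValueError("times, scores and labels must have equal length")
        if len(self.times_s) > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)

    def with_threshold(self, threshold: float) -> "ClassifierTrace":
        """Re-threshold the stored scores, keeping times and hop."""
        return ClassifierTrace(
            self.times_s, self.scores, self.scores >= threshold, self.hop_samples
        )

    @property
    def n_transitions(self) -> int:
        if len(self.labels) < 2:
            return 0
        return int(np.sum(self.labels[1:] != self.labels[:-1]))
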