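"""Synthetic LFP generation.

Emulates the statistical structure that intracranial seizure detectors
assume: long stretches of ~1 µVrms pink-noise background punctuated by
rare, seconds-long epileptiform bursts an order of magnitude larger
(~10 µVrms) whose energy overlaps the 8–22 Hz detection band. Two burst
templates are provided: a spike-wave train (low-frequency fundamental
with strong harmonics, the textbook ictal morphology) and a narrowband
oscillation confined to a given band.

Every generator is a pure function of its arguments including the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .exceptions import GenerationError
from .recording import Annotation, Recording

__all__ = [
    "SynthConfig",
    "generate_background",
    "generate_event",
    "synthesize_recording",
    "generate_test_tone",
]

#: taper length applied to each end of a burst, seconds
EVENT_TAPER_S = 0.5


@dataclass
class SynthConfig:
    """Parameters of a synthetic long-term recording.

    Defaults reproduce the amplitude scales of chronically sensed LFP
    (1 µVrms background vs 10 µVrms epileptiform activity) and an event
    density of 30 events per 24 h (1.25/h).
    """

    duration_s: float = 3600.0
    fs: float = 256.0
    background_rms_uV: float = 1.0
    event_rms_uV: float = 10.0
    event_rate_per_hour: float = 1.25
    event_duration_range_s: tuple[float, float] = (4.0, 10.0)
    event_band_hz: tuple[float, float] = (8.0, 22.0)
    template: str = "spike_wave"
    count_mode: str = "fixed"  # "fixed" (rounded expectation) or "poisson"
    min_gap_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if not self.event_rms_uV > self.background_rms_uV:
            raise ValueError("event_rms_uV must exceed background_rms_uV")
        if self.event_rate_per_hour < 0:
            raise ValueError("event_rate_per_hour must be non-negative")
        lo, hi = self.event_duration_range_s
        if not 0 < lo <= hi:
            raise ValueError("event_duration_range_s must be positive and ordered")
        if self.count_mode not in ("fixed", "poisson"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-weighted Gaussian noise, unit-free (caller rescales)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0  # avoid the DC singularity
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x - x.mean()


def _scale_to_rms(x: np.ndarray, rms: float) -> np.ndarray:
    cur = float(np.sqrt(np.mean(np.square(x))))
    if cur == 0.0 or rms == 0.0:
        return np.zeros_like(x)
    return x * (rms / cur)


def generate_background(
    duration_s: float, fs: float = 256.0, rms_uV: float = 1.0, seed: int = 0
) -> Recording:
    """Pink (1/f) Gaussian background noise scaled to the requested rms.

    Deterministic in ``seed``; returns an annotation-free :class:`Recording`.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if rms_uV < 0:
        raise ValueError("rms_uV must be non-negative")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    x = _scale_to_rms(_pink_noise(n, rng), rms_uV)
    return Recording(x, fs)


def _taper(n: int, fs: float, taper_s: float = EVENT_TAPER_S) -> np.ndarray:
    """Raised-cosine onset/offset ramp; total length n samples."""
    nt = min(int(round(taper_s * fs)), n // 2)
    env = np.ones(n)
    if nt > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(nt) / nt))
        env[:nt] = ramp
        env[-nt:] = ramp[::-1]
    return env


def generate_event(
    duration_s: float,
    fs: float = 256.0,
    rms_uV: float = 10.0,
    band_hz: tuple[float, float] = (8.0, 22.0),
    seed: int = 0,
    template: str = "spike_wave",
    fundamental_hz: float = 4.0,
) -> np.ndarray:
    """One amplitude-tapered epileptiform burst, scaled to ``rms_uV``.

    ``template="spike_wave"`` builds a sharp periodic discharge as a
    harmonic series of ``fundamental_hz`` (harmonics up to ~40 Hz, 1/k
    amplitudes, phase-locked) — energy concentrated at the fundamental
    with strong components through the detection band.
    ``template="narrowband"`` band-passes white noise into ``band_hz``.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    lo, hi = band_hz
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band_hz {band_hz} must lie inside (0, fs/2)")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    if template == "spike_wave":
        phi = rng.uniform(0.0, 2 * np.pi)
        k_max = int(min(40.0, 0.45 * fs) // fundamental_hz)
        x = np.zeros(n)
        for k in range(1, max(k_max, 1) + 1):
            x += np.sin(2 * np.pi * k * fundamental_hz * t + k * phi) / k
    elif template == "narrowband":
        sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
        x = signal.sosfilt(sos, rng.standard_normal(n))
    else:
        raise ValueError(f"unknown template {template!r}")
    x = x * _taper(n, fs)
    return _scale_to_rms(x, rms_uV)


def _draw_event_count(cfg: SynthConfig, rng: np.random.Generator) -> int:
    expectation = cfg.event_rate_per_hour * cfg.duration_s / 3600.0
    if cfg.count_mode == "fixed":
        return int(round(expectation))
    return int(rng.poisson(expectation))


def synthesize_recording(config: SynthConfig) -> Recording:
    """Background plus randomly placed, non-overlapping epileptiform events.

    Event onsets are drawn uniformly and rejection-sampled for pairwise
    disjointness with at least ``min_gap_s`` between events. Each inserted
    event gets one annotation exactly covering its tapered extent.

    Raises
    ------
    GenerationError
        If the requested events cannot be placed without overlap.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    samples = _scale_to_rms(_pink_noise(n, rng), config.background_rms_uV)

    n_events = _draw_event_count(config, rng)
    lo_d, hi_d = config.event_duration_range_s
    if n_events > 0:
        worst = n_events * hi_d + (n_events - 1) * config.min_gap_s
        if worst > config.duration_s:
            raise GenerationError(
                f"{n_events} events of up to {hi_d}s with {config.min_gap_s}s gaps "
                f"cannot fit in {config.duration_s}s without overlap"
            )

    placed: list[tuple[int, int]] = []  # sample-index intervals
    gap = int(round(config.min_gap_s * config.fs))
    max_attempts = 1000 * max(n_events, 1)
    attempts = 0
    while len(placed) < n_events:
        if attempts >= max_attempts:
            raise GenerationError(
                f"could not place {n_events} disjoint events (min gap "
                f"{config.min_gap_s}s) in {config.duration_s}s after {attempts} draws"
            )
        attempts += 1
        dur = rng.uniform(lo_d, hi_d)
        n_ev = int(round(dur * config.fs))
        if n_ev > n:
            continue
        start = int(rng.integers(0, n - n_ev + 1))
        stop = start + n_ev
        if any(start < s1 + gap and s0 - gap < stop for s0, s1 in placed):
            continue
        placed.append((start, stop))

    annotations = []
    for start, stop in sorted(placed):
        burst = generate_event(
            (stop - start) / config.fs,
            config.fs,
            config.event_rms_uV,
            config.event_band_hz,
            seed=int(rng.integers(0, 2**31)),
            template=config.template,
        )
        samples[start : start + len(burst)] += burst
        annotations.append(
            Annotation(start / config.fs, (start + len(burst)) / config.fs, "seizure")
        )
    return Recording(samples, config.fs, annotations)


def generate_test_tone(
    freq_hz: float,
    amplitude_uV: float,
    duration_s: float = 1.0,
    fs: float = 256.0,
    phase: float = 0.0,
    background_rms_uV: float = 0.0,
    seed: int = 0,
) -> Recording:
    """A sinusoidal test stimulus over fresh background noise.

    Used for the frequency/amplitude response-map experiment: a 1 s tone
    of peak amplitude ``amplitude_uV`` at ``freq_hz``, optionally riding
    on pink noise of ``background_rms_uV``.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if not 0 < freq_hz < fs / 2:
        raise ValueError(f"freq_hz {freq_hz} must lie inside (0, fs/2)")
    if amplitude_uV < 0:
        raise ValueError("amplitude_uV must be non-negative")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = amplitude_uV * np.sin(2 * np.pi * freq_hz * t + phase)
    if background_rms_uV > 0:
        rng = np.random.default_rng(seed)
        x = x + _scale_to_rms(_pink_noise(n, rng), background_rms_uV)
    return Recording(x, fs)
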