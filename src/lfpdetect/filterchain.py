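"""The baseline band-power detector: band-pass → rectify → EMA → threshold.

Mirrors the signal chain deployed in resource-constrained implantable
pulse generators: an 8–22 Hz 4th-order Butterworth band-pass realized as
a cascade of Direct Form I biquads with 16-bit coefficients and 32-bit
saturating accumulators, followed by an exponential-moving-average
envelope (decay 1/32, a single right-shift in fixed point) and a scalar
threshold. A floating-point reference path exists for validation; the
fixed-point path is bit-true to the embedded arithmetic.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .exceptions import PreconditionError, QuantizationError
from .recording import ClassifierTrace, Recording

__all__ = [
    "FilterChainConfig",
    "BiquadCascade",
    "FixedPointCascade",
    "design_bandpass",
    "quantize_coefficients",
    "filter_float",
    "filter_fixed",
    "envelope_ema",
    "envelope_ema_fixed",
    "classify_filter",
    "fixed_point_error_bound",
    "measure_band_edges",
]


@dataclass
class FilterChainConfig:
    """Operating parameters of the filter-chain classifier.

    ``threshold_uV`` is compared against the rectified-mean envelope (for
    an in-band sinusoid of peak A the steady-state envelope is 2A/π).
    ``input_lsb_uV`` sets the µV weight of one integer input step on the
    fixed-point path (full scale ±32767 LSB).
    """

    low_hz: float = 8.0
    high_hz: float = 22.0
    order: int = 4
    fs: float = 256.0
    ema_decay_samples: int = 32
    threshold_uV: float = 3.0
    input_lsb_uV: float = 0.05
    order_is_per_edge: bool = False  # True reads "order" as poles per band edge
    ema_mode: str = "factor"  # "factor": alpha=1/decay; "time_constant": alpha=1-exp(-1/decay)

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz < self.fs / 2:
            raise ValueError(
                f"band edges must satisfy 0 < {self.low_hz} < {self.high_hz} < fs/2"
            )
        if self.ema_decay_samples < 1:
            raise ValueError("ema_decay_samples must be >= 1")
        if self.order < 2 or (not self.order_is_per_edge and self.order % 2):
            raise ValueError("total band-pass order must be an even integer >= 2")


@dataclass
class BiquadCascade:
    """Float-valued second-order sections, scipy ``sos`` layout (n, 6)."""

    sos: np.ndarray

    def __post_init__(self) -> None:
        self.sos = np.atleast_2d(np.asarray(self.sos, dtype=float))
        if self.sos.shape[1] != 6:
            raise ValueError("sos must have six columns (b0,b1,b2,a0,a1,a2)")

    @property
    def n_sections(self) -> int:
        return self.sos.shape[0]

    @property
    def order(self) -> int:
        return 2 * self.n_sections

    def is_stable(self) -> bool:
        for sec in self.sos:
            poles = np.roots([sec[3], sec[4], sec[5]])
            if np.any(np.abs(poles) >= 1.0):
                return False
        return True

    def freq_response(self, freqs_hz: np.ndarray, fs: float) -> np.ndarray:
        _, h = signal.sosfreqz(self.sos, worN=np.asarray(freqs_hz, float), fs=fs)
        return h


@dataclass
class FixedPointCascade:
    """Integer-quantized biquad cascade.

    Coefficients are stored as 16-bit signed integers in a per-section
    Qn.m fixed-point format; ``shifts`` holds each section's fractional
    bit count m (the arithmetic right-shift renormalizing its output).
    """

    sections: np.ndarray  # (n, 5) int: b0, b1, b2, a1, a2
    shifts: list[int]
    coeff_bits: int = 16
    accum_bits: int = 32

    def __post_init__(self) -> None:
        self.sections = np.atleast_2d(np.asarray(self.sections, dtype=np.int64))
        if self.sections.shape[1] != 5:
            raise ValueError("sections must have five columns (b0,b1,b2,a1,a2)")
        lim = 1 << (self.coeff_bits - 1)
        if np.any(self.sections < -lim) or np.any(self.sections > lim - 1):
            raise ValueError("quantized coefficient outside signed coeff_bits range")

    @property
    def n_sections(self) -> int:
        return self.sections.shape[0]

    def dequantize(self) -> BiquadCascade:
        """Restore a float cascade from the stored integers (exact)."""
        sos = np.empty((self.n_sections, 6))
        for i, (sec, sh) in enumerate(zip(self.sections, self.shifts)):
            scale = float(1 << sh)
            b0, b1, b2, a1, a2 = (float(v) / scale for v in sec)
            sos[i] = [b0, b1, b2, 1.0, a1, a2]
        return BiquadCascade(sos)


def design_bandpass(config: FilterChainConfig) -> BiquadCascade:
    """Butterworth band-pass of the configured total order, factored into biquads.

    Discretized by the bilinear transform with pre-warped band edges
    (scipy's ``butter``), so the −3 dB points land on ``low_hz`` and
    ``high_hz`` by construction. The overall gain is distributed by
    cumulative peak scaling — after each section the partial cascade's
    peak magnitude response is 1 — so intermediate fixed-point signals
    stay within the 16-bit inter-section word.
    """
    n_per_edge = config.order if config.order_is_per_edge else config.order // 2
    z, p, k = signal.butter(
        n_per_edge,
        [config.low_hz, config.high_hz],
        btype="bandpass",
        fs=config.fs,
        output="zpk",
    )
    sos = signal.zpk2sos(z, p, 1.0)
    freqs = np.linspace(0.0, config.fs / 2, 2048)
    for j in range(sos.shape[0]):
        _, h = signal.sosfreqz(sos[: j + 1], worN=freqs, fs=config.fs)
        sos[j, :3] /= float(np.max(np.abs(h)))
    # total gain ends at 1/overall peak = k for a Butterworth band-pass
    return BiquadCascade(sos)


def quantize_coefficients(
    cascade: BiquadCascade, coeff_bits: int = 16, int_bits: int = 2
) -> FixedPointCascade:
    """Round each coefficient to the nearest value representable in Qn.m.

    Default Q2.13: 2 integer bits cover the ±4 coefficient range of any
    stable biquad, 13 fractional bits give a half-LSB error of 2^-14.

    Raises
    ------
    QuantizationError
        If a coefficient overflows the format, or a section loses
        stability after rounding.
    """
    if not np.all(np.isfinite(cascade.sos)):
        raise QuantizationError("cascade contains non-finite coefficients")
    frac_bits = coeff_bits - 1 - int_bits
    if frac_bits < 1:
        raise QuantizationError("int_bits too large for coeff_bits")
    scale = 1 << frac_bits
    lim = 1 << (coeff_bits - 1)
    sections = np.empty((cascade.n_sections, 5), dtype=np.int64)
    for i, sec in enumerate(cascade.sos):
        b0, b1, b2, a0, a1, a2 = sec
        coeffs = np.array([b0, b1, b2, a1, a2]) / a0
        q = np.round(coeffs * scale).astype(np.int64)
        if np.any(q < -lim) or np.any(q > lim - 1):
            raise QuantizationError(
                f"section {i}: coefficient magnitude exceeds Q{int_bits}.{frac_bits} range"
            )
        sections[i] = q
    fpc = FixedPointCascade(sections, [frac_bits] * cascade.n_sections, coeff_bits)
    if not fpc.dequantize().is_stable():
        raise QuantizationError("a section became unstable after quantization")
    return fpc


def filter_float(cascade: BiquadCascade, samples: np.ndarray) -> np.ndarray:
    """Floating-point reference filtering (scipy ``sosfilt``)."""
    return signal.sosfilt(cascade.sos, np.asarray(samples, dtype=float))


def _sat32(v: int, counter: list[int]) -> int:
    if v > 2147483647:
        counter[0] += 1
        return 2147483647
    if v < -2147483648:
        counter[0] += 1
        return -2147483648
    return v


def filter_fixed(
    cascade: FixedPointCascade, samples: np.ndarray
) -> tuple[np.ndarray, int]:
    """Bit-true Direct Form I cascade on integer samples.

    Per section: five 16×16-bit products accumulated with 32-bit
    saturating adds, renormalized by an arithmetic right shift with
    round-half-away-from-zero, and the section output saturated to the
    16-bit input range of the next stage.

    Returns the output sequence and the number of saturation events.
    """
    x = np.asarray(samples)
    if np.any(x > 32767) or np.any(x < -32768):
        raise PreconditionError("input samples must be representable in 16-bit signed")
    data = [int(v) for v in x]
    sat = [0]
    for (b0, b1, b2, a1, a2), sh in zip(cascade.sections, cascade.shifts):
        b0, b1, b2, a1, a2 = int(b0), int(b1), int(b2), int(a1), int(a2)
        half = 1 << (sh - 1)
        out = []
        x1 = x2 = y1 = y2 = 0
        for xn in data:
            acc = _sat32(b0 * xn, sat)
            acc = _sat32(acc + b1 * x1, sat)
            acc = _sat32(acc + b2 * x2, sat)
            acc = _sat32(acc - a1 * y1, sat)
            acc = _sat32(acc - a2 * y2, sat)
            if acc >= 0:
                yn = (acc + half) >> sh
            else:
                yn = -((-acc + half) >> sh)
            if yn > 32767:
                sat[0] += 1
                yn = 32767
            elif yn < -32768:
                sat[0] += 1
                yn = -32768
            x2, x1 = x1, xn
            y2, y1 = y1, yn
            out.append(yn)
        data = out
    if sat[0]:
        warnings.warn(f"fixed-point filter saturated {sat[0]} time(s)", RuntimeWarning)
    return np.array(data, dtype=np.int64), sat[0]


def fixed_point_error_bound(cascade: FixedPointCascade, n_impulse: int = 4096) -> float:
    """Worst-case output error (in output LSB) of shift rounding.

    Each section's renormalization injects at most 0.5 LSB per sample.
    Because the rounded output is what feeds the section's own recursion,
    that noise is shaped by 1/A_k(z) before passing through the remaining
    sections, so the bound is 0.5·Σ_k ‖(1/A_k)·H_{k+1..n}‖₁ (l1 norms of
    the corresponding impulse responses). Valid against the float
    reference run with the *dequantized* coefficients and assuming no
    saturation.
    """
    deq = cascade.dequantize().sos
    imp = np.zeros(n_impulse)
    imp[0] = 1.0
    bound = 0.0
    for k in range(cascade.n_sections):
        g = signal.lfilter([1.0], deq[k, 3:], imp)  # 1/A_k
        g = signal.sosfilt(deq[k + 1 :], g) if k + 1 < cascade.n_sections else g
        bound += 0.5 * float(np.sum(np.abs(g)))
    return bound


def envelope_ema(
    samples: np.ndarray, decay_samples: int = 32, mode: str = "factor"
) -> np.ndarray:
    """Rectify-and-smooth envelope: y[n] = y[n−1] + α(|x[n]| − y[n−1]), y[−1]=0.

    ``mode="factor"`` uses α = 1/decay_samples (a single right shift in
    the embedded implementation); ``mode="time_constant"`` reads the
    decay as an exponential time constant, α = 1 − exp(−1/decay).
    """
    if decay_samples < 1:
        raise ValueError("decay_samples must be >= 1")
    if mode == "factor":
        alpha = 1.0 / decay_samples
    elif mode == "time_constant":
        alpha = 1.0 - np.exp(-1.0 / decay_samples)
    else:
        raise ValueError(f"unknown ema mode {mode!r}")
    rect = np.abs(np.asarray(samples, dtype=float))
    # y[n] = (1-alpha) y[n-1] + alpha r[n]  -> first-order IIR
    return signal.lfilter([alpha], [1.0, alpha - 1.0], rect)


def envelope_ema_fixed(
    samples: np.ndarray, decay_samples: int = 32
) -> np.ndarray:
    """Integer EMA envelope with an extended-precision accumulator.

    The embedded form keeps the envelope in a 32-bit accumulator scaled
    by ``decay_samples`` (acc = y·decay), so the update is
    ``acc += |x| − round(acc/decay)`` — a shift-and-round when decay is a
    power of two. Returns the envelope in accumulator units; divide by
    ``decay_samples`` for input-LSB units.
    """
    if decay_samples < 1:
        raise ValueError("decay_samples must be >= 1")
    shift = int(decay_samples).bit_length() - 1
    pow2 = (1 << shift) == decay_samples
    half = 1 << (shift - 1) if shift > 0 else 0
    acc = 0
    out = np.empty(len(samples), dtype=np.int64)
    for i, xn in enumerate(np.asarray(samples)):
        r = abs(int(xn))
        if pow2:
            y = (acc + half) >> shift if shift > 0 else acc
        else:
            y = (acc + decay_samples // 2) // decay_samples
        acc = acc + r - y
        out[i] = acc
    return out


def classify_filter(
    recording: Recording,
    config: FilterChainConfig,
    arithmetic: str = "float",
) -> ClassifierTrace:
    """Run the full chain on a recording, one output per input sample.

    ``arithmetic="float"`` uses the reference float path; ``"fixed"`` is
    bit-true to the embedded integer implementation (input quantized at
    ``config.input_lsb_uV`` per LSB). Scores are the envelope in µV;
    labels are ``envelope >= threshold_uV``.
    """
    if recording.fs != config.fs:
        raise PreconditionError(
            f"recording fs {recording.fs} != chain fs {config.fs}; "
            "resample the recording first (io.resample_recording)"
        )
    cascade = design_bandpass(config)
    if arithmetic == "float":
        filtered = filter_float(cascade, recording.samples)
        env = envelope_ema(filtered, config.ema_decay_samples, config.ema_mode)
    elif arithmetic == "fixed":
        fpc = quantize_coefficients(cascade)
        ints = np.clip(
            np.round(recording.samples / config.input_lsb_uV), -32768, 32767
        ).astype(np.int64)
        filtered, _ = filter_fixed(fpc, ints)
        acc = envelope_ema_fixed(filtered, config.ema_decay_samples)
        env = acc.astype(float) * config.input_lsb_uV / config.ema_decay_samples
    else:
        raise ValueError(f"unknown arithmetic {arithmetic!r}")
    n = len(env)
    times = (np.arange(n) + 1) / config.fs
    return ClassifierTrace(times, env, env >= config.threshold_uV, hop_samples=1)


def measure_band_edges(cascade: BiquadCascade, fs: float) -> tuple[float, float]:
    """Locate the −3 dB (half-power) frequencies of a band-pass cascade."""

    def mag2(f: float) -> float:
        return float(np.abs(cascade.freq_response(np.array([f]), fs))[0]) ** 2 - 0.5

    freqs = np.linspace(0.1, fs / 2 - 0.1, 4096)
    mag = np.abs(cascade.freq_response(freqs, fs))
    peak = int(np.argmax(mag))
    lo = optimize.brentq(mag2, freqs[0], freqs[peak])
    hi = optimize.brentq(mag2, freqs[peak], freqs[-1])
    return float(lo), float(hi)
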