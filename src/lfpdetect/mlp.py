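"""Compact neural classifiers for windowed LFP samples.

A few dozen units suffice for seizure-state classification: the default
model maps a 20-sample input window through one hidden layer of 8
rectified-linear units to a single logistic output (177 parameters).
An optional 1-D convolutional front end (a small learned filter bank)
is provided for comparison. Post-training symmetric 8-bit quantization
produces the deployment artifact; windowed inference with a
consensus-of-three adjusted output suppresses label toggling without
recurrent state.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .recording import ClassifierTrace, Recording

__all__ = [
    "MLPModel",
    "ConvModel",
    "QuantizedMLP",
    "init_mlp",
    "init_conv",
    "forward",
    "conv_forward",
    "quantize_model",
    "classify_windows",
]

#: default µV full-scale used to normalize raw windows (an implant cannot
#: standardize per window online, so a fixed gain is baked into the model)
DEFAULT_INPUT_SCALE_UV = 50.0


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ez = np.exp(x[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class MLPModel:
    """Dense feed-forward network: window_len → hidden_sizes → 1.

    ``weights[i]`` has shape (fan_in, fan_out); hidden activation is
    ReLU, output activation logistic, so scores lie in (0, 1).
    """

    window_len: int
    hidden_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    input_scale_uV: float = DEFAULT_INPUT_SCALE_UV
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dims = [self.window_len, *self.hidden_sizes, 1]
        for i, w in enumerate(self.weights):
            if w.shape != (dims[i], dims[i + 1]):
                raise ValueError(
                    f"layer {i} weight shape {w.shape} != {(dims[i], dims[i + 1])}"
                )

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return forward(self, windows)


@dataclass
class ConvModel:
    """1-D convolutional front end (filter bank) followed by an MLP head."""

    window_len: int
    kernels: np.ndarray  # (n_kernels, kernel_len)
    stride: int
    head: MLPModel
    input_scale_uV: float = DEFAULT_INPUT_SCALE_UV
    activation: str = "relu"  # or "linear"

    def __post_init__(self) -> None:
        k, L = self.kernels.shape
        flen = (self.window_len - L) // self.stride + 1
        if flen < 1:
            raise ValueError("kernel longer than input window")
        if self.head.window_len != k * flen:
            raise ValueError(
                f"head expects {self.head.window_len} features, front end yields {k * flen}"
            )

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return conv_forward(self, windows)


@dataclass
class QuantizedMLP:
    """8-bit deployment form: per-tensor symmetric integers plus scales.

    Inference dequantizes (int × scale) and computes in real arithmetic,
    matching an interpreter-style embedded runtime.
    """

    window_len: int
    hidden_sizes: list[int]
    weights_q: list[np.ndarray]  # int8 matrices
    weight_scales: list[float]
    biases_q: list[np.ndarray]
    bias_scales: list[float]
    input_scale_uV: float = DEFAULT_INPUT_SCALE_UV
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dims = [self.window_len, *self.hidden_sizes, 1]
        for i, w in enumerate(self.weights_q):
            if w.shape != (dims[i], dims[i + 1]):
                raise ValueError(
                    f"layer {i} quantized weight shape {w.shape} != {(dims[i], dims[i + 1])}"
                )

    def dequantize(self) -> MLPModel:
        return MLPModel(
            self.window_len,
            list(self.hidden_sizes),
            [w.astype(float) * s for w, s in zip(self.weights_q, self.weight_scales)],
            [b.astype(float) * s for b, s in zip(self.biases_q, self.bias_scales)],
            self.input_scale_uV,
            dict(self.metadata),
        )

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return forward(self.dequantize(), windows)


def init_mlp(
    window_len: int = 20,
    hidden_sizes: list[int] | tuple[int, ...] = (8,),
    seed: int = 0,
    input_scale_uV: float = DEFAULT_INPUT_SCALE_UV,
) -> MLPModel:
    """Glorot-uniform initial weights, zero biases, deterministic in seed."""
    if window_len < 1 or any(h < 1 for h in hidden_sizes):
        raise ValueError("window_len and hidden sizes must be >= 1")
    if len(hidden_sizes) == 0:
        warnings.warn("no hidden layer: model reduces to a single-layer perceptron")
    rng = np.random.default_rng(seed)
    dims = [window_len, *hidden_sizes, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-lim, lim, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPModel(window_len, list(hidden_sizes), weights, biases, input_scale_uV)


def init_conv(
    window_len: int = 20,
    n_kernels: int = 4,
    kernel_len: int = 8,
    stride: int = 2,
    hidden_sizes: list[int] | tuple[int, ...] = (8,),
    seed: int = 0,
    input_scale_uV: float = DEFAULT_INPUT_SCALE_UV,
) -> ConvModel:
    rng = np.random.default_rng(seed)
    lim = np.sqrt(6.0 / (kernel_len + 1))
    kernels = rng.uniform(-lim, lim, size=(n_kernels, kernel_len))
    flen = (window_len - kernel_len) // stride + 1
    head = init_mlp(n_kernels * flen, hidden_sizes, seed + 1, input_scale_uV=1.0)
    return ConvModel(window_len, kernels, stride, head, input_scale_uV)


def forward(model: MLPModel, windows: np.ndarray) -> np.ndarray:
    """Score windows; accepts a single window or a (n, window_len) batch."""
    x = np.asarray(windows, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.window_len:
        raise ValueError(f"window length {x.shape[1]} != model {model.window_len}")
    a = x / model.input_scale_uV
    for w, b in zip(model.weights[:-1], model.biases[:-1]):
        a = _relu(a @ w + b)
    z = a @ model.weights[-1] + model.biases[-1]
    score = _sigmoid(z[:, 0])
    return float(score[0]) if single else score


def _conv_features(model: ConvModel, x: np.ndarray) -> np.ndarray:
    """Valid-mode strided convolution; returns (n, k·flen) feature batch."""
    k, L = model.kernels.shape
    flen = (model.window_len - L) // model.stride + 1
    idx = np.arange(L)[None, :] + model.stride * np.arange(flen)[:, None]
    patches = x[:, idx]  # (n, flen, L)
    feats = np.einsum("nfl,kl->nkf", patches, model.kernels)
    if model.activation == "relu":
        feats = _relu(feats)
    elif model.activation != "linear":
        raise ValueError(f"unknown activation {model.activation!r}")
    return feats.reshape(x.shape[0], k * flen)


def conv_forward(model: ConvModel, windows: np.ndarray) -> np.ndarray:
    x = np.asarray(windows, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.window_len:
        raise ValueError(f"window length {x.shape[1]} != model {model.window_len}")
    feats = _conv_features(model, x / model.input_scale_uV)
    score = forward(model.head, feats)
    score = np.atleast_1d(score)
    return float(score[0]) if single else score


def _quantize_tensor(t: np.ndarray, bits: int) -> tuple[np.ndarray, float]:
    qmax = (1 << (bits - 1)) - 1
    m = float(np.max(np.abs(t))) if t.size else 0.0
    scale = m / qmax if m > 0 else 1.0
    q = np.clip(np.round(t / scale), -qmax - 1, qmax).astype(np.int8)
    return q, scale


def quantize_model(model: MLPModel, bits: int = 8) -> QuantizedMLP:
    """Post-training symmetric per-tensor quantization (scale = max|w|/127)."""
    if not all(np.all(np.isfinite(w)) for w in model.weights):
        raise ValueError("model weights must be finite")
    wq, ws, bq, bs = [], [], [], []
    for w in model.weights:
        q, s = _quantize_tensor(w, bits)
        wq.append(q)
        ws.append(s)
    for b in model.biases:
        q, s = _quantize_tensor(b, bits)
        bq.append(q)
        bs.append(s)
    return QuantizedMLP(
        model.window_len, list(model.hidden_sizes), wq, ws, bq, bs,
        model.input_scale_uV, dict(model.metadata),
    )


def adjusted_scores(raw: np.ndarray, consensus: int) -> np.ndarray:
    """Trailing mean of the latest ``consensus`` raw scores (shorter at start)."""
    raw = np.asarray(raw, dtype=float)
    c = np.concatenate([[0.0], np.cumsum(raw)])
    n = len(raw)
    lo = np.maximum(np.arange(n) - consensus + 1, 0)
    return (c[np.arange(n) + 1] - c[lo]) / (np.arange(n) + 1 - lo)


def classify_windows(
    model,
    recording: Recording,
    threshold: float = 0.5,
    consensus: int = 3,
    mode: str = "mean",
) -> ClassifierTrace:
    """Windowed inference with the consensus-adjusted output.

    Non-overlapping windows of ``model.window_len`` samples (hop = window
    length) are scored once each; the adjusted score is the mean of the
    latest ``consensus`` raw scores, thresholded into the final label
    (``mode="vote"`` instead requires all ``consensus`` raw scores to
    individually exceed the threshold). Timestamps mark window ends.
    """
    w = model.window_len
    n_win = recording.n_samples // w
    if n_win == 0:
        warnings.warn("recording shorter than one window; empty trace")
        return ClassifierTrace(np.empty(0), np.empty(0), np.empty(0, bool), w)
    windows = recording.samples[: n_win * w].reshape(n_win, w)
    raw = np.atleast_1d(model.predict(windows))
    adj = adjusted_scores(raw, consensus)
    if mode == "mean":
        labels = adj >= threshold
    elif mode == "vote":
        hits = raw >= threshold
        labels = np.array(
            [bool(np.all(hits[max(0, i - consensus + 1) : i + 1])) for i in range(n_win)]
        )
    else:
        raise ValueError(f"unknown consensus mode {mode!r}")
    times = (np.arange(1, n_win + 1) * w) / recording.fs
    return ClassifierTrace(times, adj, labels, hop_samples=w)
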