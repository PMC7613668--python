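"""Formats and resampling.

Recordings travel as single-channel EDF (the clinical convention for
long-term electrophysiology) or as a two-column CSV fallback
(``time_s,amplitude_uV``); annotations and classifier traces are plain
CSV; models are self-describing JSON that round-trips quantized weights
bit-exactly. EDF reading goes through :mod:`mne`; writing uses a minimal
built-in single-channel 16-bit encoder since no installed library
exports EDF.
"""
from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .exceptions import SchemaError
from .filterchain import FilterChainConfig
from .mlp import MLPModel, QuantizedMLP
from .recording import Annotation, ClassifierTrace, Recording

__all__ = [
    "read_recording",
    "write_recording_csv",
    "write_recording_edf",
    "read_annotations",
    "write_annotations",
    "write_trace",
    "read_trace",
    "resample_recording",
    "save_model",
    "load_model",
    "load_filter_config",
    "save_filter_config",
]


# ---------------------------------------------------------------- recordings

def write_recording_csv(recording: Recording, path: str | Path) -> None:
    t = np.arange(recording.n_samples) / recording.fs
    pd.DataFrame({"time_s": t, "amplitude_uV": recording.samples}).to_csv(
        path, index=False, float_format="%.6f"
    )


def _read_csv_recording(path: Path, fs: float | None) -> Recording:
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: empty recording file")
    if "amplitude_uV" not in df.columns:
        raise SchemaError(f"{path}: missing column 'amplitude_uV'")
    if fs is None:
        raise ValueError(
            "CSV carries no sampling-rate header; pass fs= explicitly"
        )
    if "time_s" in df.columns and len(df) > 2:
        dt = np.diff(df["time_s"].to_numpy())
        if np.max(np.abs(dt - 1.0 / fs)) > 0.01 / fs:
            raise SchemaError(
                f"{path}: time_s column is not uniform at fs={fs} "
                f"(max deviation {np.max(np.abs(dt - 1.0 / fs)):.3g}s)"
            )
    return Recording(df["amplitude_uV"].to_numpy(dtype=float), fs)


def _pad_ascii(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_recording_edf(recording: Recording, path: str | Path) -> None:
    """Minimal single-channel EDF: 1 s data records, 16-bit samples.

    Requires an integer sampling rate; the final partial record, if any,
    is zero-padded. Physical range is set symmetrically from the data so
    the 16-bit quantization step is max|x|/32767 µV.
    """
    fs = recording.fs
    if fs != int(fs) or fs <= 0:
        raise ValueError("EDF writer requires a positive integer sampling rate")
    fs = int(fs)
    x = recording.samples
    pmax = float(np.max(np.abs(x))) if len(x) and np.max(np.abs(x)) > 0 else 1.0
    n_rec = int(np.ceil(len(x) / fs)) or 1
    padded = np.zeros(n_rec * fs)
    padded[: len(x)] = x
    dig = np.round(padded / pmax * 32767.0).astype("<i2")

    header = b"".join(
        [
            _pad_ascii("0", 8),
            _pad_ascii("X X X X", 80),
            _pad_ascii("Startdate 01-JAN-2000 X X X", 80),
            _pad_ascii("01.01.00", 8),
            _pad_ascii("00.00.00", 8),
            _pad_ascii(str(256 + 256), 8),
            _pad_ascii("", 44),
            _pad_ascii(str(n_rec), 8),
            _pad_ascii("1", 8),
            _pad_ascii("1", 4),
            # signal header (one channel)
            _pad_ascii("LFP", 16),
            _pad_ascii("", 80),
            _pad_ascii("uV", 8),
            _pad_ascii(f"{-pmax:.6g}"[:8], 8),
            _pad_ascii(f"{pmax:.6g}"[:8], 8),
            _pad_ascii("-32768", 8),
            _pad_ascii("32767", 8),
            _pad_ascii("", 80),
            _pad_ascii(str(fs), 8),
            _pad_ascii("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(dig.tobytes())


def _read_edf_recording(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "EDF reading requires mne (install the 'edf' extra)"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()[0] * 1e6  # mne stores SI volts internally
    return Recording(data, fs)


def read_recording(
    path: str | Path, format: str | None = None, fs: float | None = None
) -> Recording:
    """Read a recording from EDF or CSV (format inferred from the suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        return _read_edf_recording(path)
    if fmt == "csv":
        return _read_csv_recording(path, fs)
    raise ValueError(f"unsupported recording format {fmt!r}")


# ---------------------------------------------------------------- annotations

def write_annotations(annotations: list[Annotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "onset_s": [a.onset_s for a in annotations],
            "offset_s": [a.offset_s for a in annotations],
            "label": [a.label for a in annotations],
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_annotations(path: str | Path) -> list[Annotation]:
    df = pd.read_csv(path)
    for col in ("onset_s", "offset_s", "label"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return [
        Annotation(float(r.onset_s), float(r.offset_s), str(r.label))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------- traces

def write_trace(trace: ClassifierTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.times_s,
            "score": trace.scores,
            "label": trace.labels.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.8g")


def read_trace(path: str | Path, hop_samples: int = 1) -> ClassifierTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "score", "label"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return ClassifierTrace(
        df["time_s"].to_numpy(float),
        df["score"].to_numpy(float),
        df["label"].to_numpy(int).astype(bool),
        hop_samples,
    )


# ---------------------------------------------------------------- resampling

def resample_recording(recording: Recording, target_fs: float = 256.0) -> Recording:
    """Polyphase rational-ratio resampling; annotations (in seconds) unchanged."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == recording.fs:
        return recording
    ratio = Fraction(target_fs / recording.fs).limit_denominator(1000)
    resampled = signal.resample_poly(recording.samples, ratio.numerator, ratio.denominator)
    return Recording(resampled, target_fs, list(recording.annotations))


# ---------------------------------------------------------------- models

def save_model(model: MLPModel | QuantizedMLP, path: str | Path) -> None:
    """Serialize a model to self-describing JSON.

    Quantized models store raw int8 tensors and per-tensor scales and
    round-trip bit-exactly; float models round-trip to full repr precision.
    """
    if isinstance(model, QuantizedMLP):
        doc = {
            "kind": "quantized_mlp",
            "window_len": model.window_len,
            "hidden_sizes": list(model.hidden_sizes),
            "input_scale_uV": model.input_scale_uV,
            "weights_q": [w.tolist() for w in model.weights_q],
            "weight_scales": list(model.weight_scales),
            "biases_q": [b.tolist() for b in model.biases_q],
            "bias_scales": list(model.bias_scales),
            "metadata": model.metadata,
        }
    elif isinstance(model, MLPModel):
        doc = {
            "kind": "mlp",
            "window_len": model.window_len,
            "hidden_sizes": list(model.hidden_sizes),
            "input_scale_uV": model.input_scale_uV,
            "weights": [w.tolist() for w in model.weights],
            "biases": [b.tolist() for b in model.biases],
            "metadata": model.metadata,
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    Path(path).write_text(json.dumps(doc))


def _require(doc: dict, fields: tuple[str, ...], path) -> None:
    for f in fields:
        if f not in doc:
            raise SchemaError(f"{path}: model file missing field {f!r}")


def _build(cls, path):
    """Constructor wrapper turning topology violations into schema errors."""

    def make(*args, **kwargs):
        try:
            return cls(*args, **kwargs)
        except ValueError as exc:
            raise SchemaError(f"{path}: inconsistent model topology ({exc})") from exc

    return make


def load_model(path: str | Path) -> MLPModel | QuantizedMLP:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise SchemaError(f"{path}: not a valid model file ({exc})") from exc
    if not isinstance(doc, dict) or "kind" not in doc:
        raise SchemaError(f"{path}: model file missing field 'kind'")
    common = ("window_len", "hidden_sizes", "input_scale_uV", "metadata")
    if doc["kind"] == "quantized_mlp":
        _require(doc, common + ("weights_q", "weight_scales", "biases_q", "bias_scales"), path)
        return _build(QuantizedMLP, path)(
            int(doc["window_len"]),
            [int(h) for h in doc["hidden_sizes"]],
            [np.array(w, dtype=np.int8) for w in doc["weights_q"]],
            [float(s) for s in doc["weight_scales"]],
            [np.array(b, dtype=np.int8) for b in doc["biases_q"]],
            [float(s) for s in doc["bias_scales"]],
            float(doc["input_scale_uV"]),
            dict(doc["metadata"]),
        )
    if doc["kind"] == "mlp":
        _require(doc, common + ("weights", "biases"), path)
        return _build(MLPModel, path)(
            int(doc["window_len"]),
            [int(h) for h in doc["hidden_sizes"]],
            [np.array(w, dtype=float) for w in doc["weights"]],
            [np.array(b, dtype=float) for b in doc["biases"]],
            float(doc["input_scale_uV"]),
            dict(doc["metadata"]),
        )
    raise SchemaError(f"{path}: unknown model kind {doc['kind']!r}")


# ---------------------------------------------------------------- configs

def save_filter_config(config: FilterChainConfig, path: str | Path) -> None:
    doc = {
        "low_hz": config.low_hz,
        "high_hz": config.high_hz,
        "order": config.order,
        "fs": config.fs,
        "ema_decay_samples": config.ema_decay_samples,
        "threshold_uV": config.threshold_uV,
        "input_lsb_uV": config.input_lsb_uV,
        "order_is_per_edge": config.order_is_per_edge,
        "ema_mode": config.ema_mode,
    }
    Path(path).write_text(yaml.safe_dump(doc))


def load_filter_config(path: str | Path) -> FilterChainConfig:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: expected a mapping of filter-chain keys")
    allowed = {
        "low_hz", "high_hz", "order", "fs", "ema_decay_samples",
        "threshold_uV", "input_lsb_uV", "order_is_per_edge", "ema_mode",
    }
    unknown = set(doc) - allowed
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    return FilterChainConfig(**doc)
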