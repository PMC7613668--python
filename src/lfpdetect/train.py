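"""Dataset construction and network training.

Windows a recording into fixed-length input vectors labeled from the
interval annotations (majority overlap), rebalances classes to the 3:1
negative:positive ratio used for seizure work, splits 70:30 into train
and validation, and fits the compact MLP by mini-batch gradient descent
on binary cross entropy. ``grid_search`` maps validation loss over the
two hyperparameters that matter — input window length and hidden layer
size.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import TrainingDivergedError
from .mlp import MLPModel, _relu, _sigmoid, init_mlp
from .recording import Recording

__all__ = [
    "WindowedDataset",
    "TrainConfig",
    "ErrorSurface",
    "window_dataset",
    "balance_dataset",
    "split_dataset",
    "train_mlp",
    "bce_loss",
    "grid_search",
]

_EPS = 1e-7  # probability clip inside the cross entropy


@dataclass
class WindowedDataset:
    """Fixed-length windows with binary labels and provenance."""

    windows: np.ndarray  # (n, window_len) µV
    labels: np.ndarray  # (n,) in {0,1}
    fs: float
    window_len: int
    starts: np.ndarray  # (n,) start sample index in the source recording
    source_id: str = ""

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        if self.windows.ndim != 2 or self.windows.shape[1] != self.window_len:
            raise ValueError("windows must be (n, window_len)")
        if not (len(self.labels) == len(self.windows) == len(self.starts)):
            raise ValueError("windows, labels and starts must align 1:1")
        if not np.all((self.labels == 0) | (self.labels == 1)):
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.labels == 0))

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            self.windows[idx], self.labels[idx], self.fs, self.window_len,
            self.starts[idx], self.source_id,
        )


@dataclass
class TrainConfig:
    neg_pos_ratio: int = 3
    train_frac: float = 0.70
    epochs: int = 200
    learning_rate: float = 0.01
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.neg_pos_ratio < 1:
            raise ValueError("neg_pos_ratio must be >= 1")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")


def window_dataset(
    recording: Recording, window_len: int, hop: int | None = None, source_id: str = ""
) -> WindowedDataset:
    """Consecutive windows; a window is positive iff more than half of its
    samples fall inside an annotated event."""
    if recording.n_samples < window_len:
        raise ValueError(
            f"recording has {recording.n_samples} samples, need >= {window_len}"
        )
    hop = window_len if hop is None else hop
    if hop < 1:
        raise ValueError("hop must be >= 1")
    mask = recording.annotation_mask().astype(np.int64)
    starts = np.arange(0, recording.n_samples - window_len + 1, hop)
    windows = np.stack([recording.samples[s : s + window_len] for s in starts])
    csum = np.concatenate([[0], np.cumsum(mask)])
    inside = csum[starts + window_len] - csum[starts]
    labels = (inside * 2 > window_len).astype(np.int8)
    return WindowedDataset(windows, labels, recording.fs, window_len, starts, source_id)


def balance_dataset(
    dataset: WindowedDataset, neg_pos_ratio: int = 3, seed: int = 0
) -> WindowedDataset:
    """Keep every positive; subsample negatives to exactly ratio × positives."""
    n_pos = dataset.n_positive
    n_neg = dataset.n_negative
    needed = neg_pos_ratio * n_pos
    if n_pos == 0:
        raise ValueError("dataset contains no positive windows")
    if n_neg < needed:
        raise ValueError(
            f"insufficient negatives: need {needed} for {n_pos} positives "
            f"at {neg_pos_ratio}:1, have {n_neg}"
        )
    if n_neg == needed:
        return dataset
    rng = np.random.default_rng(seed)
    neg_idx = np.flatnonzero(dataset.labels == 0)
    keep_neg = rng.choice(neg_idx, size=needed, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(dataset.labels == 1), keep_neg]))
    return dataset.subset(keep)


def split_dataset(
    dataset: WindowedDataset,
    train_frac: float = 0.70,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[WindowedDataset, WindowedDataset]:
    """Disjoint, exhaustive train/validation partition, stratified by class."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(seed)
    if stratified and min(dataset.n_positive, dataset.n_negative) < 2:
        warnings.warn("a class has < 2 members; falling back to unstratified split")
        stratified = False
    train_idx: list[np.ndarray] = []
    if stratified:
        for cls in (0, 1):
            idx = np.flatnonzero(dataset.labels == cls)
            idx = rng.permutation(idx)
            n_tr = int(round(train_frac * len(idx)))
            train_idx.append(idx[:n_tr])
    else:
        idx = rng.permutation(len(dataset))
        train_idx.append(idx[: int(round(train_frac * len(dataset)))])
    tr = np.sort(np.concatenate(train_idx))
    va = np.setdiff1d(np.arange(len(dataset)), tr)
    return dataset.subset(tr), dataset.subset(va)


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross entropy with probability clipping at 1e-7."""
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1.0 - _EPS)
    y = np.asarray(y, dtype=float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _forward_cached(model: MLPModel, x: np.ndarray):
    acts = [x / model.input_scale_uV]
    for w, b in zip(model.weights[:-1], model.biases[:-1]):
        acts.append(_relu(acts[-1] @ w + b))
    z = acts[-1] @ model.weights[-1] + model.biases[-1]
    return acts, _sigmoid(z)


def train_mlp(
    train: WindowedDataset,
    validation: WindowedDataset,
    model: MLPModel,
    config: TrainConfig,
) -> tuple[MLPModel, dict]:
    """Fit by mini-batch gradient descent on binary cross entropy.

    The logistic output paired with cross entropy gives the usual
    ``p − y`` output delta; hidden deltas backpropagate through the ReLU
    mask. Weights are updated in place on a copy of ``model``; the
    returned history maps ``"train_loss"``/``"val_loss"`` to per-epoch
    values. Fully deterministic given ``config.seed``.
    """
    if train.window_len != model.window_len:
        raise ValueError("dataset window_len does not match the model")
    rng = np.random.default_rng(config.seed)
    weights = [w.copy() for w in model.weights]
    biases = [b.copy() for b in model.biases]
    fitted = MLPModel(
        model.window_len, list(model.hidden_sizes), weights, biases,
        model.input_scale_uV, dict(model.metadata),
    )
    X, y = train.windows, train.labels.astype(float)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    for epoch in range(config.epochs):
        order = rng.permutation(len(X))
        for lo in range(0, len(X), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb, yb = X[idx], y[idx]
            acts, p = _forward_cached(fitted, xb)
            delta = (p - yb[:, None]) / len(idx)  # output-layer gradient
            for layer in range(len(weights) - 1, -1, -1):
                gw = acts[layer].T @ delta
                gb = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ weights[layer].T) * (acts[layer] > 0)
                weights[layer] -= config.learning_rate * gw
                biases[layer] -= config.learning_rate * gb
        tr_loss = bce_loss(_forward_cached(fitted, X)[1][:, 0], y)
        va_loss = bce_loss(
            _forward_cached(fitted, validation.windows)[1][:, 0],
            validation.labels.astype(float),
        )
        if not (np.isfinite(tr_loss) and np.isfinite(va_loss)):
            raise TrainingDivergedError(
                f"non-finite loss at epoch {epoch}: train {tr_loss}, val {va_loss}"
            )
        history["train_loss"].append(tr_loss)
        history["val_loss"].append(va_loss)
    fitted.metadata.update(
        {"epochs": config.epochs, "learning_rate": config.learning_rate,
         "batch_size": config.batch_size, "seed": config.seed}
    )
    return fitted, history


@dataclass
class ErrorSurface:
    """Validation cross entropy over (window length × hidden size)."""

    window_lengths: list[int]
    hidden_sizes: list[int]
    loss: np.ndarray  # (n_windows, n_hidden); NaN marks a failed cell
    chosen_cell: tuple[int, int]  # (window_len, hidden) values

    def loss_at(self, window_len: int, hidden: int) -> float:
        i = self.window_lengths.index(window_len)
        j = self.hidden_sizes.index(hidden)
        return float(self.loss[i, j])


def _choose_cell(
    window_lengths, hidden_sizes, loss: np.ndarray, rule: str, tol: float = 0.10
) -> tuple[int, int]:
    finite = np.isfinite(loss)
    if not finite.any():
        raise RuntimeError("every grid cell failed to train")
    best = np.nanmin(loss)
    if rule == "min_loss":
        i, j = np.unravel_index(np.nanargmin(loss), loss.shape)
    elif rule == "low_complexity":
        # smallest parameter count among cells within tol of the best loss
        cands = [
            (w * h + h + h + 1, i, j)
            for i, w in enumerate(window_lengths)
            for j, h in enumerate(hidden_sizes)
            if finite[i, j] and loss[i, j] <= best * (1 + tol)
        ]
        _, i, j = min(cands)
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return window_lengths[i], hidden_sizes[j]


def grid_search(
    recordings: Recording | list[Recording],
    window_lengths: list[int],
    hidden_sizes: list[int],
    config: TrainConfig,
    rule: str = "min_loss",
    repeats: int = 1,
) -> ErrorSurface:
    """Train one fresh model per (window length, hidden size) cell.

    Each cell re-windows the source recordings at its window length,
    rebalances, splits, trains a freshly initialized model, and records
    the final validation cross entropy (averaged over ``repeats`` seeds).
    A cell whose training fails is marked NaN; the surface is returned
    regardless.
    """
    if not window_lengths or not hidden_sizes:
        raise ValueError("both hyperparameter axes must be non-empty")
    recs = [recordings] if isinstance(recordings, Recording) else list(recordings)
    loss = np.full((len(window_lengths), len(hidden_sizes)), np.nan)
    for i, w in enumerate(window_lengths):
        parts = [window_dataset(r, w, source_id=str(k)) for k, r in enumerate(recs)]
        ds = parts[0]
        for extra in parts[1:]:
            ds = WindowedDataset(
                np.vstack([ds.windows, extra.windows]),
                np.concatenate([ds.labels, extra.labels]),
                ds.fs, w,
                np.concatenate([ds.starts, extra.starts]),
                "+".join(filter(None, [ds.source_id, extra.source_id])),
            )
        for j, h in enumerate(hidden_sizes):
            vals = []
            for r in range(repeats):
                seed = config.seed + 1000 * r
                try:
                    bal = balance_dataset(ds, config.neg_pos_ratio, seed)
                    tr, va = split_dataset(bal, config.train_frac, seed)
                    model = init_mlp(w, [h], seed=seed)
                    cfg = TrainConfig(
                        config.neg_pos_ratio, config.train_frac, config.epochs,
                        config.learning_rate, config.batch_size, seed,
                    )
                    _, hist = train_mlp(tr, va, model, cfg)
                    vals.append(hist["val_loss"][-1])
                except Exception as exc:  # cell marked invalid, surface survives
                    warnings.warn(f"grid cell (w={w}, h={h}) failed: {exc}")
            if vals:
                loss[i, j] = float(np.mean(vals))
    chosen = _choose_cell(window_lengths, hidden_sizes, loss, rule)
    return ErrorSurface(list(window_lengths), list(hidden_sizes), loss, chosen)
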