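"""Shared fixtures: synthetic study recordings and a trained compact MLP.

Session-scoped so the (cheap but not free) training run is shared by the
learning, quantization, latency and response-map tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from lfpdetect import filterchain as fc
from lfpdetect import mlp as ml
from lfpdetect import synth as sy
from lfpdetect import train as tr


@pytest.fixture(scope="session")
def train_recording():
    """480 s study recording with 12 spike-wave events over pink background."""
    return sy.synthesize_recording(
        sy.SynthConfig(
            duration_s=480.0,
            event_rate_per_hour=90.0,
            event_duration_range_s=(4.0, 8.0),
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def test_recording():
    """900 s held-out recording with 20 events for latency/overlap work."""
    return sy.synthesize_recording(
        sy.SynthConfig(
            duration_s=900.0,
            event_rate_per_hour=80.0,
            event_duration_range_s=(4.0, 8.0),
            seed=12,
        )
    )


@pytest.fixture(scope="session")
def windowed_split(train_recording):
    ds = tr.window_dataset(train_recording, 20, source_id="train")
    bal = tr.balance_dataset(ds, neg_pos_ratio=3, seed=0)
    return tr.split_dataset(bal, train_frac=0.70, seed=0)


@pytest.fixture(scope="session")
def trained_model(windowed_split):
    train_ds, val_ds = windowed_split
    model, history = tr.train_mlp(
        train_ds, val_ds, ml.init_mlp(20, [8], seed=0), tr.TrainConfig(seed=0)
    )
    return model, history


@pytest.fixture(scope="session")
def quantized_model(trained_model):
    return ml.quantize_model(trained_model[0])


@pytest.fixture()
def chain_config():
    return fc.FilterChainConfig()
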