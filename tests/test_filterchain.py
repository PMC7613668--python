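"""Filter-chain baseline: design, quantization, fixed-point arithmetic, EMA."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfpdetect import synth as sy
from lfpdetect.exceptions import PreconditionError, QuantizationError
from lfpdetect.filterchain import (
    FilterChainConfig,
    classify_filter,
    design_bandpass,
    envelope_ema,
    envelope_ema_fixed,
    filter_fixed,
    filter_float,
    fixed_point_error_bound,
    measure_band_edges,
    quantize_coefficients,
)
from lfpdetect.recording import Recording


class TestDesign:
    def test_half_power_points_on_band_edges(self, chain_config):
        cascade = design_bandpass(chain_config)
        freqs = np.array([8.0, 22.0])
        mag_db = 20 * np.log10(np.abs(cascade.freq_response(freqs, 256.0)))
        np.testing.assert_allclose(mag_db, [-3.0103, -3.0103], atol=0.1)

    def test_band_pass_structure(self, chain_config):
        cascade = design_bandpass(chain_config)
        h = np.abs(cascade.freq_response(np.array([1e-3, 127.9]), 256.0))
        assert h[0] < 1e-3 and 20 * np.log10(h[1] + 1e-300) < -60
        mid = np.abs(cascade.freq_response(np.array([np.sqrt(8 * 22.0)]), 256.0))[0]
        assert abs(20 * np.log10(mid)) < 0.5

    def test_order_and_stability(self, chain_config):
        cascade = design_bandpass(chain_config)
        assert cascade.order == 4 and cascade.n_sections == 2
        assert cascade.is_stable()
        per_edge = design_bandpass(
            FilterChainConfig(order=4, order_is_per_edge=True)
        )
        assert per_edge.order == 8

    def test_bad_band_edges_rejected(self):
        with pytest.raises(ValueError):
            FilterChainConfig(low_hz=22.0, high_hz=8.0)
        with pytest.raises(ValueError):
            FilterChainConfig(high_hz=200.0)


class TestQuantization:
    def test_integers_fit_16_bit_and_half_lsb(self, chain_config):
        cascade = design_bandpass(chain_config)
        fpc = quantize_coefficients(cascade)
        assert np.all(fpc.sections >= -32768) and np.all(fpc.sections <= 32767)
        deq = fpc.dequantize().sos
        orig = cascade.sos
        err = np.abs(deq[:, [0, 1, 2, 4, 5]] - orig[:, [0, 1, 2, 4, 5]])
        assert np.max(err) <= 2.0**-14 + 1e-12

    def test_band_edges_survive_quantization(self, chain_config):
        cascade = design_bandpass(chain_config)
        lo, hi = measure_band_edges(quantize_coefficients(cascade).dequantize(), 256.0)
        assert lo == pytest.approx(8.0, rel=0.03)
        assert hi == pytest.approx(22.0, rel=0.03)

    def test_quantized_cascade_remains_stable(self, chain_config):
        fpc = quantize_coefficients(design_bandpass(chain_config))
        assert fpc.dequantize().is_stable()

    def test_overflowing_coefficient_raises(self):
        from lfpdetect.filterchain import BiquadCascade

        bad = BiquadCascade(np.array([[5.0, 0, 0, 1.0, 0, 0]]))
        with pytest.raises(QuantizationError, match="section 0"):
            quantize_coefficients(bad)


class TestFixedPointFilter:
    def test_zero_in_zero_out(self, chain_config):
        fpc = quantize_coefficients(design_bandpass(chain_config))
        y, sat = filter_fixed(fpc, np.zeros(100, dtype=int))
        assert np.all(y == 0) and sat == 0

    def test_matches_float_reference_within_bound(self, chain_config):
        """Shift-rounding noise stays inside the analytic l1-norm envelope."""
        fpc = quantize_coefficients(design_bandpass(chain_config))
        bound = fixed_point_error_bound(fpc)
        for seed in range(3):
            x = np.random.default_rng(seed).integers(-16383, 16384, 2560)
            y, sat = filter_fixed(fpc, x)
            ref = filter_float(fpc.dequantize(), x.astype(float))
            assert sat == 0
            assert np.max(np.abs(y - ref)) <= bound

    def test_out_of_band_tone_attenuated(self, chain_config):
        """Full-scale 50 Hz tone comes out >=20 dB below an equal 14 Hz tone."""
        fpc = quantize_coefficients(design_bandpass(chain_config))
        t = np.arange(2560) / 256.0
        rms = {}
        for f in (14.0, 50.0):
            tone = np.round(16383 * np.sin(2 * np.pi * f * t)).astype(int)
            y, _ = filter_fixed(fpc, tone)
            rms[f] = np.sqrt(np.mean(y[512:].astype(float) ** 2))
        assert 20 * np.log10(rms[14.0] / rms[50.0]) >= 20.0

    def test_shift_invariance(self, chain_config):
        fpc = quantize_coefficients(design_bandpass(chain_config))
        x = np.random.default_rng(5).integers(-8000, 8000, 512)
        y, _ = filter_fixed(fpc, x)
        k = 37
        yd, _ = filter_fixed(fpc, np.concatenate([np.zeros(k, dtype=int), x]))
        np.testing.assert_array_equal(yd[k:], y)

    def test_oversized_input_rejected(self, chain_config):
        fpc = quantize_coefficients(design_bandpass(chain_config))
        with pytest.raises(PreconditionError):
            filter_fixed(fpc, np.array([40000]))


class TestEnvelope:
    def test_step_response_closed_form(self):
        """Unit step: y[31] = 1 - (1 - 1/32)^32 after 32 updates."""
        y = envelope_ema(np.ones(64), decay_samples=32)
        assert y[31] == pytest.approx(1.0 - (1.0 - 1.0 / 32.0) ** 32, abs=1e-12)

    def test_constant_input_converges_monotonically(self):
        y = envelope_ema(np.full(4096, -2.5), decay_samples=32)
        assert np.all(np.diff(y) >= -1e-15)
        assert y[-1] == pytest.approx(2.5, rel=1e-4)

    def test_zero_stays_zero(self):
        assert np.all(envelope_ema(np.zeros(100)) == 0.0)

    def test_fixed_point_tracks_float(self):
        x = np.random.default_rng(0).integers(-2000, 2000, 4096)
        acc = envelope_ema_fixed(x, 32)
        ref = envelope_ema(x.astype(float), 32)
        assert np.max(np.abs(acc / 32.0 - ref)) < 2.0

    def test_time_constant_mode(self):
        y = envelope_ema(np.ones(256), decay_samples=32, mode="time_constant")
        # exponential time-constant reading: 63.2% of final value at n = 32
        assert y[31] == pytest.approx(1.0 - np.exp(-1.0), abs=0.02)


class TestClassifyFilter:
    def test_degenerate_thresholds(self, chain_config, test_recording):
        rec = Recording(test_recording.samples[:2560], 256.0)
        lo = classify_filter(rec, FilterChainConfig(threshold_uV=0.0))
        assert np.all(lo.labels)
        hi = classify_filter(rec, FilterChainConfig(threshold_uV=1e9))
        assert not np.any(hi.labels)

    def test_event_detected_with_midway_threshold(self):
        """10 µVrms in-band event over 1 µVrms background splits cleanly."""
        bg = sy.generate_background(40.0, 256.0, 1.0, seed=3).samples
        ev = sy.generate_event(8.0, 256.0, 10.0, (10.0, 14.0), seed=4, template="narrowband")
        x = bg.copy()
        x[4096 : 4096 + len(ev)] += ev
        rec = Recording(x, 256.0)
        env = classify_filter(rec, FilterChainConfig(threshold_uV=np.inf)).scores
        thr = 0.5 * (np.median(env[:4000]) + np.median(env[4600:5800]))
        trace = classify_filter(rec, FilterChainConfig(threshold_uV=thr))
        # envelope ripple keeps a few interior samples under the midway line
        assert np.mean(trace.labels[4800:5600]) > 0.8  # event interior
        assert not np.any(trace.labels[1000:3500])  # remote background

    def test_fs_mismatch_instructs_resample(self, chain_config):
        rec = Recording(np.zeros(100), 512.0)
        with pytest.raises(PreconditionError, match="[Rr]esample"):
            classify_filter(rec, chain_config)

    def test_fixed_and_float_paths_agree(self, chain_config):
        rec = sy.generate_background(8.0, 256.0, 2.0, seed=6)
        a = classify_filter(rec, chain_config, arithmetic="float")
        b = classify_filter(rec, chain_config, arithmetic="fixed")
        # fixed path adds input quantization (0.05 µV LSB), coefficient
        # quantization and shift-rounding noise; the EMA smooths the latter
        # to a few input LSB on the envelope
        assert np.max(np.abs(a.scores - b.scores)) < 4 * chain_config.input_lsb_uV
        assert np.mean(np.abs(a.scores - b.scores)) < chain_config.input_lsb_uV

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_threshold_monotonicity(self, t1, t2):
        """Raising the threshold never flips a label negative -> positive."""
        rec = sy.generate_background(4.0, 256.0, 2.0, seed=1)
        lo, hi = sorted([t1, t2])
        a = classify_filter(rec, FilterChainConfig(threshold_uV=lo))
        b = classify_filter(rec, FilterChainConfig(threshold_uV=hi))
        assert not np.any(b.labels & ~a.labels)
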