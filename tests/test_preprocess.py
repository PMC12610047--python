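"""Filter probes, envelope oracle equivalence, fusion and windowing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmh_har.activities import ActivityClass, CHANNEL_NAMES
from mmh_har.preprocess import (
    FusedSeries, NyquistViolationError, bandpass_butterworth, fuse_channels,
    mvc_normalize, notch_filter, preprocess_session, rectify, rms_envelope,
    resample_to_240, segment_windows,
)
from mmh_har.synth import ProtocolStep, SubjectParams, generate_session

from oracles import rms_envelope_naive

FS = 2000.0


def _tone(freq: float, fs: float = FS, dur: float = 2.0) -> np.ndarray:
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x**2)))


class TestNotch:
    def test_mains_tone_attenuated_20db(self):
        x = _tone(50.0)
        y = notch_filter(x, FS, 50.0)
        assert _rms(y) <= 0.1 * _rms(x)

    def test_passband_tone_preserved(self):
        x = _tone(5.0)
        y = notch_filter(x, FS, 50.0)
        assert abs(_rms(y) - _rms(x)) <= 0.05 * _rms(x)

    def test_zero_in_zero_out(self):
        assert np.allclose(notch_filter(np.zeros(500), FS), 0.0)

    def test_nyquist_violation(self):
        with pytest.raises(NyquistViolationError):
            notch_filter(_tone(5.0), 80.0, 50.0)


class TestBandpass:
    @pytest.mark.parametrize("freq, band", [(100.0, "pass"), (5.0, "stop"),
                                            (900.0, "stop")])
    def test_probe_tones(self, freq, band):
        x = _tone(freq)
        y = bandpass_butterworth(x, FS)
        ratio = _rms(y) / _rms(x)
        if band == "pass":
            assert 0.95 <= ratio <= 1.05
        else:
            assert ratio <= 0.1

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass_butterworth(np.zeros(1000), FS), 0.0)

    def test_nyquist_violation(self):
        with pytest.raises(NyquistViolationError):
            bandpass_butterworth(_tone(10.0), 800.0, 20.0, 500.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        lhs = bandpass_butterworth(3.5 * x, FS)
        rhs = 3.5 * bandpass_butterworth(x, FS)
        assert np.max(np.abs(lhs - rhs)) < 1e-9


class TestRectifyMvc:
    def test_rectify_examples(self):
        assert (rectify(np.array([-1.0, 2.0, -3.0])) == [1, 2, 3]).all()
        assert (rectify(np.zeros(4)) == 0).all()

    def test_rectify_idempotent(self):
        x = np.random.default_rng(1).standard_normal(100)
        assert (rectify(rectify(x)) == rectify(x)).all()

    def test_mvc_normalize(self):
        assert mvc_normalize(np.array([0.5]), 0.5) == pytest.approx([1.0])
        x = np.random.default_rng(2).standard_normal(10)
        assert np.allclose(mvc_normalize(x, 1.0), x)
        assert np.allclose(mvc_normalize(x, 2.0), x / 2)
        with pytest.raises(ValueError):
            mvc_normalize(x, 0.0)


class TestRmsEnvelope:
    def test_constant_series(self):
        assert np.allclose(rms_envelope(np.full(1000, -3.0), FS), 3.0)

    def test_sinusoid_interior_is_inv_sqrt2(self):
        x = _tone(100.0, dur=1.0)  # window 500 samples >> period 20
        env = rms_envelope(x, FS)
        interior = env[500:-500]
        assert np.allclose(interior, 1 / np.sqrt(2), atol=2e-3)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(700)
        got = rms_envelope(x, FS, 250.0)
        want = rms_envelope_naive(x, FS, 250.0)
        assert np.max(np.abs(got - want)) < 1e-9

    @settings(max_examples=100, deadline=None)
    @given(
        st.integers(min_value=1, max_value=300),
        st.integers(min_value=0, max_value=2**31 - 1),
        st.sampled_from([40.0, 125.0, 250.0]),
    )
    def test_oracle_equivalence_property(self, n, seed, window_ms):
        """100 random series: envelope equals the O(n*w) loop oracle."""
        x = np.random.default_rng(seed).standard_normal(n) * 5
        got = rms_envelope(x, FS, window_ms)
        want = rms_envelope_naive(x, FS, window_ms)
        assert np.max(np.abs(got - want)) < 1e-9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rms_envelope(np.array([]), FS)


class TestResample:
    def test_constant_preserved(self):
        out = resample_to_240(np.ones(2000), 2000.0)
        assert out.shape == (240,)
        assert np.allclose(out, 1.0, atol=1e-6)

    def test_identity_at_240(self):
        x = np.random.default_rng(4).standard_normal(240)
        assert (resample_to_240(x, 240.0) == x).all()

    def test_ramp_endpoints(self):
        x = np.linspace(0.0, 1.0, 2000)
        out = resample_to_240(x, 2000.0)
        assert abs(out[0] - 0.0) < 0.01
        assert abs(out[-1] - 1.0) < 0.01

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample_to_240(np.ones(100), 120.0)


class TestFuseAndSegment:
    def _session(self, steps):
        return generate_session(
            steps, SubjectParams(subject_id="S01", seed=0)
        )

    def test_fusion_shape_and_order(self):
        sess = self._session([ProtocolStep(ActivityClass.N, 5.0, 0.0)])
        fused = preprocess_session(sess)
        assert fused.data.shape == (10, 1200)
        assert sess.channel_names == CHANNEL_NAMES
        assert (fused.data[:8] == sess.kin).all()
        assert (fused.data[8:] >= 0).all()  # envelopes are non-negative

    def test_fusion_length_mismatch(self):
        sess = self._session([ProtocolStep(ActivityClass.N, 1.0, 0.0)])
        with pytest.raises(ValueError):
            fuse_channels(sess, np.zeros((2, 100)))

    def test_window_count_exact_division(self):
        fused = FusedSeries(
            data=np.zeros((10, 1200)), labels=np.zeros(1200, dtype=int),
            subject_id="S01",
        )
        assert len(segment_windows(fused)) == 5

    def test_window_count_drops_remainder(self):
        fused = FusedSeries(
            data=np.zeros((10, 1000)), labels=np.zeros(1000, dtype=int),
        )
        assert len(segment_windows(fused)) == 4

    def test_short_series_warns_empty(self):
        fused = FusedSeries(
            data=np.zeros((10, 100)), labels=np.zeros(100, dtype=int),
        )
        with pytest.warns(UserWarning):
            out = segment_windows(fused)
        assert len(out) == 0

    def test_majority_label(self):
        labels = np.concatenate([
            np.full(130, int(ActivityClass.LF)),
            np.full(110, int(ActivityClass.N)),
        ])
        fused = FusedSeries(data=np.zeros((10, 240)), labels=labels)
        seg = segment_windows(fused).segments[0]
        assert seg.y is ActivityClass.LF

    def test_tie_broken_toward_center_sample(self):
        labels = np.concatenate([
            np.full(120, int(ActivityClass.LF)),
            np.full(120, int(ActivityClass.N)),
        ])
        fused = FusedSeries(data=np.zeros((10, 240)), labels=labels)
        # center sample (index 120) carries N
        assert segment_windows(fused).segments[0].y is ActivityClass.N

    def test_windows_cover_prefix_without_overlap(self):
        t = 1111
        fused = FusedSeries(
            data=np.arange(10 * t, dtype=float).reshape(10, t),
            labels=np.zeros(t, dtype=int), subject_id="S09",
        )
        segs = segment_windows(fused)
        for k, seg in enumerate(segs.segments):
            assert (seg.x == fused.data[:, k * 240:(k + 1) * 240]).all()
            assert seg.subject_id == "S09"
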