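"""EMG processing chain: filters, rectification, envelopes, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emgsim as es

FS = 2000.0
SPEC = es.FilterSpec()


def sinusoid(freq, fs=FS, duration=3.0, amp=1.0):
    t = np.arange(int(fs * duration)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def rec_of(x, fs=FS, name="m"):
    return es.RawEMGRecording((name,), fs, np.asarray(x, dtype=float)[:, None])


def measured_amplitude(x):
    """Steady-state sinusoid amplitude from the central half, via RMS."""
    mid = x[len(x) // 4: 3 * len(x) // 4]
    return float(np.sqrt(2.0 * np.mean(mid**2)))


class TestBandpass:
    def test_zero_input_gives_zero_output(self):
        out = es.bandpass_filter(rec_of(np.zeros(4000)), SPEC)
        assert np.all(out.samples == 0.0)

    @pytest.mark.parametrize("freq", [50.0, 100.0, 150.0, 200.0, 400.0])
    def test_passband_gain_matches_analytic_magnitude(self, freq):
        out = es.bandpass_filter(rec_of(sinusoid(freq)), SPEC).samples[:, 0]
        expected = es.zero_phase_bandpass_gain(freq, SPEC, FS)
        assert measured_amplitude(out) == pytest.approx(expected, rel=0.01)

    def test_stopband_5hz_strongly_attenuated(self):
        out = es.bandpass_filter(rec_of(sinusoid(5.0)), SPEC).samples[:, 0]
        steady = out[len(out) // 4: 3 * len(out) // 4]
        assert np.max(np.abs(steady)) <= 0.01

    def test_nyquist_violation_rejected(self):
        with pytest.raises(es.ConfigurationError):
            es.bandpass_filter(rec_of(np.ones(100), fs=800.0), SPEC)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            es.bandpass_filter(rec_of(np.ones(10)), SPEC)


class TestRectifyAndEnvelope:
    def test_rectify_is_absolute_value(self):
        out = es.rectify(rec_of([-1.0, 2.0, -3.0]))
        assert np.array_equal(out.samples[:, 0], [1.0, 2.0, 3.0])

    def test_rectified_sine_mean_is_two_over_pi(self):
        out = es.rectify(rec_of(sinusoid(100.0, duration=5.0)))
        assert np.mean(out.samples) == pytest.approx(2 / np.pi, rel=0.01)

    def test_constant_passes_with_dc_gain_one(self):
        envs = es.extract_envelope(rec_of(np.full(4000, 0.5)), SPEC)
        assert np.allclose(envs[0].values, 0.5, atol=1e-9)

    def test_envelope_of_rectified_sine_near_dc_level(self):
        rect = np.abs(sinusoid(100.0, duration=4.0))
        envs = es.extract_envelope(rec_of(rect), SPEC)
        mid = envs[0].values[2000:6000]
        assert np.all(np.abs(mid - 2 / np.pi) < 0.05 * 2 / np.pi)

    def test_envelope_of_zeros_is_zero_and_nonnegative(self):
        envs = es.extract_envelope(rec_of(np.zeros(4000)), SPEC)
        assert np.all(envs[0].values == 0.0)

    def test_zero_phase_no_lag_on_symmetric_burst(self):
        # envelope peak of a symmetric burst must not shift (zero-lag filters)
        t = np.arange(8000) / FS
        center = 2.0
        burst = np.exp(-(((t - center) / 0.3) ** 2)) * np.sin(2 * np.pi * 80 * t)
        envs = es.extract_envelope(es.rectify(es.bandpass_filter(rec_of(burst), SPEC)), SPEC)
        i_peak = np.argmax(envs[0].values)
        assert abs(t[i_peak] - center) < 1.0 / FS + 1e-12


class TestNormalization:
    def test_single_trial_scaled_to_unit_peak(self):
        t = np.linspace(0.0, 1.0, 101)  # peak lands exactly on the grid
        env = es.ActivationEnvelope("BIClong", t, 0.4 * np.sin(np.pi * t) ** 2)
        (out,) = es.normalize_envelopes([env])
        assert out.values.max() == pytest.approx(1.0)
        assert np.allclose(out.values, env.values * 2.5)
        assert out.norm_reference == pytest.approx(0.4)

    def test_global_maximum_shared_across_trials(self):
        t = np.arange(100) / FS
        shape = np.sin(np.pi * t / t[-1]) ** 2
        e1 = es.ActivationEnvelope("BIClong", t, 0.4 * shape)
        e2 = es.ActivationEnvelope("BIClong", t, 0.8 * shape)
        o1, o2 = es.normalize_envelopes([e1, e2])
        assert o1.values.max() == pytest.approx(0.5)
        assert o2.values.max() == pytest.approx(1.0)

    def test_all_zero_envelope_raises_naming_muscle(self):
        t = np.arange(100) / FS
        env = es.ActivationEnvelope("BRD", t, np.zeros_like(t))
        with pytest.raises(es.DegenerateSignalError, match="BRD"):
            es.normalize_envelopes([env])

    def test_normalization_is_idempotent(self):
        t = np.arange(200) / FS
        env = es.ActivationEnvelope("BRA", t, 0.3 * np.sin(np.pi * t / t[-1]) ** 2)
        once = es.normalize_envelopes([env])
        twice = es.normalize_envelopes(once)
        assert np.max(np.abs(twice[0].values - once[0].values)) <= 1e-12


class TestResampling:
    def test_identity_grid_preserves_values(self):
        t = np.arange(100) / FS
        env = es.ActivationEnvelope("m", t, np.random.default_rng(0).random(100))
        out = es.resample_to_grid(env, t)
        assert np.allclose(out.values, env.values)

    def test_linear_ramp_interpolates_exactly(self):
        env = es.ActivationEnvelope("m", np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        out = es.resample_to_grid(env, np.array([0.25]))
        assert out.values[0] == pytest.approx(0.25)

    def test_grid_outside_span_rejected(self):
        env = es.ActivationEnvelope("m", np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            es.resample_to_grid(env, np.array([0.5, 1.5]))


class TestProcessRecording:
    def test_zero_recording_raises_degenerate(self):
        with pytest.raises(es.DegenerateSignalError):
            es.process_recording(rec_of(np.zeros(4000)), SPEC)

    def test_processing_is_deterministic(self):
        spec = es.SyntheticProfileSpec(seed=3, duration=1.0)
        rec = es.synthesize_recording(spec)
        a = es.process_recording(rec, SPEC)
        b = es.process_recording(rec, SPEC)
        for ea, eb in zip(a, b):
            assert np.array_equal(ea.values, eb.values)

    @given(scale=st.floats(0.05, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_normalized_output_invariant_to_input_scale(self, scale):
        spec = es.SyntheticProfileSpec(seed=5, duration=1.0)
        rec = es.synthesize_recording(spec)
        scaled = es.RawEMGRecording(rec.muscle_names, rec.sample_rate,
                                    rec.samples * scale)
        a = es.process_recording(rec, SPEC)
        b = es.process_recording(scaled, SPEC)
        for ea, eb in zip(a, b):
            assert np.allclose(ea.values, eb.values, atol=1e-9)
            assert 0.0 <= eb.values.min() and eb.values.max() <= 1.0 + 1e-12
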