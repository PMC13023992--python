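"""TFRIM pipeline tests against the closed-form RIC oracle and the stated
geometry/screening contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfrim_sad.simulate import (
    BreathingPattern, ExcitationSpec, IOSRecording, SimImpedanceModel,
    impedance_at, resistance_at, resonant_frequency, synthesize_recording,
)
from tfrim_sad.tfrim import (
    QualityError, TFRIMConfig, build_tfrim, coherence_screen, global_impedance,
    ios_scalar_params, scalar_ios_parameters, select_channels, stft_windows,
    window_impedance, TFRIMTransformer,
)

HARMONICS = 2.5 * np.arange(1, 25)


def harmonic_indices(freqs):
    return np.argmin(np.abs(freqs[None, :] - HARMONICS[:, None]), axis=1)


class TestGlobalImpedance:
    def test_identity_channels(self, rng):
        x = rng.normal(size=4000)
        Z, _ = global_impedance(IOSRecording(pressure=x, flow=x))
        ok = np.isfinite(Z)
        assert np.allclose(Z[ok], 1.0 + 0j, atol=1e-9)

    def test_linear_scaling(self, rng):
        x = rng.normal(size=4000)
        Z, _ = global_impedance(IOSRecording(pressure=2.0 * x, flow=x))
        ok = np.isfinite(Z)
        assert np.allclose(Z[ok], 2.0 + 0j, atol=1e-9)

    def test_all_zero_flow_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            global_impedance(IOSRecording(pressure=np.ones(100), flow=np.zeros(100)))

    def test_ric_oracle_at_every_harmonic(self, ric_model, ric_recording):
        """Estimated Z at every excited harmonic within 2% per component of
        the generating closed-form impedance."""
        rec = IOSRecording(ric_recording.pressure[:9120], ric_recording.flow[:9120])
        Z, freqs = global_impedance(rec)
        idx = harmonic_indices(freqs)
        z_true = impedance_at(ric_model, freqs[idx])
        scale = np.abs(z_true)
        np.testing.assert_allclose(Z[idx].real, z_true.real, atol=0.02 * scale.max())
        np.testing.assert_allclose(Z[idx].imag, z_true.imag, atol=0.02 * scale.max())
        assert np.all(np.abs(Z[idx] - z_true) / np.abs(z_true) < 0.02)


class TestScalarParams:
    def test_ric_fres_and_x5(self, ric_model, ric_recording):
        sp = ios_scalar_params(ric_recording)
        assert sp.Fres == pytest.approx(resonant_frequency(ric_model), abs=0.25)
        assert sp.X5 == pytest.approx(-0.1387, abs=0.02 * 0.1387 + 1e-3)
        assert sp.Z5 == pytest.approx(np.hypot(sp.R5, sp.X5))

    def test_no_zero_crossing_flagged(self):
        freqs = np.linspace(5, 35, 13)
        Z = 0.3 + 1j * np.linspace(0.1, 0.5, 13)  # X > 0 everywhere
        assert scalar_ios_parameters(Z, freqs).Fres is None

    def test_narrow_band_gives_undefined_not_failure(self):
        freqs = np.array([5.0, 10.0])
        Z = np.array([0.3 - 0.1j, 0.3 - 0.05j])
        sp = scalar_ios_parameters(Z, freqs)
        assert sp.R35 is None and sp.R5 is not None


class TestSTFTGeometry:
    def test_9120_samples_gives_48_windows(self):
        rec = IOSRecording(np.random.default_rng(0).normal(size=9120),
                           np.random.default_rng(1).normal(size=9120))
        ws = stft_windows(rec)
        assert ws.Pt.shape[0] == 48
        assert ws.freqs[1] - ws.freqs[0] == pytest.approx(0.25)
        # 2.5 Hz lands on bin 10 of the 0.25 Hz grid
        assert np.argmin(np.abs(ws.freqs - 2.5)) == 10

    def test_single_window_boundary(self):
        rec = IOSRecording(np.random.default_rng(0).normal(size=1600),
                           np.random.default_rng(1).normal(size=1600))
        assert stft_windows(rec).Pt.shape[0] == 1

    def test_shorter_than_window_rejected(self):
        rec = IOSRecording(np.zeros(1000), np.ones(1000))
        with pytest.raises(ValueError, match="window"):
            stft_windows(rec)


class TestWindowImpedance:
    def test_identity(self, rng):
        x = rng.normal(size=9120)
        raw = window_impedance(stft_windows(IOSRecording(pressure=x, flow=x)))
        assert np.allclose(raw.R[raw.mask], 1.0, atol=1e-9)
        assert np.allclose(raw.X[raw.mask], 0.0, atol=1e-9)
        assert np.all(raw.gamma2[raw.mask] > 0.999)

    def test_ric_recovery_and_coherence(self, ric_model, ric_recording):
        """Noise-free simulation: coherence >= 0.99 and R within 2% at every
        excited harmonic, in every window."""
        rec = IOSRecording(ric_recording.pressure[:9120], ric_recording.flow[:9120])
        raw = window_impedance(stft_windows(rec))
        idx = harmonic_indices(raw.freqs)
        assert np.all(raw.gamma2[:, idx] >= 0.99)
        r_true = resistance_at(ric_model, raw.freqs[idx])
        scale = np.abs(impedance_at(ric_model, raw.freqs[idx]))
        err = np.abs(raw.R[:, idx] - r_true[None, :]) / scale[None, :]
        assert err.max() < 0.02

    def test_independent_noise_drops_coherence(self):
        """Strong independent noise at unexcited bins: median coherence over
        windows below 0.9 (50-seed Monte Carlo)."""
        medians = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            p = r.normal(size=2000)
            f = r.normal(size=2000)  # independent of p
            ws = stft_windows(IOSRecording(pressure=p, flow=f))
            medians.append(np.median(ws.gamma2, axis=0))
        assert np.median(np.concatenate(medians)) < 0.9

    def test_coherence_bounds_random_inputs(self, rng):
        for _ in range(10):
            p = rng.normal(size=3200)
            f = rng.normal(size=3200) + 0.5 * p
            ws = stft_windows(IOSRecording(pressure=p, flow=f))
            assert np.all(ws.gamma2 >= 0.0) and np.all(ws.gamma2 <= 1.0)


class TestScreeningAndSelection:
    def _toy_raw(self):
        rec = IOSRecording(np.random.default_rng(3).normal(size=9120),
                           np.random.default_rng(4).normal(size=9120))
        return window_impedance(stft_windows(rec))

    def test_screen_threshold_rule(self):
        raw = self._toy_raw()
        raw.gamma2[:] = 0.5
        raw.gamma2[0, 5] = 0.95
        raw.gamma2[0, 6] = 0.89
        screened = coherence_screen(raw, 0.90)
        assert screened.mask[0, 5] and not screened.mask[0, 6]
        assert screened.R[0, 6] == 0.0 and screened.X[0, 6] == 0.0
        assert not screened.mask[1, 5]

    def test_all_below_threshold_raises_quality_error(self):
        raw = self._toy_raw()
        raw.gamma2[:] = 0.1
        screened = coherence_screen(raw, 0.90)
        with pytest.raises(QualityError, match="24"):
            select_channels(screened, 24)

    def test_selection_matches_brute_force(self, ric_recording):
        rec = IOSRecording(ric_recording.pressure[:9120], ric_recording.flow[:9120])
        screened = coherence_screen(window_impedance(stft_windows(rec)), 0.90)
        tensor = select_channels(screened, 24)
        score = np.where(screened.mask, screened.gamma2, 0.0).mean(axis=0)
        brute = np.sort(np.argsort(-score, kind="stable")[:24])
        np.testing.assert_array_equal(tensor.freqs, screened.freqs[brute])
        # retained channels sorted ascending and dominate discarded ones
        assert np.all(np.diff(tensor.freqs) > 0)
        discarded = np.delete(score, brute)
        assert tensor.mean_coherence.min() >= discarded.max()

    def test_tie_break_prefers_lower_frequency(self):
        raw = self._toy_raw()
        raw.gamma2[:] = 0.0
        raw.mask[:] = True
        raw.gamma2[:, 10] = 0.95   # candidates with identical scores
        raw.gamma2[:, 40] = 0.95
        raw.gamma2[:, 20] = 0.99
        tensor = select_channels(coherence_screen(raw, 0.90), 2)
        np.testing.assert_array_equal(tensor.freqs, raw.freqs[[10, 20]])


class TestBuild:
    def test_default_shape(self, ric_recording):
        t = build_tfrim(ric_recording)
        assert t.values.shape == (2, 24, 48)
        assert t.freqs.size == 24 and t.times.size == 48

    def test_short_recording_rejected(self):
        rec = IOSRecording(np.zeros(9000), np.ones(9000))
        with pytest.raises(ValueError, match="9120"):
            build_tfrim(rec)

    def test_nonfinite_rejected(self, ric_recording):
        bad = IOSRecording(ric_recording.pressure.copy(), ric_recording.flow.copy())
        bad.pressure[5] = np.nan
        with pytest.raises(ValueError, match="finite"):
            build_tfrim(bad)

    def test_channel_mean_matches_generating_resistance(self, ric_model, ric_recording):
        t = build_tfrim(ric_recording)
        r_true = resistance_at(ric_model, t.freqs)
        assert np.abs(t.values[0].mean() - r_true.mean()) / r_true.mean() < 0.02

    def test_linearity_in_pressure(self, ric_recording):
        t1 = build_tfrim(ric_recording)
        scaled = IOSRecording(3.0 * ric_recording.pressure, ric_recording.flow)
        t3 = build_tfrim(scaled)
        np.testing.assert_array_equal(t1.freqs, t3.freqs)
        np.testing.assert_allclose(t3.values, 3.0 * t1.values, rtol=1e-9, atol=1e-12)

    def test_expiratory_resistance_elevation_resolved_in_time(self):
        """With dR_exp planted, expiratory-phase windows show higher estimated
        R at 5 Hz than inspiratory windows (direction, 20-seed majority)."""
        wins = 0
        for seed in range(20):
            m = SimImpedanceModel(R0=0.35, dR_exp=0.2, I=6.5e-4, C=0.2,
                                  noise_sd_p=0.002, noise_sd_f=0.01)
            breathing = BreathingPattern(breath_rate=10.0)
            rec = synthesize_recording(m, breathing, ExcitationSpec(),
                                       duration=30.0, seed=seed)
            rec = IOSRecording(rec.pressure[:9120], rec.flow[:9120])
            raw = window_impedance(stft_windows(rec))
            k5 = int(np.argmin(np.abs(raw.freqs - 5.0)))
            f_breath = breathing.breath_rate / 60.0
            phase = np.sin(2 * np.pi * f_breath * raw.window_times)
            r5 = raw.R[:, k5]
            if r5[phase > 0].mean() > r5[phase < 0].mean():
                wins += 1
        assert wins >= 14  # clear majority of seeds

    def test_transformer_stacks_and_roundtrips_params(self, ric_recording):
        tr = TFRIMTransformer(n_channels=24)
        out = tr.fit_transform([ric_recording, ric_recording])
        assert out.shape == (2, 2, 24, 48)
        assert TFRIMTransformer(**tr.get_params()).get_params() == tr.get_params()


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_oracle_equivalence_global_vs_windowed(seed):
    """On stationary noise-free recordings the windowed estimator agrees with
    the whole-recording estimator at excited harmonics within 2%."""
    r = np.random.default_rng(seed)
    m = SimImpedanceModel(R0=float(r.uniform(0.2, 0.6)), I=float(r.uniform(4e-4, 8e-4)),
                          C=float(r.uniform(0.1, 0.3)))
    full = synthesize_recording(m, seed=seed)
    rec = IOSRecording(full.pressure[:9120], full.flow[:9120])
    Zg, fg = global_impedance(rec)
    raw = window_impedance(stft_windows(rec))
    idx_g = harmonic_indices(fg)
    idx_w = harmonic_indices(raw.freqs)
    Zw = (raw.R + 1j * raw.X)[:, idx_w].mean(axis=0)
    rel = np.abs(Zw - Zg[idx_g]) / np.abs(Zg[idx_g])
    assert rel.max() < 0.02
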