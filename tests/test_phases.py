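import numpy as np
import pytest

from myobeat.errors import ParameterError
from myobeat.phases import ContractionEvent, PhaseConfig, detect_phases, smooth_derivative
from myobeat.synth import WaveformParams, generate_length_waveform

FPS = 100.0


def linear_params(**kw):
    base = dict(
        resting_length=2.0, amplitude=0.4, period=1.0, contraction_duration=0.2,
        expansion_duration=0.3, n_cycles=3, fps=FPS, noise_sd=0.0, ramp="linear",
    )
    base.update(kw)
    return WaveformParams(**base)


class TestSmoothDerivative:
    def test_constant_zero(self):
        cfg = PhaseConfig()
        d = smooth_derivative(np.full(100, 2.0), cfg, FPS)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_linear_ramp_exact(self):
        cfg = PhaseConfig()
        t = np.arange(200) / FPS
        d = smooth_derivative(2.0 + 0.5 * t, cfg, FPS)
        assert np.max(np.abs(d - 0.5)) < 1e-6

    def test_cosine_matches_analytic(self):
        # oracle: d/dt [-(A/2) cos(2 pi t / T)] = (A pi / T) sin(2 pi t / T)
        cfg = PhaseConfig()
        A, T = 0.4, 1.0
        t = np.arange(300) / FPS
        y = 2.0 - (A / 2) * (1 - np.cos(2 * np.pi * t / T))
        d = smooth_derivative(y, cfg, FPS)
        analytic = -(A / 2) * (2 * np.pi / T) * np.sin(2 * np.pi * t / T)
        peak = np.max(np.abs(analytic))
        interior = slice(cfg.sg_window, -cfg.sg_window)
        assert np.max(np.abs(d[interior] - analytic[interior])) < 0.01 * peak

    def test_too_short_signal(self):
        with pytest.raises(ParameterError):
            smooth_derivative(np.zeros(5), PhaseConfig(sg_window=11), FPS)

    def test_invalid_config(self):
        with pytest.raises(ParameterError):
            PhaseConfig(sg_window=10).validate()
        with pytest.raises(ParameterError):
            PhaseConfig(sg_polyorder=15).validate()
        with pytest.raises(ParameterError):
            PhaseConfig(high_zone_fraction=1.5).validate()
        with pytest.raises(ParameterError):
            PhaseConfig(derivative_threshold=0.0).validate()


class TestDetectPhases:
    def test_constant_signal_empty(self):
        y = np.full(200, 2.0)
        cfg = PhaseConfig()
        d = smooth_derivative(y, cfg, FPS)
        assert detect_phases(y, d, cfg, FPS) == []

    def test_linear_ramp_ground_truth(self):
        p = linear_params()
        wf = generate_length_waveform(p, seed=0)
        ramp_slope = p.amplitude / p.contraction_duration  # 2.0 um/s
        cfg = PhaseConfig(derivative_threshold=0.5 * ramp_slope)
        d = smooth_derivative(wf.clean, cfg, FPS)
        events = detect_phases(wf.clean, d, cfg, FPS)
        complete = [e for e in events if e.complete]
        assert len(complete) == p.n_cycles
        for e, gt in zip(complete, wf.events):
            assert abs(e.relaxed_start - gt["relaxed_start"]) <= 2 / FPS
            assert abs(e.contraction_onset - gt["contraction_onset"]) <= 2 / FPS
            assert abs(e.peak_contraction - gt["peak_contraction"]) <= 1 / FPS

    def test_raised_cosine_peaks(self):
        p = linear_params(ramp="cosine")
        wf = generate_length_waveform(p, seed=0)
        cfg = PhaseConfig(derivative_threshold=0.2)
        d = smooth_derivative(wf.clean, cfg, FPS)
        complete = [e for e in detect_phases(wf.clean, d, cfg, FPS) if e.complete]
        assert len(complete) == p.n_cycles
        for e, gt in zip(complete, wf.events):
            assert abs(e.peak_contraction - gt["peak_contraction"]) <= 1 / FPS

    def test_event_ordering_invariants(self):
        wf = generate_length_waveform(linear_params(n_cycles=4), seed=0)
        cfg = PhaseConfig(derivative_threshold=0.5)
        d = smooth_derivative(wf.clean, cfg, FPS)
        events = detect_phases(wf.clean, d, cfg, FPS)
        complete = [e for e in events if e.complete]
        for e in complete:
            assert e.relaxed_start <= e.contraction_onset < e.peak_contraction < e.relaxation_end
        for a, b in zip(complete, complete[1:]):
            assert a.relaxation_end <= b.contraction_onset

    def test_complete_count_le_positive_blocks(self):
        wf = generate_length_waveform(linear_params(), seed=0)
        cfg = PhaseConfig(derivative_threshold=0.5)
        d = smooth_derivative(wf.clean, cfg, FPS)
        events = detect_phases(wf.clean, d, cfg, FPS)
        x = wf.clean - wf.clean.mean()
        n_pos_blocks = int(np.sum(np.diff(np.concatenate(([0], (x > 0).astype(int), [0]))) == 1))
        assert sum(e.complete for e in events) <= n_pos_blocks

    def test_monotone_decrease_onset_to_peak(self):
        wf = generate_length_waveform(linear_params(ramp="cosine"), seed=0)
        cfg = PhaseConfig(derivative_threshold=0.2)
        d = smooth_derivative(wf.clean, cfg, FPS)
        for e in detect_phases(wf.clean, d, cfg, FPS):
            if e.complete:
                drop = wf.clean[e.contraction_onset_idx] - wf.clean[e.peak_contraction_idx]
                assert drop > 0

    def test_threshold_fallback_flagged(self):
        # a pure sine has no flat samples: an unattainable threshold falls
        # back to the high-zone boundary and flags the event
        t = np.arange(300) / FPS
        # incommensurate frequency/phase: no sample lands on an extremum
        y = 2.0 + 0.2 * np.sin(2 * np.pi * 1.37 * t + 0.413)
        cfg = PhaseConfig(derivative_threshold=1e-9)
        d = smooth_derivative(y, cfg, FPS)
        events = detect_phases(y, d, cfg, FPS)
        assert events
        assert all(e.threshold_fallback for e in events)

    def test_shape_mismatch(self):
        with pytest.raises(ParameterError):
            detect_phases(np.zeros(50), np.zeros(49), PhaseConfig(), FPS)

    def test_noise_robustness_after_denoising(self):
        # noise at 2% of the amplitude shifts detected times by <= 3 samples
        from myobeat.denoise import LengthSignal, gpr_denoise

        p = linear_params(ramp="cosine", noise_sd=0.0)
        clean_wf = generate_length_waveform(p, seed=0)
        noisy_wf = generate_length_waveform(
            linear_params(ramp="cosine", noise_sd=0.02 * p.amplitude), seed=7
        )
        sig = LengthSignal("whole", noisy_wf.t, noisy_wf.length, FPS)
        den = gpr_denoise(sig)
        cfg = PhaseConfig(derivative_threshold=0.2)
        ev_clean = [
            e for e in detect_phases(
                clean_wf.clean, smooth_derivative(clean_wf.clean, cfg, FPS), cfg, FPS
            ) if e.complete
        ]
        ev_noisy = [
            e for e in detect_phases(
                den.denoised, smooth_derivative(den.denoised, cfg, FPS), cfg, FPS
            ) if e.complete
        ]
        assert len(ev_clean) == len(ev_noisy)
        for a, b in zip(ev_clean, ev_noisy):
            assert abs(a.contraction_onset - b.contraction_onset) <= 3 / FPS
            assert abs(a.peak_contraction - b.peak_contraction) <= 3 / FPS
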