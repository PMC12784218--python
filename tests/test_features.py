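import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from myobeat.denoise import LengthSignal
from myobeat.errors import InsufficientPairsError
from myobeat.features import FEATURE_COLUMNS, extract_features, paired_comparison
from myobeat.phases import PhaseConfig, detect_phases, smooth_derivative
from myobeat.synth import WaveformParams, generate_length_waveform

FPS = 100.0


def waveform_record(params: WaveformParams, seed=0, sarc_per_frame=20, spread=0.05):
    """Feature record computed straight from a waveform (no imaging)."""
    wf = generate_length_waveform(params, seed=seed)
    rng = np.random.default_rng(seed + 1)
    n = wf.t.size
    rows = {
        "frame": np.repeat(np.arange(n), sarc_per_frame),
        "length_um": np.repeat(wf.clean, sarc_per_frame)
        + rng.normal(0, spread, n * sarc_per_frame),
        "longitudinal": "center",
        "transverse": "top",
    }
    det = pd.DataFrame(rows)
    sig = LengthSignal("whole", wf.t, wf.clean.copy(), FPS)
    sig.denoised = wf.clean.copy()
    sig.noise_level = 0.0
    cfg = PhaseConfig(derivative_threshold=0.2)
    deriv = smooth_derivative(sig.denoised, cfg, FPS)
    events = detect_phases(sig.denoised, deriv, cfg, FPS)
    rec = extract_features(events, sig, [None] * n, det, um_per_px=0.2, phase_cfg=cfg)
    return rec, wf


@pytest.fixture(scope="module")
def default_record():
    p = WaveformParams(
        resting_length=2.0, amplitude=0.4, period=1.0, contraction_duration=0.2,
        expansion_duration=0.3, n_cycles=5, fps=FPS, noise_sd=0.0,
    )
    return waveform_record(p)


class TestExtractFeatures:
    def test_period_frequency_amplitude(self, default_record):
        rec, _ = default_record
        assert rec["number_of_contractions"] == 5
        assert rec["contraction_period"] == pytest.approx(1.0, abs=0.02)
        assert rec["contraction_frequency"] == pytest.approx(1.0, abs=0.02)
        assert rec["shortening_amplitude"] == pytest.approx(0.4, abs=0.02)

    def test_peak_velocity_closed_form(self, default_record):
        rec, _ = default_record
        expected = np.pi * 0.4 / (2 * 0.2)  # pi A / (2 d_c) ~ 3.1416 um/s
        assert rec["peak_shortening_velocity"] == pytest.approx(expected, rel=0.05)

    def test_frequency_period_identity(self, default_record):
        rec, _ = default_record
        assert rec["contraction_frequency"] * rec["contraction_period"] == pytest.approx(1.0, abs=1e-9)

    def test_relaxed_and_peak_sl_stats(self, default_record):
        rec, _ = default_record
        assert rec["relaxed_sl_mean"] == pytest.approx(2.0, abs=0.02)
        assert rec["peak_sl_mean"] == pytest.approx(1.6, abs=0.03)
        for prefix in ("relaxed_sl", "peak_sl"):
            assert rec[f"{prefix}_p25"] <= rec[f"{prefix}_median"] <= rec[f"{prefix}_p75"]

    def test_timing_decompositions(self, default_record):
        rec, _ = default_record
        one_sample = 1 / FPS
        assert rec["onset_to_half_contracted"] + rec["half_to_peak"] == pytest.approx(
            rec["onset_to_peak"], abs=one_sample
        )
        assert rec["peak_to_half_relaxed"] + rec["half_relaxed_to_full"] == pytest.approx(
            rec["peak_to_relaxation_end"], abs=one_sample
        )
        assert rec["onset_to_peak"] + rec["peak_to_relaxation_end"] == pytest.approx(
            rec["onset_to_relaxation_end"], abs=one_sample
        )

    def test_schema_complete(self, default_record):
        rec, _ = default_record
        assert len(FEATURE_COLUMNS) == 35  # one column per published metric row
        assert set(rec) == set(FEATURE_COLUMNS)

    def test_total_sarcomeres(self, default_record):
        rec, _ = default_record
        assert rec["total_sarcomeres"] == pytest.approx(20.0)

    def test_no_complete_events_gives_missing_functional(self):
        p = WaveformParams(amplitude=0.0, n_cycles=2, noise_sd=0.0)
        with pytest.warns(UserWarning):
            rec, _ = waveform_record(p)
        assert rec["number_of_contractions"] == 0
        assert np.isnan(rec["contraction_period"])
        assert np.isnan(rec["shortening_amplitude"])
        assert rec["total_sarcomeres"] == pytest.approx(20.0)  # structural still computed

    def test_parameter_recovery_grid(self):
        # signal-level recovery of amplitude and period over a 3x3 grid
        for A in (0.2, 0.3, 0.4):
            for T in (0.8, 1.0, 1.25):
                p = WaveformParams(amplitude=A, period=T, contraction_duration=0.2,
                                   expansion_duration=0.3, n_cycles=4, noise_sd=0.0)
                rec, _ = waveform_record(p)
                assert rec["contraction_period"] == pytest.approx(T, rel=0.05)
                assert rec["shortening_amplitude"] == pytest.approx(A, rel=0.05)


class TestPairedComparison:
    def test_identical_pairs_zero_delta(self):
        with pytest.warns(UserWarning):  # zero-variance differences
            res = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.delta_pct == 0.0

    def test_hand_computed_example(self):
        # oracle: diffs (0.5, 0.6, 0.4); t = 0.5 / (0.1 / sqrt(3)) = 5 sqrt(3)
        res = paired_comparison([1.0, 2.0, 3.0], [1.5, 2.6, 3.4])
        assert res.delta_pct == pytest.approx(25.0, abs=1e-9)
        t_expected = 0.5 / (np.std([0.5, 0.6, 0.4], ddof=1) / np.sqrt(3))
        assert res.t_statistic == pytest.approx(t_expected, abs=1e-6)
        assert t_expected == pytest.approx(5 * np.sqrt(3), abs=1e-12)
        p_expected = 2 * sstats.t.sf(t_expected, df=2)
        assert res.p_value == pytest.approx(p_expected, abs=1e-9)
        assert res.p_value == pytest.approx(0.0131, abs=2e-4)
        assert res.n == 3

    def test_single_pair_raises(self):
        with pytest.raises(InsufficientPairsError):
            paired_comparison([1.0], [2.0])

    def test_missing_pairs_dropped(self):
        res = paired_comparison([1.0, 2.0, np.nan, 3.0], [1.5, 2.6, 2.0, 3.4])
        assert res.n == 3

    def test_all_missing_raises(self):
        with pytest.raises(InsufficientPairsError):
            paired_comparison([np.nan, np.nan, 1.0], [1.0, 2.0, np.nan])

    def test_zero_variance_differences(self):
        with pytest.warns(UserWarning):
            res = paired_comparison([1.0, 2.0, 3.0], [1.1, 2.1, 3.1])
        assert np.isnan(res.p_value)
        assert res.delta_pct == pytest.approx(100 * 0.1 / 2.0)
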