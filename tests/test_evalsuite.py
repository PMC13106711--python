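"""Evaluation machinery: RMSE, Welch PSD, Butterworth baselines, classical
smoothers, and the exact binomial preference test."""

import numpy as np
import pytest
from scipy import signal

import sonopoint as sp
from sonopoint.evalsuite import (
    PreferenceCounts,
    baseline_smoothers,
    butterworth_filter,
    preference_test,
    psd,
    rmse,
)


def traj_from_series(x, y=None, fps=50.0):
    x = np.asarray(x, dtype=float)
    y = x.copy() if y is None else np.asarray(y, dtype=float)
    return sp.Trajectory(0, np.column_stack([x, y]), fps=fps)


# -- RMSE ------------------------------------------------------------------

def test_rmse_identity_and_constant_offset():
    a = traj_from_series(np.arange(100.0))
    assert rmse(a, a) == 0.0
    b = a.with_positions(a.positions + [3.0, 4.0])
    assert rmse(a, b) == pytest.approx(5.0)
    assert rmse(a, b, pitch=75.0) == pytest.approx(375.0)


def test_rmse_requires_matching_ranges():
    a = traj_from_series(np.arange(10.0))
    b = traj_from_series(np.arange(12.0))
    with pytest.raises(ValueError):
        rmse(a, b)


def test_rmse_triangle_inequality():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a, b, c = (
            traj_from_series(rng.normal(size=50), rng.normal(size=50)) for _ in range(3)
        )
        assert rmse(a, c) <= rmse(a, b) + rmse(b, c) + 1e-12


# -- PSD -------------------------------------------------------------------

def test_psd_of_constant_trajectory_is_zero():
    series = psd(traj_from_series(np.full(256, 7.0)))
    assert series.integrated_power(0.1) == pytest.approx(0.0, abs=1e-20)


def test_psd_sinusoid_satisfies_parseval():
    t = np.arange(1024) / 50.0
    x = np.sin(2 * np.pi * 3.0 * t)
    est = psd(traj_from_series(x))  # same sinusoid on both axes
    peak_f = est.frequencies[np.argmax(est.power)]
    assert abs(peak_f - 3.0) <= est.frequencies[1]
    assert est.integrated_power() == pytest.approx(0.5, rel=0.10)


def test_psd_white_noise_total_power_equals_variance():
    rng = np.random.default_rng(42)
    x = rng.normal(size=4096)
    y = rng.normal(size=4096)
    est = psd(traj_from_series(x, y))
    assert est.integrated_power() == pytest.approx(1.0, rel=0.10)


def test_psd_rejects_short_input():
    with pytest.raises(ValueError, match="too short"):
        psd(traj_from_series(np.arange(32.0)))


# -- Butterworth baselines -------------------------------------------------

def test_lowpass_preserves_dc_highpass_rejects_it():
    const = traj_from_series(np.full(300, 5.0))
    lp = butterworth_filter(const, 5.0, "lowpass")
    np.testing.assert_allclose(lp.positions, const.positions, atol=1e-8)
    hp = butterworth_filter(const, 1.5, "highpass")
    np.testing.assert_allclose(hp.positions, 0.0, atol=1e-6)


def test_forward_backward_halves_amplitude_at_cutoff():
    """Zero-phase filtering squares the Butterworth magnitude: the -3 dB
    single-pass point becomes amplitude x 1/2."""
    fps, cutoff = 50.0, 5.0
    sos = signal.butter(4, cutoff, btype="lowpass", fs=fps, output="sos")
    w, h = signal.sosfreqz(sos, worN=[cutoff], fs=fps)
    assert abs(h[0]) == pytest.approx(1 / np.sqrt(2), rel=1e-6)  # single pass
    t = np.arange(4096) / fps
    x = np.sin(2 * np.pi * cutoff * t)
    out = butterworth_filter(traj_from_series(x), cutoff, "lowpass")
    envelope = np.abs(signal.hilbert(out.x))[500:-500]
    assert envelope.mean() == pytest.approx(0.5, rel=0.02)


def test_cutoff_at_nyquist_rejected():
    with pytest.raises(ValueError, match="Nyquist"):
        butterworth_filter(traj_from_series(np.arange(100.0)), 25.0, "lowpass")


def test_scalar_series_filtering_round_trips_type():
    series = sp.ScalarSeries("d", np.sin(np.arange(300) * 0.3), fps=50.0)
    out = butterworth_filter(series, 5.0, "lowpass")
    assert isinstance(out, sp.ScalarSeries)
    assert out.name == "d" and len(out) == 300


# -- classical smoothers ---------------------------------------------------

@pytest.mark.parametrize("method, params", [
    ("kalman_cv", {"process_var": 0.01, "measurement_var": 1.0}),
    ("rts", {"process_var": 0.01, "measurement_var": 1.0}),
    ("ema", {"alpha": 0.3}),
    ("savgol", {"window": 11, "polyorder": 3}),
])
def test_constant_input_maps_to_constant_output(method, params):
    const = traj_from_series(np.full(120, 9.0))
    out = baseline_smoothers(const, method, **params)
    np.testing.assert_allclose(out.positions, 9.0, atol=1e-6)


def test_rts_smoother_beats_causal_kalman():
    """The two-pass smoother uses future data and cannot do worse than the
    causal filter on a constant-velocity track in Gaussian noise."""
    rng = np.random.default_rng(7)
    truth = traj_from_series(0.3 * np.arange(400), 0.1 * np.arange(400))
    noisy = truth.with_positions(truth.positions + rng.normal(0, 2.0, (400, 2)))
    params = {"process_var": 0.01, "measurement_var": 4.0}
    kf = baseline_smoothers(noisy, "kalman_cv", **params)
    rts = baseline_smoothers(noisy, "rts", **params)
    assert rmse(truth, rts) <= rmse(truth, kf)


def test_savgol_reproduces_cubic_exactly():
    t = np.arange(60, dtype=float)
    cubic = 0.001 * t**3 - 0.05 * t**2 + t + 3.0
    out = baseline_smoothers(traj_from_series(cubic), "savgol", window=11, polyorder=3)
    interior = slice(5, -5)
    np.testing.assert_allclose(out.x[interior], cubic[interior], atol=1e-9)


def test_invalid_smoother_params_rejected():
    t = traj_from_series(np.arange(50.0))
    with pytest.raises(ValueError):
        baseline_smoothers(t, "ema", alpha=0.0)
    with pytest.raises(ValueError):
        baseline_smoothers(t, "savgol", window=10, polyorder=3)
    with pytest.raises(ValueError):
        baseline_smoothers(t, "median")


# -- preference test -------------------------------------------------------

def test_blinded_preference_analysis_reproduces_reported_statistics():
    prop, p, lo, hi = preference_test(PreferenceCounts(127, 109, 152))
    assert prop == pytest.approx(0.538, abs=5e-4)
    assert p == pytest.approx(0.268, abs=5e-4)
    assert lo == pytest.approx(0.472, abs=5e-4)
    assert hi == pytest.approx(0.603, abs=5e-4)


def test_symmetric_counts_give_p_one():
    prop, p, lo, hi = preference_test(PreferenceCounts(50, 50, 3))
    assert prop == 0.5
    assert p == pytest.approx(1.0)
    assert lo < 0.5 < hi


def test_one_sided_sweep_matches_exact_enumeration():
    # all 10 preferences to A: p = 2 * (1/2)**10
    _, p, _, _ = preference_test(PreferenceCounts(10, 0, 0))
    assert p == pytest.approx(2 * 0.5**10, rel=1e-9)


def test_ci_contains_proportion_and_narrows_with_n():
    widths = []
    for n in (20, 80, 320):
        k = int(0.6 * n)
        prop, _, lo, hi = preference_test(PreferenceCounts(k, n - k, 0))
        assert lo <= prop <= hi
        widths.append(hi - lo)
    assert widths[0] > widths[1] > widths[2]


def test_no_preferences_rejected():
    with pytest.raises(ValueError):
        preference_test(PreferenceCounts(0, 0, 10))
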