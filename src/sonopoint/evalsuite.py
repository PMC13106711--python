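"""Evaluation machinery: RMSE, spectral analysis, baseline filters, and the
blinded-preference binomial test.

These are the tools used to quantify tracking quality: positional RMSE
against ground truth, Welch power spectral density of trajectories (jitter
lives at high frequency), zero-phase Butterworth low/high-pass baselines,
classical trajectory smoothers (Kalman, Rauch-Tung-Striebel, exponential
moving average, Savitzky-Golay) for comparison, and an exact binomial test
with Clopper-Pearson interval for blinded A/B preference counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .measures import ScalarSeries
from .trajectory import Trajectory

__all__ = [
    "PreferenceCounts",
    "SpectrumEstimate",
    "rmse",
    "psd",
    "band_power",
    "butterworth_filter",
    "baseline_smoothers",
    "preference_test",
]


@dataclass(frozen=True)
class PreferenceCounts:
    """Blinded A/B preference tallies; ties are excluded from testing."""

    n_pref_a: int
    n_pref_b: int
    n_tie: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pref_a, self.n_pref_b, self.n_tie) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class SpectrumEstimate:
    """One-sided power spectral density on a frequency grid in [0, fps/2]."""

    frequencies: np.ndarray
    power: np.ndarray
    n_segments: int

    def integrated_power(self, f_low: float = 0.0, f_high: float | None = None) -> float:
        """Trapezoidal integral of the PSD over [f_low, f_high] (Hz)."""
        f = self.frequencies
        hi = f[-1] if f_high is None else f_high
        mask = (f >= f_low) & (f <= hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(self.power[mask], f[mask]))


def rmse(a: Trajectory, b: Trajectory, pitch: float | None = None) -> float:
    """Root-mean-square Euclidean 2-D displacement between two trajectories.

    ``sqrt(mean_t ||a_t - b_t||^2)``, in micrometres when ``pitch`` (um/px)
    is given, else pixels.
    """
    if not a.same_range(b):
        raise ValueError("trajectories must cover the same frame range")
    sq = np.sum((a.positions - b.positions) ** 2, axis=1)
    value = float(np.sqrt(np.mean(sq)))
    return value * pitch if pitch is not None else value


def psd(traj: Trajectory, nperseg: int | None = None) -> SpectrumEstimate:
    """Welch power spectral density of a trajectory, averaged over x and y.

    Each axis is mean-removed, Welch-estimated with a Hann window, segment
    length ``min(256, n)`` and 50% overlap, and the two per-axis densities
    are averaged.  Satisfies Parseval (integral ~ per-axis-mean variance)
    within windowing tolerance.
    """
    n = len(traj)
    if n < 64:
        raise ValueError(f"trajectory too short for spectral estimation ({n} < 64 frames)")
    seg = min(256, n) if nperseg is None else min(nperseg, n)
    powers = []
    for axis in range(2):
        series = traj.positions[:, axis]
        f, p = signal.welch(
            series - series.mean(), fs=traj.fps, window="hann",
            nperseg=seg, noverlap=seg // 2, detrend="constant",
        )
        powers.append(p)
    n_segments = max(1, 1 + (n - seg) // (seg - seg // 2))
    return SpectrumEstimate(frequencies=f, power=(powers[0] + powers[1]) / 2.0,
                            n_segments=n_segments)


def band_power(traj: Trajectory, f_low: float, f_high: float | None = None) -> float:
    """Integrated PSD of a trajectory over a frequency band (convenience)."""
    return psd(traj).integrated_power(f_low, f_high)


def _apply_sos_zero_phase(values: np.ndarray, sos: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, values, axis=0)


def butterworth_filter(series, cutoff: float, mode: str = "lowpass", order: int = 4):
    """Zero-phase (forward-backward) Butterworth filter.

    Accepts a :class:`Trajectory` (filters x and y) or a
    :class:`ScalarSeries`; returns the same type.  The forward-backward pass
    squares the magnitude response, so a single-pass -3 dB cutoff becomes a
    -6 dB (amplitude x1/2) point.  DC gain is 1 for lowpass, 0 for highpass.
    """
    if mode not in ("lowpass", "highpass"):
        raise ValueError(f"mode must be 'lowpass' or 'highpass', got {mode!r}")
    fps = series.fps
    if not 0 < cutoff < fps / 2:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, {fps / 2}) (Nyquist)")
    sos = signal.butter(order, cutoff, btype=mode, fs=fps, output="sos")
    if isinstance(series, Trajectory):
        return series.with_positions(_apply_sos_zero_phase(series.positions, sos))
    if isinstance(series, ScalarSeries):
        return ScalarSeries(
            name=series.name, values=_apply_sos_zero_phase(series.values, sos),
            units=series.units, fps=series.fps, first_frame=series.first_frame,
        )
    raise TypeError(f"expected Trajectory or ScalarSeries, got {type(series).__name__}")


# ---------------------------------------------------------------------------
# classical trajectory smoothers (comparison baselines)
# ---------------------------------------------------------------------------

def _kalman_cv(series: np.ndarray, q: float, r: float, smooth: bool) -> np.ndarray:
    """Constant-velocity Kalman filter (optionally RTS-smoothed), one axis.

    State [position, velocity]; process noise enters through acceleration
    with variance ``q``, measurement noise variance ``r``.
    """
    n = series.shape[0]
    F = np.array([[1.0, 1.0], [0.0, 1.0]])
    H = np.array([[1.0, 0.0]])
    Q = q * np.array([[0.25, 0.5], [0.5, 1.0]])  # discrete white-accel model, dt=1
    R = np.array([[r]])

    x = np.array([series[0], 0.0])
    P = np.diag([r, 1.0])
    xs_pred = np.empty((n, 2)); Ps_pred = np.empty((n, 2, 2))
    xs_filt = np.empty((n, 2)); Ps_filt = np.empty((n, 2, 2))
    for t in range(n):
        if t == 0:
            xp, Pp = x, P
        else:
            xp = F @ xs_filt[t - 1]
            Pp = F @ Ps_filt[t - 1] @ F.T + Q
        xs_pred[t], Ps_pred[t] = xp, Pp
        S = H @ Pp @ H.T + R
        K = Pp @ H.T / S
        innov = series[t] - (H @ xp)[0]
        xs_filt[t] = xp + (K * innov).ravel()
        Ps_filt[t] = (np.eye(2) - K @ H) @ Pp

    if not smooth:
        return xs_filt[:, 0]
    xs = xs_filt.copy()
    Ps = Ps_filt.copy()
    for t in range(n - 2, -1, -1):
        C = Ps_filt[t] @ F.T @ np.linalg.inv(Ps_pred[t + 1])
        xs[t] = xs_filt[t] + C @ (xs[t + 1] - xs_pred[t + 1])
        Ps[t] = Ps_filt[t] + C @ (Ps[t + 1] - Ps_pred[t + 1]) @ C.T
    return xs[:, 0]


def _ema(series: np.ndarray, alpha: float) -> np.ndarray:
    out = np.empty_like(series)
    out[0] = series[0]
    for t in range(1, series.shape[0]):
        out[t] = alpha * series[t] + (1 - alpha) * out[t - 1]
    return out


def baseline_smoothers(traj: Trajectory, method: str, **params) -> Trajectory:
    """Classical per-axis trajectory smoothers used as comparison baselines.

    method:
        ``kalman_cv`` — causal constant-velocity Kalman filter
        (``process_var``, ``measurement_var``);
        ``rts`` — the Rauch-Tung-Striebel two-pass smoother of the same
        model (same params);
        ``ema`` — exponential moving average (``alpha`` in (0, 1]);
        ``savgol`` — Savitzky-Golay (``window`` odd, ``polyorder`` < window).

    Unlike the transposed sliding-window filter these operate on the time
    series alone and use no motion information from the video.
    """
    if method in ("kalman_cv", "rts"):
        q = float(params.get("process_var", 0.01))
        r = float(params.get("measurement_var", 1.0))
        if q <= 0 or r <= 0:
            raise ValueError("process_var and measurement_var must be positive")
        cols = [
            _kalman_cv(traj.positions[:, ax], q, r, smooth=(method == "rts"))
            for ax in range(2)
        ]
    elif method == "ema":
        alpha = float(params.get("alpha", 0.3))
        if not 0 < alpha <= 1:
            raise ValueError(f"ema alpha must be in (0, 1], got {alpha}")
        cols = [_ema(traj.positions[:, ax], alpha) for ax in range(2)]
    elif method == "savgol":
        window = int(params.get("window", 11))
        polyorder = int(params.get("polyorder", 3))
        if window % 2 == 0 or polyorder >= window:
            raise ValueError("savgol needs odd window and polyorder < window")
        cols = [
            signal.savgol_filter(traj.positions[:, ax], window, polyorder)
            for ax in range(2)
        ]
    else:
        raise ValueError(f"unknown smoother {method!r}")
    return traj.with_positions(np.column_stack(cols))


def preference_test(counts: PreferenceCounts) -> tuple[float, float, float, float]:
    """Exact two-sided binomial test of A-vs-B preference against p=0.5.

    Ties are excluded.  Returns ``(proportion, p_value, ci_low, ci_high)``
    where the interval is the exact 95% Clopper-Pearson interval for the
    proportion preferring A.
    """
    n = counts.n_pref_a + counts.n_pref_b
    if n < 1:
        raise ValueError("need at least one non-tie preference")
    result = stats.binomtest(counts.n_pref_a, n, p=0.5, alternative="two-sided")
    ci = result.proportion_ci(confidence_level=0.95, method="exact")
    return (
        counts.n_pref_a / n,
        float(result.pvalue),
        float(ci.low),
        float(ci.high),
    )
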