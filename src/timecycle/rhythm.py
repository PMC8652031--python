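"""Period, phase and amplitude estimation from a harmonic fit.

Runs on the replicate-averaged, imputed but UNSCALED series so that
amplitude stays in input units.  A linearly detrended, moving-average
smoothed copy of the signal selects the three strongest DFT harmonics;
the trend and those harmonics are then jointly least-squares fitted to
the raw series, which makes recovery exact on bin-aligned noiseless
sinusoids (coefficients read off the smoothed spectrum would be
attenuated by the smoother's frequency response).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from timecycle.types import Series

__all__ = ["detrend_linear", "moving_average", "estimate_rhythm",
           "HarmonicFit"]

_FLAT_TOL = 1e-10


class HarmonicFit:
    """Result of the trend + three-harmonic least-squares fit."""

    __slots__ = ("harmonics", "fitted_values", "trend_slope",
                 "trend_intercept")

    def __init__(self, harmonics, fitted_values, trend_slope,
                 trend_intercept) -> None:
        freqs = [h[0] for h in harmonics]
        if len(set(freqs)) != len(freqs) or any(f <= 0 for f in freqs):
            raise ValueError("harmonic frequencies must be positive, distinct")
        self.harmonics = list(harmonics)  # (freq cyc/h, amplitude, phase rad)
        self.fitted_values = np.asarray(fitted_values, dtype=float)
        self.trend_slope = float(trend_slope)
        self.trend_intercept = float(trend_intercept)


def detrend_linear(s: Series) -> Series:
    """Remove the least-squares line; output is mean-0, time-uncorrelated."""
    if s.mask.any():
        raise ValueError("detrend_linear requires a fully observed series")
    if len(s) < 3:
        raise ValueError("need at least 3 points")
    slope, intercept = np.polyfit(s.times, s.values, 1)
    return Series(s.times.copy(), s.values - (slope * s.times + intercept))


def moving_average(s: Series, window: int = 3) -> Series:
    """Centered moving average; the window is clipped at the edges."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(s):
        raise ValueError(f"window {window} exceeds series length {len(s)}")
    if s.mask.any():
        raise ValueError("moving_average requires a fully observed series")
    half = window // 2
    n = len(s)
    out = np.empty(n)
    for i in range(n):
        out[i] = s.values[max(0, i - half): min(n, i + half + 1)].mean()
    return Series(s.times.copy(), out)


def _design(times: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(times), times]
    for f in freqs:
        w = 2 * np.pi * f * times
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    return np.column_stack(cols)


def fit_harmonics(s: Series, expected_period_h: float = 24.0,
                  n_harmonics: int = 3,
                  smooth_window: int = 3) -> Optional[HarmonicFit]:
    """Three-harmonic fit; None when the signal is flat after detrending."""
    n = len(s)
    if n < 8:
        raise ValueError("need at least 8 points on a uniform grid")
    dt = np.diff(s.times)
    if dt.max() - dt.min() > 1e-9:
        raise ValueError("estimate_rhythm requires a uniform time grid")
    step = float(dt[0])

    smoothed = moving_average(detrend_linear(s), smooth_window)
    spec = np.fft.rfft(smoothed.values)
    freqs = np.fft.rfftfreq(n, d=step)  # cycles per hour
    mags = np.abs(spec)
    mags[0] = 0.0  # DC is not a harmonic
    if mags.max() < _FLAT_TOL * max(1.0, float(np.abs(s.values).max())):
        return None
    keep = np.argsort(mags)[::-1][:n_harmonics]
    keep = np.array([k for k in keep if mags[k] > 0.0])
    if keep.size == 0:
        return None

    X = _design(s.times, freqs[keep])
    beta, *_ = np.linalg.lstsq(X, s.values, rcond=None)
    intercept, slope = beta[0], beta[1]
    harmonics = []
    for idx, k in enumerate(keep):
        a = beta[2 + 2 * idx]      # cos coefficient
        b = beta[3 + 2 * idx]      # sin coefficient
        amp = float(np.hypot(a, b))
        phase = float(np.arctan2(-b, a))  # x ~ amp * cos(w t + phase)
        harmonics.append((float(freqs[k]), amp, phase))
    fitted = X[:, 2:] @ beta[2:]
    return HarmonicFit(harmonics, fitted, slope, intercept)


def _harmonic_curve(fit: HarmonicFit, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    for f, amp, phase in fit.harmonics:
        out += amp * np.cos(2 * np.pi * f * t + phase)
    return out


def estimate_rhythm(
    s: Series,
    expected_period_h: float = 24.0,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(period_h, phase_h, amplitude) from the harmonic fit.

    The dominant harmonic is the largest-amplitude fitted harmonic with
    period within [expected/2, 2*expected] (falling back to the overall
    largest); period = 1/f_dominant, phase = time of the fitted curve's
    first maximum in [0, period), amplitude = half the fitted curve's
    peak-to-trough range.  Returns (None, None, None) for flat signals.
    """
    try:
        fit = fit_harmonics(s, expected_period_h)
    except np.linalg.LinAlgError:
        return None, None, None
    if fit is None:
        return None, None, None
    resid_scale = float(np.std(s.values)) or 1.0
    if max(h[1] for h in fit.harmonics) < _FLAT_TOL * max(1.0, resid_scale):
        return None, None, None

    lo, hi = 1.0 / (2 * expected_period_h), 2.0 / expected_period_h
    in_band = [h for h in fit.harmonics if lo <= h[0] <= hi]
    pool = in_band if in_band else fit.harmonics
    f_dom = max(pool, key=lambda h: h[1])[0]
    period = 1.0 / f_dom

    # fitted harmonic curve on a fine grid over one period for the phase
    fine = np.linspace(0.0, period, 4096, endpoint=False)
    curve = _harmonic_curve(fit, fine)
    i = int(np.argmax(curve))
    # parabolic refinement around the discrete maximum (cyclic neighbours)
    y0, y1, y2 = curve[i - 1], curve[i], curve[(i + 1) % len(curve)]
    denom = y0 - 2 * y1 + y2
    offset = 0.0 if abs(denom) < 1e-300 else 0.5 * (y0 - y2) / denom
    phase = (fine[1] - fine[0]) * (i + offset) % period

    # amplitude over the sampled record; parabolic refinement of the
    # discrete extrema removes the fine-grid discretization error
    span = np.linspace(s.times[0], s.times[-1], 4096)
    rec = _harmonic_curve(fit, span)

    def refined(idx: int) -> float:
        if idx == 0 or idx == len(rec) - 1:
            return rec[idx]
        y0, y1, y2 = rec[idx - 1], rec[idx], rec[idx + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) < 1e-300:
            return y1
        return y1 - (y0 - y2) ** 2 / (8 * denom)

    top = refined(int(np.argmax(rec)))
    bot = refined(int(np.argmin(rec)))
    amplitude = float((top - bot) / 2.0)
    return float(period), float(phase), amplitude
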