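"""Time-signal metrics of per-vessel WSS statistics.

The fluctuating part of each signal (mean, max, min, sigma of WSS over a
vessel versus time) is summarized by its RMS and by an oscillation
timescale: the inverse of the dominant nonzero frequency of the
mean-removed spectrum (plain FFT, no window).  A timescale is flagged
undefined when the spectral peak does not rise above the noise floor
(three times the median spectral amplitude).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SignalMetrics:
    rms: float
    timescale: float      # s; NaN when undefined
    defined: bool


def signal_metrics(signal, cadence: float, noise_floor_factor: float = 3.0) -> SignalMetrics:
    """RMS of fluctuations and FFT-based oscillation timescale of one signal."""
    s = np.asarray(signal, dtype=float)
    if s.ndim != 1 or len(s) < 16:
        raise ValueError("need a 1D signal with at least 16 uniform samples")
    if cadence <= 0:
        raise ValueError("cadence must be positive")
    fluct = s - s.mean()
    rms = float(np.sqrt(np.mean(fluct**2)))
    amp = np.abs(np.fft.rfft(fluct))
    freqs = np.fft.rfftfreq(len(s), d=cadence)
    amp[0] = 0.0
    peak = int(np.argmax(amp))
    floor = noise_floor_factor * float(np.median(amp[1:]))
    if amp[peak] <= floor or freqs[peak] == 0.0:
        return SignalMetrics(rms, float("nan"), False)
    return SignalMetrics(rms, float(1.0 / freqs[peak]), True)


def time_signal_metrics(signals: dict, cadence: float) -> pd.DataFrame:
    """Metrics for a nested mapping {vessel: {statistic: 1D array}}.

    Raises on non-uniform cadence input (pass the scalar snapshot
    spacing); returns a tidy table with one row per vessel/statistic.
    """
    rows = []
    for vessel, stats in signals.items():
        for stat, arr in stats.items():
            m = signal_metrics(arr, cadence)
            rows.append(
                {
                    "vessel": vessel,
                    "statistic": stat,
                    "rms": m.rms,
                    "timescale": m.timescale,
                    "timescale_defined": m.defined,
                }
            )
    return pd.DataFrame(rows)


def rms_vs_diameter_fit(rms, diameters):
    """Power-law regression RMS = prefactor * D**exponent.

    Least squares on log-log axes; nonpositive entries are excluded.
    Returns (exponent, prefactor, r_squared).
    """
    rms = np.asarray(rms, dtype=float)
    d = np.asarray(diameters, dtype=float)
    ok = (rms > 0) & (d > 0)
    if ok.sum() < np.count_nonzero(np.isfinite(rms)):
        import warnings

        warnings.warn("nonpositive RMS/diameter entries excluded from power-law fit")
    rms, d = rms[ok], d[ok]
    if len(rms) < 3 or np.unique(d).size < 2:
        raise ValueError("power-law fit needs >= 3 vessels spanning > 1 diameter")
    x, y = np.log(d), np.log(rms)
    A = np.vstack([x, np.ones_like(x)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(A, y, rcond=None)
    yhat = A @ np.array([slope, intercept])
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(np.exp(intercept)), r2
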