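"""Noise and drift models for the synthetic generator.

ECoG broadband activity is pink (1/f) noise, produced by passing white noise
through the classic three-pole "economy" pinking IIR filter (cheap and
streaming-friendly at long recording lengths). Baseline drift is a sum of
two slow sinusoids with a bounded slope, emulating electrode/DC drift;
optical traces get white noise plus a small linear drift.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

__all__ = ["pink_noise", "slow_drift", "linear_drift"]

# Paul Kellet's economy pinking filter (approximates a 1/f spectrum over
# several decades with a 3-pole IIR).
_PINK_B = (0.049922035, -0.095993537, 0.050612699, -0.004408786)
_PINK_A = (1.0, -2.494956002, 2.017265875, -0.522189400)


def pink_noise(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Pink (1/f) noise, ``n`` samples, scaled to standard deviation ``sigma``."""
    white = rng.standard_normal(n + 2000)
    pink = sps.lfilter(_PINK_B, _PINK_A, white)[2000:]  # drop filter warm-up
    scale = pink.std()
    if scale > 0:
        pink *= sigma / scale
    return pink


def slow_drift(
    t_s: np.ndarray,
    rng: np.random.Generator,
    amplitude_mV: float = 1.5,
    max_slope_mV_per_min: float = 0.2,
) -> np.ndarray:
    """Bounded-slope baseline drift: two slow sinusoids with random phase.

    Periods are drawn from 40-90 min; amplitudes are reduced if needed so the
    worst-case slope stays below ``max_slope_mV_per_min``.
    """
    drift = np.zeros_like(t_s, dtype=float)
    for _ in range(2):
        period_s = rng.uniform(40.0, 90.0) * 60.0
        amp = amplitude_mV * rng.uniform(0.3, 1.0)
        # slope bound: amp * 2*pi/period <= max_slope / 60 (per second)
        max_amp = max_slope_mV_per_min / 60.0 * period_s / (2.0 * np.pi) / 2.0
        amp = min(amp, max_amp)
        drift += amp * np.sin(2.0 * np.pi * t_s / period_s + rng.uniform(0, 2 * np.pi))
    return drift


def linear_drift(n: int, dt_s: float, slope_pct_per_h: float) -> np.ndarray:
    """Linear drift in percent-of-baseline units."""
    t_h = np.arange(n) * dt_s / 3600.0
    return slope_pct_per_h * t_h
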