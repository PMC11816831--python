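"""Analytic waveforms used by the synthetic generator.

Hemodynamic component pulses are modelled as a short linear rise followed by
a half-Gaussian decay. The shape is smooth on the decay side, strictly
positive-support and asymmetric (fast rise, slow return) like observed SD
vasomotor transients, and its two defining properties are exact by
construction:

* the pulse foot sits exactly at the component onset, with a linear leading
  edge whose zero-crossing an edge-extrapolation onset estimator recovers to
  sub-sample precision;
* the full width at half maximum equals the requested ``fwhm`` exactly
  (``rise/2`` on the way up plus ``tau * sqrt(2 ln 2)`` on the way down).

The ECoG slow potential change is a negative trapezoid: a fast fall, a
plateau and a slower linear recovery.
"""

from __future__ import annotations

import numpy as np

__all__ = ["component_pulse", "spc_waveform", "DEFAULT_RISE_S"]

_HALF_WIDTH = np.sqrt(2.0 * np.log(2.0))

#: Default leading-edge duration of hemodynamic pulses (seconds): SD
#: wavefront passage produces a sharp vasomotor onset.
DEFAULT_RISE_S = 10.0


def component_pulse(
    t_s: np.ndarray, amplitude: float, fwhm_s: float, rise_s: float = DEFAULT_RISE_S
) -> np.ndarray:
    """Evaluate a unit hemodynamic pulse starting at t = 0.

    Parameters
    ----------
    t_s : time axis in seconds (the pulse foot is at 0).
    amplitude : signed peak value.
    fwhm_s : full width at half maximum, seconds; must exceed ``rise_s / 2``.
    rise_s : linear leading-edge duration, seconds.
    """
    if fwhm_s <= rise_s / 2.0:
        raise ValueError(f"fwhm_s={fwhm_s} must exceed rise_s/2={rise_s / 2}")
    t = np.asarray(t_s, dtype=float)
    tau = (fwhm_s - rise_s / 2.0) / _HALF_WIDTH
    out = np.zeros_like(t)
    rising = (t > 0) & (t < rise_s)
    out[rising] = t[rising] / rise_s
    decaying = t >= rise_s
    out[decaying] = np.exp(-0.5 * ((t[decaying] - rise_s) / tau) ** 2)
    return amplitude * out


def spc_waveform(
    t_s: np.ndarray,
    depth_mV: float,
    duration_s: float,
    fall_s: float = 10.0,
    recovery_s: float = 30.0,
) -> np.ndarray:
    """Negative slow-potential-change deflection starting at t = 0.

    Linear fall over ``fall_s`` to ``-depth_mV``, plateau, then linear
    recovery over ``recovery_s``; total support is ``duration_s``.
    """
    if duration_s <= fall_s + recovery_s:
        raise ValueError("SPC duration must exceed fall + recovery time")
    t = np.asarray(t_s, dtype=float)
    plateau_end = duration_s - recovery_s
    out = np.zeros_like(t)
    falling = (t > 0) & (t < fall_s)
    out[falling] = -depth_mV * t[falling] / fall_s
    flat = (t >= fall_s) & (t < plateau_end)
    out[flat] = -depth_mV
    recovering = (t >= plateau_end) & (t < duration_s)
    out[recovering] = -depth_mV * (1.0 - (t[recovering] - plateau_end) / recovery_s)
    return out
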