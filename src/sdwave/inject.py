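"""Injection of ground-truth SD waves into synthetic recordings.

Each injector adds the physical signature of one kinematic SD wave to an
existing recording/trace set: reached sensors receive the template's
waveform delayed by ``distance(origin, sensor) / speed``; unreached sensors
are untouched. All three follow the field's sign conventions:

* ECoG: a negative slow potential deflection plus suppression of the
  superimposed broadband activity;
* IOS: component pulses are specified in CBV-positive percent and converted
  to intensity with the inverted 564 nm convention (hyperemia = darker);
* LSCI: a monophasic CBF rise with positively-coupled OxyHb and
  negatively-coupled, slightly lagged deOxyHb.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .model import CorticalLayout, ROITraceSet, SDTemplate, TimeSeriesRecording
from .pulses import DEFAULT_RISE_S, component_pulse, spc_waveform

__all__ = ["inject_sd_ecog", "inject_sd_optical", "inject_sd_lsci"]


def inject_sd_ecog(
    recording: TimeSeriesRecording,
    template: SDTemplate,
    layout: CorticalLayout,
    hf_cut_hz: float = 0.5,
) -> list[str]:
    """Add one SD's electrophysiological signature in place.

    Returns a list of flags ("truncated" when an arrival falls beyond the
    recorded span; the event is then clipped rather than dropped).
    """
    fs = recording.sampling_rate
    flags: list[str] = []
    arrivals = template.arrival_times(layout)
    span_s = recording.duration_s - recording.occlusion_time_s
    if min(arrivals.values()) >= span_s:
        warnings.warn(
            f"event {template.event_id}: arrivals beyond recording end; truncated",
            stacklevel=2,
        )
        return ["truncated"]

    dep_len_s = template.depression_duration_min * 60.0
    for ch, arrival in arrivals.items():
        if arrival >= span_s:
            flags.append("truncated")
            continue
        idx = recording.channel_index(ch)
        t0 = recording.occlusion_time_s + arrival  # s from record start
        i0 = int(round(t0 * fs))
        n_pulse = int(template.dc_duration_s * fs) + 1
        i1 = min(i0 + n_pulse, recording.n_samples)
        if i1 <= i0:
            flags.append("truncated")
            continue
        t_rel = (np.arange(i0, i1) - t0 * fs) / fs
        recording.data[idx, i0:i1] += spc_waveform(
            t_rel, template.dc_amplitude_mV, template.dc_duration_s
        )
        _apply_depression(
            recording.data[idx],
            fs,
            start_s=t0,
            duration_s=dep_len_s,
            fraction=template.depression_fraction,
            hf_cut_hz=hf_cut_hz,
        )
    return flags


def _apply_depression(
    channel: np.ndarray,
    fs: float,
    start_s: float,
    duration_s: float,
    fraction: float,
    hf_cut_hz: float,
    ramp_s: float = 10.0,
) -> None:
    """Suppress the >= ``hf_cut_hz`` activity to ``fraction`` over a window.

    Works on a local slice only: the slice is split into slow + fast parts
    with a zero-phase high-pass, the fast part is scaled by a smooth
    envelope, and the parts are recombined.
    """
    pad_s = 30.0
    i0 = max(0, int((start_s - pad_s) * fs))
    i1 = min(len(channel), int((start_s + duration_s + pad_s) * fs))
    if i1 - i0 < int(4 * fs):
        return
    sos = sps.butter(2, hf_cut_hz, btype="highpass", fs=fs, output="sos")
    segment = channel[i0:i1]
    fast = sps.sosfiltfilt(sos, segment)
    slow = segment - fast
    t = np.arange(i0, i1) / fs
    envelope = np.ones_like(t)
    in_dep = (t >= start_s) & (t <= start_s + duration_s)
    envelope[in_dep] = fraction
    # cosine ramps at the edges of the depression window
    for edge, direction in ((start_s, +1), (start_s + duration_s, -1)):
        ramp = (t >= edge - ramp_s / 2) & (t <= edge + ramp_s / 2)
        phase = (t[ramp] - edge) / ramp_s * np.pi * direction
        envelope[ramp] = fraction + (1 - fraction) * (0.5 - 0.5 * np.sin(phase))
    channel[i0:i1] = slow + fast * envelope


def inject_sd_optical(
    traceset: ROITraceSet,
    template: SDTemplate,
    layout: CorticalLayout,
    rise_s: float = DEFAULT_RISE_S,
) -> list[str]:
    """Add one SD's hemodynamic signature to an IOS trace set in place.

    Component pulses are summed in CBV-percent and written to intensity with
    the inverted sign convention ``I = I - I0 * cbv / 100`` relative to each
    ROI's nominal baseline ``I0``.
    """
    if traceset.modality != "IOS":
        raise ValueError("inject_sd_optical expects an IOS trace set")
    flags: list[str] = []
    arrivals = template.arrival_times(layout)
    dt = traceset.sampling_interval_s
    t = traceset.times_s() - traceset.occlusion_time_s  # s post-occlusion
    intensity = traceset.signals["intensity"]
    baselines = traceset.baseline_values
    if baselines is None:
        raise ValueError("trace set lacks nominal baseline values for injection")
    span_s = traceset.duration_s - traceset.occlusion_time_s
    for roi, arrival in arrivals.items():
        if arrival >= span_s:
            warnings.warn(f"event {template.event_id}: ROI {roi} arrival truncated", stacklevel=2)
            flags.append("truncated")
            continue
        idx = traceset.roi_index(roi)
        cbv = np.zeros_like(t)
        for comp in template.components_for(roi):
            cbv += component_pulse(
                t - arrival - comp.lag_min * 60.0,
                comp.peak_amplitude_pct,
                comp.fwhm_min * 60.0,
                rise_s,
            )
        intensity[idx] -= baselines[idx] * cbv / 100.0
    return flags


def inject_sd_lsci(
    traceset: ROITraceSet,
    template: SDTemplate,
    layout: CorticalLayout,
    rise_s: float = DEFAULT_RISE_S,
) -> list[str]:
    """Add one SD's perfusion signature to an LSCI trace set in place.

    The CBF trace rises by the template's component-III amplitude (percent of
    baseline) and returns to baseline; OxyHb co-varies positively with gain
    ``oxy_gain``; deOxyHb co-varies negatively with gain ``deoxy_gain`` and a
    small onset lag.
    """
    if traceset.modality != "LSCI":
        raise ValueError("inject_sd_lsci expects an LSCI trace set")
    flags: list[str] = []
    arrivals = template.arrival_times(layout)
    t = traceset.times_s() - traceset.occlusion_time_s
    baselines = traceset.baseline_values
    if baselines is None:
        raise ValueError("trace set lacks nominal baseline values for injection")
    span_s = traceset.duration_s - traceset.occlusion_time_s
    for roi, arrival in arrivals.items():
        if arrival >= span_s:
            warnings.warn(f"event {template.event_id}: ROI {roi} arrival truncated", stacklevel=2)
            flags.append("truncated")
            continue
        idx = traceset.roi_index(roi)
        for comp in template.components_for(roi):
            shape = component_pulse(
                t - arrival - comp.lag_min * 60.0, comp.peak_amplitude_pct / 100.0,
                comp.fwhm_min * 60.0, rise_s,
            )
            lagged = component_pulse(
                t - arrival - comp.lag_min * 60.0 - template.deoxy_lag_s,
                comp.peak_amplitude_pct / 100.0, comp.fwhm_min * 60.0, rise_s,
            )
            cbf0 = baselines[idx]
            traceset.signals["CBF"][idx] += cbf0 * shape
            oxy0 = np.median(traceset.signals["OxyHb"][idx][: max(3, int(60 / traceset.sampling_interval_s))])
            deoxy0 = np.median(traceset.signals["deOxyHb"][idx][: max(3, int(60 / traceset.sampling_interval_s))])
            traceset.signals["OxyHb"][idx] += oxy0 * template.oxy_gain * shape
            traceset.signals["deOxyHb"][idx] -= deoxy0 * template.deoxy_gain * lagged
    return flags
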