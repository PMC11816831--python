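"""IOS pipeline: baseline, deviation detection, the >= 2-ROI rule, component
decomposition and morphology classification.

At the 564 nm isosbestic wavelength, reflected intensity tracks total
hemoglobin: a *drop* in intensity means more blood volume (hyperemia).
Traces are therefore converted to a CBV-positive percent scale,
``cbv = -(I - I0)/I0 * 100``, before any thresholding. An SD is an
intensity change expanding to at least two ROIs; each ROI's response is
decomposed into the canonical vasomotor components (I brief hyperemia,
II initial hypoperfusion, III peak hyperemia, IV late hyperemia, V post-SD
oligemia) and classified into one of the four observed morphologies by its
component-kind sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal as sps

from .grouping import SensorCandidate, estimate_onset, group_candidates, runs_above
from .model import (
    Component, CorticalLayout, HemodynamicResponse, ROITraceSet, SDEvent,
)
from .pulses import DEFAULT_RISE_S, component_pulse
from .ecog import expansion

__all__ = [
    "OpticalConfig", "Deviation", "ResponseWindow",
    "to_cbv", "establish_baseline", "detect_deviations", "group_sd_ios", "refine_onset",
    "decompose_components", "classify_morphology", "hyperemia_metrics",
    "analyze_responses", "motion_qc",
]

#: morphology taxonomy: exact component-kind sequences
_MORPHOLOGY_TABLE = {
    ("III",): "monophasic",
    ("III", "IV"): "biphasic",
    ("II", "III", "IV"): "triphasic",
    ("I", "II", "III", "IV"): "tetraphasic",
}


@dataclass
class OpticalConfig:
    """Deviation / decomposition thresholds for optical traces."""

    k_sigma: float = 3.0
    min_len_s: float = 20.0
    merge_gap_s: float = 420.0  # segments closer than this belong to one response
    pad_s: float = 60.0
    smooth_s: float = 15.0
    peak_separation_s: float = 60.0
    rise_s: float = DEFAULT_RISE_S
    speed_band_mm_per_min: tuple[float, float] = (1.0, 10.0)
    scope: str = "hemisphere"
    min_baseline_s: float = 300.0
    refine_fit: bool = True


@dataclass
class Deviation:
    """One maximal supra-threshold deflection segment of a CBV trace."""

    polarity: int  # +1 hyperemic, -1 hypoperfusive
    onset_s: float  # leading-edge extrapolated, trace time base
    t_start_s: float
    t_end_s: float
    peak_pct: float  # signed CBV percent
    i_peak: int


@dataclass
class ResponseWindow:
    """Per-(event, ROI) analysis window handed to the decomposition."""

    roi_id: str
    onset_s: float  # s post-occlusion
    t0_s: float  # window bounds, s post-occlusion
    t1_s: float
    baseline: float
    sigma_pct: float
    deviations: list[Deviation]


def to_cbv(trace: np.ndarray, baseline: float) -> np.ndarray:
    """Intensity -> CBV percent with the inverted 564 nm sign convention."""
    if baseline <= 0:
        raise ValueError("baseline intensity must be positive")
    return -(np.asarray(trace, dtype=float) - baseline) / baseline * 100.0


def establish_baseline(
    trace: np.ndarray,
    event_free_mask: np.ndarray | None = None,
    dt_s: float = 1.0,
    min_baseline_s: float = 300.0,
) -> tuple[float, float]:
    """Robust per-ROI baseline: median and 1.4826*MAD over event-free samples.

    If the event-free window is shorter than ``min_baseline_s`` the mask is
    widened to the whole trace with a warning (median/MAD stay robust to the
    events themselves).
    """
    trace = np.asarray(trace, dtype=float)
    if event_free_mask is None:
        event_free_mask = np.ones(trace.size, dtype=bool)
    if event_free_mask.sum() * dt_s < min_baseline_s:
        warnings.warn(
            f"event-free baseline shorter than {min_baseline_s:.0f} s; "
            "widening to the full trace", stacklevel=2)
        event_free_mask = np.ones(trace.size, dtype=bool)
    sample = trace[event_free_mask]
    i0 = float(np.median(sample))
    sigma = float(1.4826 * np.median(np.abs(sample - i0)))
    return i0, sigma


def detect_deviations(
    cbv: np.ndarray,
    sigma_pct: float,
    dt_s: float = 1.0,
    k_sigma: float = 3.0,
    min_len_s: float = 20.0,
) -> list[Deviation]:
    """Maximal contiguous segments with ``|cbv| >= k*sigma`` for >= ``min_len``.

    Adjacent opposite-polarity segments are kept separate (they are distinct
    vasomotor phases). Onsets are leading-edge extrapolations.
    """
    cbv = np.asarray(cbv, dtype=float)
    t = np.arange(cbv.size) * dt_s
    min_len = max(2, int(round(min_len_s / dt_s)))
    out: list[Deviation] = []
    for polarity in (+1, -1):
        y = polarity * cbv
        for start, stop in runs_above(y >= k_sigma * sigma_pct, min_len):
            i_peak = start + int(np.argmax(y[start:stop]))
            out.append(Deviation(
                polarity=polarity,
                onset_s=estimate_onset(t, y, i_peak),
                t_start_s=float(t[start]),
                t_end_s=float(t[stop - 1]),
                peak_pct=float(polarity * y[i_peak]),
                i_peak=i_peak,
            ))
    out.sort(key=lambda d: d.t_start_s)
    return out


def refine_onset(
    cbv: np.ndarray,
    dt_s: float,
    devs: Deviation | list[Deviation],
    rise_s: float = DEFAULT_RISE_S,
) -> float:
    """Sharpen a response's onset by pulse-fitting its leading segments.

    The edge-extrapolated onset is noise-limited for small components; a
    local least-squares fit of one pulse per segment (the first two
    segments of the response, so an adjacent opposite-polarity phase is
    modeled rather than contaminating the tail) uses every sample and
    recovers the foot of the first pulse to a fraction of a frame. Falls
    back to the edge estimate if the fit fails or wanders.
    """
    if isinstance(devs, Deviation):
        devs = [devs]
    devs = devs[:2]
    first = devs[0]
    i0 = max(0, int(round(first.t_start_s / dt_s)) - int(round(30.0 / dt_s)))
    i1 = min(cbv.size, int(round(devs[-1].t_end_s / dt_s)) + 2)
    if i1 - i0 < 5:
        return first.onset_s
    t = np.arange(i0, i1) * dt_s
    y = np.asarray(cbv[i0:i1], dtype=float)
    span = float(t[-1] - t[0])
    x0, lo, hi = [], [], []
    for d in devs:
        amp0 = d.peak_pct  # signed
        fwhm0 = float(np.clip(d.t_end_s - d.t_start_s, rise_s, span))
        x0 += [np.clip(d.onset_s, d.t_start_s - 60.0, d.t_start_s + 45.0), amp0, fwhm0]
        lo += [d.t_start_s - 60.0, min(amp0 * 0.2, amp0 * 3.0), rise_s * 0.6]
        hi += [d.t_start_s + 45.0, max(amp0 * 0.2, amp0 * 3.0), span * 2.0]

    def model(x):
        out = np.zeros_like(y)
        for k in range(len(devs)):
            t0, amp, fwhm = x[3 * k: 3 * k + 3]
            out += component_pulse(t - t0, amp, fwhm, rise_s)
        return out

    # two starts for the leading onset: the edge extrapolation (can be
    # thrown far off by noise on a shallow edge) and the threshold crossing
    best = None
    for t0_init in (x0[0], np.clip(first.t_start_s - rise_s / 2.0, lo[0], hi[0])):
        try:
            res = optimize.least_squares(
                lambda x: model(x) - y, [t0_init] + x0[1:],
                bounds=(lo, hi), max_nfev=120)
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return first.onset_s
    t0 = float(best.x[0])
    if abs(t0 - first.t_start_s) > 60.0:
        return first.onset_s
    return t0


def _merge_into_responses(
    deviations: list[Deviation], merge_gap_s: float
) -> list[list[Deviation]]:
    """Cluster a ROI's segments into responses: one SD produces a train of
    adjacent segments; distinct SDs are separated by tens of minutes."""
    responses: list[list[Deviation]] = []
    for dev in deviations:
        if responses and dev.t_start_s - responses[-1][-1].t_end_s <= merge_gap_s:
            responses[-1].append(dev)
        else:
            responses.append([dev])
    return responses


def group_sd_ios(
    traceset: ROITraceSet,
    layout: CorticalLayout,
    config: OpticalConfig | None = None,
    exclude_mask: np.ndarray | None = None,
) -> tuple[list[SDEvent], dict[tuple[str, str], ResponseWindow]]:
    """Full IOS detection: per-ROI deviations -> >= 2-ROI propagation groups.

    Returns the detected events plus, for every (event id, roi id), the
    response window to hand to :func:`decompose_components`.
    ``exclude_mask`` (per-sample True = excluded) applies motion-QC flags.
    """
    cfg = config or OpticalConfig()
    dt = traceset.sampling_interval_s
    occ = traceset.occlusion_time_s
    n_pre = int(occ / dt)
    roi_candidates: list[SensorCandidate] = []
    for i, roi in enumerate(traceset.roi_ids):
        trace = traceset.signals["intensity"][i]
        mask = np.zeros(trace.size, dtype=bool)
        mask[:n_pre] = True
        if exclude_mask is not None:
            mask &= ~exclude_mask
        i0, sigma_i = establish_baseline(trace, mask, dt, cfg.min_baseline_s)
        cbv = to_cbv(trace, i0)
        sigma = sigma_i / i0 * 100.0  # robust noise scale on the percent axis
        devs = detect_deviations(cbv, sigma, dt, cfg.k_sigma, cfg.min_len_s)
        if exclude_mask is not None:
            devs = [d for d in devs
                    if not exclude_mask[int(d.t_start_s / dt):int(d.t_end_s / dt) + 1].any()]
        for response in _merge_into_responses(devs, cfg.merge_gap_s):
            onset_post = refine_onset(cbv, dt, response, cfg.rise_s) - occ
            hemi, pos = layout.rois_ios[roi]
            roi_candidates.append(SensorCandidate(
                sensor_id=roi, onset_s=onset_post, hemisphere=hemi, position_mm=pos,
                payload=ResponseWindow(
                    roi_id=roi, onset_s=onset_post,
                    t0_s=response[0].t_start_s - occ - cfg.pad_s,
                    t1_s=response[-1].t_end_s - occ + cfg.pad_s,
                    baseline=i0, sigma_pct=sigma, deviations=response,
                ),
            ))
    groups, _orphans = group_candidates(roi_candidates, cfg.speed_band_mm_per_min, 2)
    events: list[SDEvent] = []
    windows: dict[tuple[str, str], ResponseWindow] = {}
    for k, group in enumerate(groups):
        hemi = group[0].hemisphere
        onsets = {m.sensor_id: m.onset_s for m in group}
        event_id = f"{traceset.animal_id}-ios-det{k + 1}"
        events.append(SDEvent(
            event_id=event_id, modality="ios", animal_id=traceset.animal_id,
            hemisphere=hemi, onsets_s=onsets,
            expansion_pct=expansion(onsets, layout, hemi, cfg.scope, "ios"),
            summary_amplitude=float(np.mean(
                [max((d.peak_pct for d in m.payload.deviations), key=abs) for m in group])),
        ))
        for m in group:
            windows[(event_id, m.sensor_id)] = m.payload
    return events, windows


# ---------------------------------------------------------------------------
# decomposition and classification
# ---------------------------------------------------------------------------


def _label_extrema(
    peaks: list[tuple[float, float]], troughs: list[tuple[float, float]],
    t_end: float,
) -> list[tuple[str, float, float]]:
    """Apply the ordered extremum rules: largest positive peak is III; a
    positive peak before any trough and before III is I; a trough before III
    is II; a positive peak after III is IV; a terminal trough is V."""
    if not peaks:
        if not troughs:
            return []
        # no hyperemic peak at all: keep the deepest trough as hypoperfusion
        t, v = min(troughs, key=lambda tv: tv[1])
        return [("II", t, v)]
    t_iii, v_iii = max(peaks, key=lambda tv: tv[1])
    labeled = [("III", t_iii, v_iii)]
    troughs_before = [tv for tv in troughs if tv[0] < t_iii]
    if troughs_before:
        t_ii, v_ii = min(troughs_before, key=lambda tv: tv[1])
        labeled.append(("II", t_ii, v_ii))
        first_trough_t = min(tv[0] for tv in troughs_before)
        peaks_i = [tv for tv in peaks if tv[0] < first_trough_t]
    else:
        peaks_i = []
    if peaks_i:
        labeled.append(("I",) + max(peaks_i, key=lambda tv: tv[1]))
    peaks_after = [tv for tv in peaks if tv[0] > t_iii]
    if peaks_after:
        labeled.append(("IV",) + max(peaks_after, key=lambda tv: tv[1]))
    t_iv = labeled[-1][1] if peaks_after else t_iii
    terminal = [tv for tv in troughs if tv[0] > t_iv and tv[0] > t_end - 0.25 * (t_end - t_iii)]
    if terminal:
        labeled.append(("V",) + min(terminal, key=lambda tv: tv[1]))
    labeled.sort(key=lambda x: x[1])
    return labeled


def decompose_components(
    cbv: np.ndarray,
    dt_s: float,
    window: tuple[float, float],
    sigma_pct: float,
    config: OpticalConfig | None = None,
    t_offset_s: float = 0.0,
) -> list[Component]:
    """Decompose one response window into labeled vasomotor components.

    Local extrema of the smoothed CBV trace exceeding the deviation
    threshold are labeled by the ordered rules above, then (optionally) a
    sum of rise/decay pulses is least-squares fitted with the kinds held
    fixed, so each component carries its *own* peak amplitude and
    half-maximum duration even when pulses overlap (e.g. a late hyperemia
    superimposed on the peak). Times are reported on the caller's post-
    occlusion axis via ``t_offset_s``.
    """
    cfg = config or OpticalConfig()
    t = np.arange(cbv.size) * dt_s
    i0 = max(0, int(round((window[0] - t_offset_s) / dt_s)))
    i1 = min(cbv.size, int(round((window[1] - t_offset_s) / dt_s)) + 1)
    seg, t_seg = np.asarray(cbv[i0:i1], float), t[i0:i1] + t_offset_s
    if seg.size < 5:
        return []
    n_smooth = max(1, int(round(cfg.smooth_s / dt_s)))
    smooth = np.convolve(seg, np.ones(n_smooth) / n_smooth, mode="same")
    height = cfg.k_sigma * sigma_pct
    # prominence scales with the response size so noise wiggles riding on a
    # large, broad peak cannot masquerade as secondary components
    prominence = max(2.0 * sigma_pct, 0.05 * float(np.max(np.abs(smooth))))
    distance = max(1, int(round(cfg.peak_separation_s / dt_s)))
    peaks_i, _ = sps.find_peaks(smooth, height=height, prominence=prominence,
                                distance=distance)
    troughs_i, _ = sps.find_peaks(-smooth, height=height, prominence=prominence,
                                  distance=distance)
    peaks = [(float(t_seg[i]), float(smooth[i])) for i in peaks_i]
    troughs = [(float(t_seg[i]), float(smooth[i])) for i in troughs_i]
    # a supra-threshold plateau with no interior extremum (single-component
    # response): fall back to the global extremum of the segment
    if not peaks and smooth.max() >= height:
        i = int(np.argmax(smooth))
        peaks = [(float(t_seg[i]), float(smooth[i]))]
    if not troughs and smooth.min() <= -height:
        i = int(np.argmin(smooth))
        troughs = [(float(t_seg[i]), float(smooth[i]))]
    labeled = _label_extrema(peaks, troughs, float(t_seg[-1]))
    if not labeled:
        return []

    components = [
        Component(
            kind=kind,
            onset_s=peak_t - cfg.rise_s,
            peak_amplitude_pct=value,
            duration_min=_half_max_width(t_seg, smooth, peak_t, value) / 60.0,
            peak_time_s=peak_t,
        )
        for kind, peak_t, value in labeled
    ]
    if cfg.refine_fit:
        components = _refine_fit(seg, t_seg, components, cfg.rise_s)
        # drop phantom components the joint fit reduced below the deviation
        # threshold (noise bumps on a long decay mislabeled as extrema)
        kept = [c for c in components if abs(c.peak_amplitude_pct) >= height]
        if len(kept) != len(components) and kept:
            components = _refine_fit(seg, t_seg, kept, cfg.rise_s)
    components.sort(key=lambda c: c.onset_s)
    return components


def _half_max_width(t: np.ndarray, y: np.ndarray, peak_t: float, value: float) -> float:
    """Crude half-maximum width of one extremum on the raw trace (fit seed)."""
    sign = 1.0 if value >= 0 else -1.0
    above = sign * y >= sign * value / 2.0
    i_peak = int(np.argmin(np.abs(t - peak_t)))
    j0 = i_peak
    while j0 > 0 and above[j0 - 1]:
        j0 -= 1
    j1 = i_peak
    while j1 < y.size - 1 and above[j1 + 1]:
        j1 += 1
    return float(t[j1] - t[j0]) if j1 > j0 else float(t[1] - t[0])


def _refine_fit(
    seg: np.ndarray, t_seg: np.ndarray, components: list[Component], rise_s: float
) -> list[Component]:
    """Joint least-squares fit of a pulse per component plus a constant
    offset; kinds and signs stay fixed, (onset, amplitude, FWHM) are free."""
    n = len(components)
    x0, lo, hi = [0.0], [-10.0], [10.0]  # baseline offset, percent
    span = float(t_seg[-1] - t_seg[0])
    for c in components:
        amp = c.peak_amplitude_pct
        fwhm = max(c.duration_min * 60.0, rise_s)
        x0 += [c.onset_s, amp, fwhm]
        lo += [c.onset_s - 120.0, 0.0 if amp >= 0 else -80.0, rise_s * 0.6]
        hi += [c.onset_s + 120.0, 80.0 if amp >= 0 else 0.0, span]

    def model(x: np.ndarray) -> np.ndarray:
        out = np.full_like(seg, x[0])
        for k in range(n):
            t0, amp, fwhm = x[1 + 3 * k: 4 + 3 * k]
            out += component_pulse(t_seg - t0, amp, fwhm, rise_s)
        return out

    try:
        res = optimize.least_squares(
            lambda x: model(x) - seg, x0, bounds=(lo, hi), max_nfev=400)
    except ValueError:
        return components
    fitted = []
    for k, c in enumerate(components):
        t0, amp, fwhm = res.x[1 + 3 * k: 4 + 3 * k]
        fitted.append(Component(
            kind=c.kind, onset_s=float(t0), peak_amplitude_pct=float(amp),
            duration_min=float(fwhm) / 60.0, peak_time_s=float(t0 + rise_s),
        ))
    return fitted


def classify_morphology(components: list[Component] | list[str]) -> str:
    """Four-class morphology from the exact component-kind sequence.

    [III] monophasic; [III, IV] biphasic; [II, III, IV] triphasic;
    [I, II, III, IV] tetraphasic; anything else "other". Classification is a
    pure function of the kind sequence; an empty list is a caller error
    (sub-threshold responses must not be classified).
    """
    if not components:
        raise ValueError("cannot classify an empty component list")
    kinds = tuple(c.kind if isinstance(c, Component) else str(c) for c in components)
    return _MORPHOLOGY_TABLE.get(kinds, "other")


def hyperemia_metrics(response: HemodynamicResponse) -> tuple[float, float]:
    """(amplitude % of baseline, half-maximum duration in min) of the peak
    hyperemia, measured on component III's own fitted pulse so a
    superimposed late hyperemia does not inflate the duration."""
    c3 = response.component("III")
    if c3 is None:
        raise ValueError("response has no peak-hyperemia component")
    return c3.peak_amplitude_pct, c3.duration_min


def analyze_responses(
    traceset: ROITraceSet,
    events: list[SDEvent],
    windows: dict[tuple[str, str], ResponseWindow],
    config: OpticalConfig | None = None,
) -> list[HemodynamicResponse]:
    """Decompose and classify every (event, ROI) response of a trace set."""
    cfg = config or OpticalConfig()
    occ = traceset.occlusion_time_s
    out: list[HemodynamicResponse] = []
    for event in events:
        for roi in event.onsets_s:
            win = windows[(event.event_id, roi)]
            trace = traceset.trace(roi)
            cbv = to_cbv(trace, win.baseline)
            comps = decompose_components(
                cbv, traceset.sampling_interval_s, (win.t0_s, win.t1_s),
                win.sigma_pct, cfg, t_offset_s=-occ)
            if not comps:
                continue  # sub-threshold at this ROI after refinement
            out.append(HemodynamicResponse(
                roi_id=roi, event_id=event.event_id, animal_id=traceset.animal_id,
                hemisphere=event.hemisphere, components=comps,
                morphology=classify_morphology(comps),
                baseline_value=win.baseline, noise_sigma=win.sigma_pct,
                event_onset_s=event.onset_s,
            ))
    return out


def motion_qc(
    source: np.ndarray | ROITraceSet,
    threshold: float = 8.0,
    dilate_s: float = 10.0,
) -> np.ndarray:
    """Flag frames/samples contaminated by bulk motion.

    For an image stack (frames x H x W): the frame-to-frame global absolute
    intensity shift, robustly z-scored; for a trace set: the median absolute
    first difference across ROIs, robustly z-scored. Samples whose score
    exceeds ``threshold`` (plus a short dilation) are flagged True =
    exclude; detection skips flagged intervals.
    """
    if isinstance(source, ROITraceSet):
        diffs = np.abs(np.diff(source.signals["intensity"], axis=1))
        score = np.median(diffs, axis=0)
        dt = source.sampling_interval_s
    else:
        frames = np.asarray(source, dtype=float)
        score = np.abs(np.diff(frames, axis=0)).mean(axis=(1, 2))
        dt = 1.0
    med = np.median(score)
    mad = 1.4826 * np.median(np.abs(score - med)) + 1e-12
    z = (score - med) / mad
    flagged = np.concatenate([[False], z > threshold])
    if flagged.any():
        n_dilate = max(1, int(dilate_s / dt))
        kernel = np.ones(2 * n_dilate + 1, dtype=bool)
        flagged = np.convolve(flagged, kernel, mode="same") > 0
    return flagged
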