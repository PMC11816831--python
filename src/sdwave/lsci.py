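"""LSCI pipeline: CBF event detection, percent elevation, oxygenation
coupling and cross-modal (LSCI vs ECoG) chronological matching.

Laser-speckle traces arrive in arbitrary perfusion units (APU), so every
quantity here is a per-animal percentage of baseline; nothing is comparable
across animals in absolute units. The SD signature is a monophasic CBF rise
returning to baseline, with a synchronous OxyHb rise and a slightly lagged
deOxyHb fall. With the instrument's 5 s sampling the detection reuses the
optical deviation -> propagation-grouping path at 0.2 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grouping import SensorCandidate, estimate_onset, group_candidates
from .model import CorticalLayout, PerfusionResponse, ROITraceSet, SDEvent
from .optical import (
    _merge_into_responses, detect_deviations, establish_baseline, refine_onset,
)
from .ecog import expansion

__all__ = [
    "LSCIConfig", "percent_elevation", "detect_sd_lsci", "oxy_coupling",
    "match_modalities",
]


@dataclass
class LSCIConfig:
    k_sigma: float = 3.0
    min_len_s: float = 20.0
    merge_gap_s: float = 420.0
    pad_s: float = 60.0
    smooth_samples: int = 3
    speed_band_mm_per_min: tuple[float, float] = (1.0, 10.0)
    min_baseline_s: float = 300.0
    match_window_min: float = 5.0


def percent_elevation(
    cbf: np.ndarray,
    baseline_mask: np.ndarray,
    dt_s: float = 5.0,
    smooth_samples: int = 3,
) -> tuple[float, bool]:
    """Percent CBF elevation over baseline: ``100 * (peak - base) / base``.

    ``baseline_mask`` selects the pre-event samples (at least 3 required).
    The peak is taken on a lightly smoothed trace outside the baseline
    window. Also reports whether the trace returns to baseline (re-enters
    +-2 sigma of the baseline after the peak).
    """
    cbf = np.asarray(cbf, dtype=float)
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    if baseline_mask.sum() < 3:
        raise ValueError("need at least 3 baseline samples")
    base = float(np.median(cbf[baseline_mask]))
    if base <= 0:
        raise ValueError("CBF baseline must be positive")
    sigma = 1.4826 * float(np.median(np.abs(cbf[baseline_mask] - base)))
    kernel = np.ones(smooth_samples) / smooth_samples
    smooth = np.convolve(cbf, kernel, mode="same")
    search = ~baseline_mask
    if not search.any():
        return 0.0, True
    idx = np.flatnonzero(search)
    i_peak = idx[int(np.argmax(smooth[idx]))]
    peak = float(smooth[i_peak])
    elevation = 100.0 * (peak - base) / base
    tail = smooth[i_peak:]
    returns = bool(np.any(np.abs(tail - base) <= 2.0 * max(sigma, 1e-12)))
    return elevation, returns


def detect_sd_lsci(
    traceset: ROITraceSet,
    layout: CorticalLayout,
    config: LSCIConfig | None = None,
) -> tuple[list[SDEvent], list[PerfusionResponse]]:
    """Detect SDs in the CBF traces and characterize each ROI's passage.

    Events reuse the deviation -> plausibility-band grouping (>= 2 ROIs);
    each event carries its ROI onset ordering (the propagation direction)
    and a :class:`PerfusionResponse` per reached ROI with percent elevation
    and oxygenation coupling.
    """
    cfg = config or LSCIConfig()
    dt = traceset.sampling_interval_s
    occ = traceset.occlusion_time_s
    n_pre = int(occ / dt)
    candidates: list[SensorCandidate] = []
    for i, roi in enumerate(traceset.roi_ids):
        cbf = traceset.signals["CBF"][i]
        mask = np.zeros(cbf.size, dtype=bool)
        mask[:n_pre] = True
        base, sigma_apu = establish_baseline(cbf, mask, dt, cfg.min_baseline_s)
        pct = 100.0 * (cbf - base) / base
        sigma = sigma_apu / base * 100.0
        devs = detect_deviations(pct, sigma, dt, cfg.k_sigma, cfg.min_len_s)
        hemi, pos = layout.rois_lsci[roi]
        for response in _merge_into_responses(devs, cfg.merge_gap_s):
            onset = refine_onset(pct, dt, response)
            candidates.append(SensorCandidate(
                sensor_id=roi, onset_s=onset - occ,
                hemisphere=hemi, position_mm=pos,
                payload=(i, base, sigma, response),
            ))
    groups, _ = group_candidates(candidates, cfg.speed_band_mm_per_min, 2)
    events: list[SDEvent] = []
    responses: list[PerfusionResponse] = []
    for k, group in enumerate(groups):
        hemi = group[0].hemisphere
        onsets = {m.sensor_id: m.onset_s for m in group}
        event_id = f"{traceset.animal_id}-lsci-det{k + 1}"
        elevations = []
        for m in group:
            i, base, sigma, devs = m.payload
            cbf = traceset.signals["CBF"][i]
            t0 = devs[0].t_start_s - cfg.pad_s
            t1 = devs[-1].t_end_s + cfg.pad_s
            window = (np.arange(cbf.size) * dt >= t0) & (np.arange(cbf.size) * dt <= t1)
            baseline_mask = np.zeros(cbf.size, dtype=bool)
            baseline_mask[:n_pre] = True
            # restrict the peak search to this event's window
            local = np.where(window, cbf, base)
            elev, returns = percent_elevation(local, baseline_mask, dt, cfg.smooth_samples)
            # count vasomotor phases: same-polarity segments separated by a
            # short threshold-hover gap are one phase, not two
            phases = 1
            for prev, nxt in zip(devs, devs[1:]):
                if nxt.polarity != prev.polarity or nxt.t_start_s - prev.t_end_s > 120.0:
                    phases += 1
            pattern = "monophasic" if (
                returns and all(d.polarity > 0 for d in devs) and phases == 1
            ) else "other"
            oxy_sign, deoxy_sign, lag, lowconf = oxy_coupling(
                traceset, m.sensor_id, (t0, t1), cfg)
            responses.append(PerfusionResponse(
                roi_id=m.sensor_id, cbf_baseline_apu=base,
                cbf_peak_apu=base * (1 + elev / 100.0), percent_elevation=elev,
                oxy_sign=oxy_sign, deoxy_sign=deoxy_sign, deoxy_lag_s=lag,
                onset_s=m.onset_s, pattern=pattern, returns_to_baseline=returns,
                low_confidence=lowconf,
            ))
            elevations.append(elev)
        events.append(SDEvent(
            event_id=event_id, modality="lsci", animal_id=traceset.animal_id,
            hemisphere=hemi, onsets_s=onsets,
            expansion_pct=expansion(onsets, layout, hemi, "hemisphere", "lsci"),
            summary_amplitude=float(np.mean(elevations)),
        ))
    return events, responses


def oxy_coupling(
    traceset: ROITraceSet,
    roi_id: str,
    window_s: tuple[float, float],
    config: LSCIConfig | None = None,
) -> tuple[int, int, float, bool]:
    """Oxygenation co-variation in an event window.

    Returns (OxyHb peak-delta sign, deOxyHb peak-delta sign, deOxyHb onset
    lag in s relative to the CBF onset, low-confidence flag). Signs are the
    signs of the largest baseline deviation inside the window; the flag is
    set when neither trace deviates beyond 3 sigma (uncorrelated noise).
    """
    cfg = config or LSCIConfig()
    dt = traceset.sampling_interval_s
    occ = traceset.occlusion_time_s
    n_pre = int(occ / dt)
    t = traceset.times_s()
    in_win = (t >= window_s[0]) & (t <= window_s[1])
    out: dict[str, tuple[int, float, float]] = {}
    for name in ("CBF", "OxyHb", "deOxyHb"):
        x = traceset.signals[name][traceset.roi_index(roi_id)]
        base = float(np.median(x[:n_pre]))
        sigma = 1.4826 * float(np.median(np.abs(x[:n_pre] - base))) + 1e-12
        delta = x[in_win] - base
        i_ext = int(np.argmax(np.abs(delta)))
        sign = int(np.sign(delta[i_ext])) or 1
        z = abs(delta[i_ext]) / sigma
        y = sign * (x - base)
        i_peak = int(np.flatnonzero(in_win)[i_ext])
        onset = estimate_onset(t, y, i_peak)
        out[name] = (sign, z, onset)
    low_confidence = out["OxyHb"][1] < 3.0 or out["deOxyHb"][1] < 3.0
    lag = out["deOxyHb"][2] - out["CBF"][2]
    return out["OxyHb"][0], out["deOxyHb"][0], float(lag), low_confidence


def match_modalities(
    lsci_events: list[SDEvent],
    ecog_events: list[SDEvent],
    window_min: float = 5.0,
) -> list[tuple[SDEvent, SDEvent]]:
    """Chronologically match LSCI and ECoG detections of the same SDs.

    Greedy nearest-onset pairing within ``+-window_min``; each event is used
    at most once. The pairing is symmetric in its arguments (pairs are
    ranked by absolute onset difference, not by argument order).
    """
    pairs = sorted(
        ((abs(a.onset_s - b.onset_s), i, j)
         for i, a in enumerate(lsci_events) for j, b in enumerate(ecog_events)),
        key=lambda x: x[0],
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for delta, i, j in pairs:
        if delta > window_min * 60.0 or i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((lsci_events[i], ecog_events[j]))
    matched.sort(key=lambda pair: pair[0].onset_s)
    return matched
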