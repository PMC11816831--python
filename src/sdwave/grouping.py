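"""Shared detection primitives: run extraction, onset estimation and the
propagation-plausibility grouping used by all three modalities.

An SD travels at mm/min speeds, so per-sensor detections belong to one wave
only when their pairwise onset lags are consistent with such a speed given
the metric sensor distances. Grouping is greedy in onset order (event
density after occlusion is low, a handful per hour at most), never crosses
the midline, uses each sensor at most once per event, and demands at least
two sensors per event; leftovers are reported as orphans rather than
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

__all__ = ["SensorCandidate", "group_candidates", "estimate_onset", "runs_above"]


@dataclass
class SensorCandidate:
    """One per-sensor detection awaiting propagation grouping."""

    sensor_id: str
    onset_s: float
    hemisphere: str
    position_mm: tuple[float, float]
    payload: Any = None


def runs_above(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Contiguous True runs of at least ``min_len`` samples, as [start, stop)."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    return [(int(a), int(b)) for a, b in zip(starts, stops) if b - a >= min_len]


def estimate_onset(
    t: np.ndarray,
    y: np.ndarray,
    i_peak: int,
    frac_lo: float = 0.2,
    frac_hi: float = 0.8,
) -> float:
    """Onset of a positive-going deflection by leading-edge extrapolation.

    Walks back from the peak to the sub-``frac_lo`` baseline, fits a line to
    the 20-80 % leading edge and extrapolates it to zero. For deflections
    with a roughly linear front this recovers the true foot to sub-sample
    precision; the fallback is the last sub-threshold sample.
    """
    peak = y[i_peak]
    j = i_peak
    while j > 0 and y[j] > frac_lo * peak:
        j -= 1
    # leading edge only: stop at the first crossing of the upper fraction so
    # post-peak samples that fall back into the band cannot flatten the fit
    k = j
    while k < i_peak and y[k] < frac_hi * peak:
        k += 1
    edge = slice(j, k + 1)
    ys, ts = y[edge], t[edge]
    sel = (ys >= frac_lo * peak) & (ys <= frac_hi * peak)
    if sel.sum() >= 2:
        slope, intercept = np.polyfit(ts[sel], ys[sel], 1)
        if slope > 0:
            return float(-intercept / slope)
    return float(t[j])


def group_candidates(
    candidates: list[SensorCandidate],
    speed_band_mm_per_min: tuple[float, float] = (1.0, 10.0),
    min_sensors: int = 2,
) -> tuple[list[list[SensorCandidate]], list[SensorCandidate]]:
    """Greedily merge per-sensor candidates into propagating events.

    A candidate joins an event only if, against *every* current member, the
    implied propagation speed ``distance / lag`` lies inside the band, the
    hemisphere matches (SDs do not cross the midline barrier) and its sensor
    is not already used. Ties are broken by earliest onset because
    candidates are scanned in onset order.
    """
    v_lo, v_hi = speed_band_mm_per_min
    ordered = sorted(candidates, key=lambda c: (c.onset_s, c.sensor_id))
    assigned = [False] * len(ordered)
    groups: list[list[SensorCandidate]] = []
    for i, seed in enumerate(ordered):
        if assigned[i]:
            continue
        group = [seed]
        assigned[i] = True
        for j in range(i + 1, len(ordered)):
            if assigned[j]:
                continue
            cand = ordered[j]
            if cand.hemisphere != seed.hemisphere:
                continue
            if any(cand.sensor_id == m.sensor_id for m in group):
                continue
            if all(_plausible(cand, m, v_lo, v_hi) for m in group):
                group.append(cand)
                assigned[j] = True
        groups.append(group)
    events = [g for g in groups if len(g) >= min_sensors]
    orphans = [c for g in groups if len(g) < min_sensors for c in g]
    return events, orphans


def _plausible(a: SensorCandidate, b: SensorCandidate, v_lo: float, v_hi: float) -> bool:
    dist = float(np.hypot(a.position_mm[0] - b.position_mm[0],
                          a.position_mm[1] - b.position_mm[1]))
    lag = abs(a.onset_s - b.onset_s)
    if lag == 0.0:
        return False  # simultaneous arrival at distinct sensors: implausibly fast
    speed = dist / lag * 60.0
    return v_lo <= speed <= v_hi
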