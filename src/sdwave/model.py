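"""Core data model shared by all pipeline stages.

Conventions
-----------
* Time is measured in seconds from the start of the recording; the occlusion
  timestamp is carried in the metadata and event times are reported in
  seconds *post-occlusion* (the literature reports "min post-occlusion").
* Sensor coordinates are millimetres in a right-handed craniotomy plane with
  the midline at ``x = 0``; the occlusion site sits on the midline.
* Optical intensity follows the total-hemoglobin (CBV surrogate) sign
  convention: an intensity *decrease* means more hemoglobin, i.e. hyperemia.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Hemisphere",
    "CorticalLayout",
    "TimeSeriesRecording",
    "ROITraceSet",
    "SDEvent",
    "SPCCandidate",
    "ComponentSpec",
    "SDTemplate",
    "HemodynamicResponse",
    "Component",
    "PerfusionResponse",
    "COMPONENT_KINDS",
    "MORPHOLOGIES",
]

Hemisphere = str  # "left" | "right"

#: Canonical vasomotor component kinds, in their physiological order:
#: I  brief initial hyperemia, II initial hypoperfusion, III peak hyperemia,
#: IV late hyperemia, V post-SD oligemia.
COMPONENT_KINDS = ("I", "II", "III", "IV", "V")

#: Hyperemic kinds carry positive CBV amplitudes, hypoperfusive ones negative.
KIND_SIGN = {"I": +1, "II": -1, "III": +1, "IV": +1, "V": -1}

MORPHOLOGIES = ("monophasic", "biphasic", "triphasic", "tetraphasic", "other")


def _check_finite(a: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(a)):
        bad = np.argwhere(~np.isfinite(np.asarray(a)))
        raise ValueError(f"{what} contains NaN/Inf (first offence at index {tuple(bad[0])})")


@dataclass
class CorticalLayout:
    """Sensor geometry of the craniotomy field.

    ``contacts`` maps ECoG channel ids to (hemisphere, (x, y) mm); ``rois_ios``
    and ``rois_lsci`` do the same for optical / speckle ROIs. The occlusion
    site lies on the midline (x = 0 by convention).
    """

    contacts: dict[str, tuple[Hemisphere, tuple[float, float]]]
    rois_ios: dict[str, tuple[Hemisphere, tuple[float, float]]]
    rois_lsci: dict[str, tuple[Hemisphere, tuple[float, float]]]
    occlusion_site: tuple[float, float] = (0.0, 0.0)
    contact_spacing_mm: float = 10.0

    def __post_init__(self) -> None:
        for name, sensors in (("contacts", self.contacts),
                              ("rois_ios", self.rois_ios),
                              ("rois_lsci", self.rois_lsci)):
            for sid, (hemi, pos) in sensors.items():
                if hemi not in ("left", "right"):
                    raise ValueError(f"{name}[{sid}]: unknown hemisphere {hemi!r}")
                if not np.all(np.isfinite(pos)):
                    raise ValueError(f"{name}[{sid}]: non-finite position {pos}")
        if abs(self.occlusion_site[0]) > 1e-9:
            raise ValueError("occlusion site must sit on the midline (x = 0)")
        if self.contact_spacing_mm <= 0:
            raise ValueError("contact_spacing_mm must be positive")
        n_left = sum(h == "left" for h, _ in self.rois_ios.values())
        n_right = sum(h == "right" for h, _ in self.rois_ios.values())
        if self.rois_ios and n_left != n_right:
            raise ValueError("IOS ROIs must be placed symmetrically (equal left/right counts)")

    def sensors(self, modality: str) -> dict[str, tuple[Hemisphere, tuple[float, float]]]:
        return {"ecog": self.contacts, "ios": self.rois_ios, "lsci": self.rois_lsci}[modality]

    def hemisphere_size(self, modality: str, hemisphere: Hemisphere) -> int:
        return sum(h == hemisphere for h, _ in self.sensors(modality).values())


@dataclass
class TimeSeriesRecording:
    """Multichannel DC-coupled ECoG recording.

    ``data`` is (n_channels, n_samples) in mV; channel geometry mirrors the
    layout so that propagation grouping can compute metric distances.
    """

    channel_ids: list[str]
    hemispheres: list[Hemisphere]
    positions_mm: np.ndarray  # (n_channels, 2)
    sampling_rate: float  # Hz, 1000 for the physical amplifier setup
    data: np.ndarray  # (n_channels, n_samples), mV
    occlusion_time_s: float
    animal_id: str = "animal"

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n = len(self.channel_ids)
        if self.data.shape[0] != n or len(self.hemispheres) != n or self.positions_mm.shape != (n, 2):
            raise ValueError("channel metadata and data shapes disagree")
        _check_finite(self.data, f"ECoG data ({self.animal_id})")
        if not 0 <= self.occlusion_time_s <= self.duration_s:
            raise ValueError("occlusion time outside the recorded span")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.sampling_rate

    @property
    def monitored_post_occlusion_h(self) -> float:
        return (self.duration_s - self.occlusion_time_s) / 3600.0

    def channel_index(self, channel_id: str) -> int:
        return self.channel_ids.index(channel_id)


@dataclass
class ROITraceSet:
    """Per-ROI optical time series.

    IOS carries a single ``intensity`` signal (arbitrary units, CBV surrogate);
    LSCI carries the ``CBF`` / ``OxyHb`` / ``deOxyHb`` triplet in arbitrary
    perfusion units (APU). Sampling is uniform: 1 s frames for IOS, 5 s for
    the speckle instrument.
    """

    roi_ids: list[str]
    hemispheres: list[Hemisphere]
    positions_mm: np.ndarray  # (n_rois, 2)
    modality: str  # "IOS" | "LSCI"
    signals: dict[str, np.ndarray]  # name -> (n_rois, n_samples)
    sampling_interval_s: float
    occlusion_time_s: float
    animal_id: str = "animal"
    baseline_values: np.ndarray | None = None  # nominal per-ROI baseline (generator bookkeeping)

    def __post_init__(self) -> None:
        if self.modality not in ("IOS", "LSCI"):
            raise ValueError(f"unknown modality {self.modality!r}")
        expected = {"IOS": {"intensity"}, "LSCI": {"CBF", "OxyHb", "deOxyHb"}}[self.modality]
        if set(self.signals) != expected:
            raise ValueError(f"{self.modality} trace set must carry signals {sorted(expected)}")
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        n = len(self.roi_ids)
        if self.modality == "IOS" and n < 2:
            raise ValueError("IOS analysis requires at least two ROIs")
        lengths = set()
        for name in self.signals:
            self.signals[name] = np.atleast_2d(np.asarray(self.signals[name], dtype=float))
            if self.signals[name].shape[0] != n:
                raise ValueError(f"signal {name!r} row count != number of ROIs")
            _check_finite(self.signals[name], f"{self.modality} signal {name!r} ({self.animal_id})")
            lengths.add(self.signals[name].shape[1])
        if len(lengths) != 1:
            raise ValueError("all signals must share one uniform sampling grid")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling interval must be positive")
        if self.modality == "LSCI" and np.any(self.signals["CBF"] < 0):
            raise ValueError("negative CBF values are not physical")

    @property
    def n_samples(self) -> int:
        return next(iter(self.signals.values())).shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.sampling_interval_s

    @property
    def monitored_post_occlusion_h(self) -> float:
        return (self.duration_s - self.occlusion_time_s) / 3600.0

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sampling_interval_s

    def roi_index(self, roi_id: str) -> int:
        return self.roi_ids.index(roi_id)

    def trace(self, roi_id: str, signal: str | None = None) -> np.ndarray:
        if signal is None:
            signal = "intensity" if self.modality == "IOS" else "CBF"
        return self.signals[signal][self.roi_index(roi_id)]


@dataclass
class SDEvent:
    """One detected spreading depolarization.

    ``onsets_s`` maps each reached sensor to its onset in seconds
    post-occlusion; sensors that are absent were not reached. The detection
    rule requires at least two sensors.
    """

    event_id: str
    modality: str  # "ecog" | "ios" | "lsci"
    animal_id: str
    hemisphere: Hemisphere
    onsets_s: dict[str, float]
    expansion_pct: float
    summary_amplitude: float = float("nan")
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.onsets_s) < 2:
            raise ValueError("an SD event requires onsets on at least two sensors")

    @property
    def onset_s(self) -> float:
        """Event onset: earliest sensor onset (s post-occlusion)."""
        return min(self.onsets_s.values())

    @property
    def onset_min(self) -> float:
        return self.onset_s / 60.0

    @property
    def n_sensors(self) -> int:
        return len(self.onsets_s)

    def propagation_order(self) -> list[str]:
        return sorted(self.onsets_s, key=self.onsets_s.get)


@dataclass
class SPCCandidate:
    """A per-channel slow-potential-change candidate (pre-grouping)."""

    channel_id: str
    onset_s: float  # s post-occlusion
    amplitude_mV: float  # trough depth, positive number
    duration_s: float
    depression: tuple[float, float, float] | None = None  # (start, end, residual power fraction)
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ComponentSpec:
    """Generator-side description of one vasomotor component pulse."""

    kind: str  # I..V
    peak_amplitude_pct: float  # signed % of baseline, positive = hyperemia
    fwhm_min: float
    lag_min: float = 0.0  # onset lag after local wavefront arrival

    def __post_init__(self) -> None:
        if self.kind not in COMPONENT_KINDS:
            raise ValueError(f"unknown component kind {self.kind!r}")
        if np.sign(self.peak_amplitude_pct) != KIND_SIGN[self.kind] and self.peak_amplitude_pct != 0:
            raise ValueError(
                f"component {self.kind} amplitude must have sign {KIND_SIGN[self.kind]:+d}"
            )
        if self.fwhm_min <= 0:
            raise ValueError("component FWHM must be positive")
        if self.lag_min < 0:
            raise ValueError("component lag must be non-negative")


def validate_component_order(components: list[ComponentSpec]) -> None:
    """Reject component lists that violate the canonical I<II<III<IV<V ordering."""
    order = [COMPONENT_KINDS.index(c.kind) for c in components]
    if order != sorted(order):
        raise ValueError(f"components out of canonical order: {[c.kind for c in components]}")
    lags = [c.lag_min for c in components]
    if lags != sorted(lags):
        raise ValueError("component lags must be non-decreasing in canonical order")


@dataclass
class SDTemplate:
    """Ground-truth description of one injected SD wave.

    The wave is kinematic: it starts at ``origin`` (on/near the midline
    occlusion site) at ``onset_min`` post-occlusion and travels at
    ``speed_mm_per_min``; each sensor's arrival time is exactly
    ``onset + distance(origin, sensor) / speed``. ``reached_sensors`` pins
    which sensors the wavefront reaches (the nearest fraction
    ``target_expansion`` of the hemisphere's sensors).
    """

    event_id: str
    modality: str  # "ecog" | "ios" | "lsci"
    hemisphere: Hemisphere
    origin_mm: tuple[float, float]
    onset_min: float
    speed_mm_per_min: float
    target_expansion: float
    # electrophysiology parameters
    dc_amplitude_mV: float = 5.0
    dc_duration_s: float = 90.0
    depression_fraction: float = 0.2
    depression_duration_min: float = 3.0
    # hemodynamic parameters
    components: list[ComponentSpec] = field(default_factory=list)
    roi_components: dict[str, list[ComponentSpec]] = field(default_factory=dict)
    oxy_gain: float = 0.6
    deoxy_gain: float = 0.4
    deoxy_lag_s: float = 10.0
    speed_band: tuple[float, float] = (1.0, 10.0)

    def __post_init__(self) -> None:
        lo, hi = self.speed_band
        if not lo <= self.speed_mm_per_min <= hi:
            raise ValueError(
                f"speed {self.speed_mm_per_min} mm/min outside plausibility band {self.speed_band}"
            )
        if not 0 < self.target_expansion <= 1:
            raise ValueError("target_expansion must lie in (0, 1]")
        if self.dc_amplitude_mV <= 0 or self.dc_duration_s <= 0:
            raise ValueError("DC deflection depth and duration must be positive")
        if not 0 <= self.depression_fraction <= 1:
            raise ValueError("depression_fraction must lie in [0, 1]")
        validate_component_order(self.components)
        for comps in self.roi_components.values():
            validate_component_order(comps)

    def components_for(self, roi_id: str) -> list[ComponentSpec]:
        return self.roi_components.get(roi_id, self.components)

    def reached_sensors(self, layout: CorticalLayout) -> list[str]:
        """Sensors reached by the wavefront: the nearest ``target_expansion``
        fraction of this hemisphere's sensors, by distance from the origin."""
        sensors = {
            sid: pos
            for sid, (hemi, pos) in layout.sensors(self.modality).items()
            if hemi == self.hemisphere
        }
        n_total = len(sensors)
        n_reached = max(1, int(round(self.target_expansion * n_total)))
        by_distance = sorted(sensors, key=lambda sid: self.distance_to(sensors[sid]))
        return by_distance[:n_reached]

    def distance_to(self, pos_mm: tuple[float, float]) -> float:
        return float(np.hypot(pos_mm[0] - self.origin_mm[0], pos_mm[1] - self.origin_mm[1]))

    def arrival_s(self, pos_mm: tuple[float, float]) -> float:
        """Exact kinematic arrival time (s post-occlusion) at a sensor."""
        return self.onset_min * 60.0 + self.distance_to(pos_mm) / self.speed_mm_per_min * 60.0

    def arrival_times(self, layout: CorticalLayout) -> dict[str, float]:
        sensors = layout.sensors(self.modality)
        return {sid: self.arrival_s(sensors[sid][1]) for sid in self.reached_sensors(layout)}


@dataclass
class Component:
    """One fitted vasomotor component of a hemodynamic response."""

    kind: str
    onset_s: float  # s post-occlusion
    peak_amplitude_pct: float  # CBV-positive convention
    duration_min: float  # width at half maximum of this component's own pulse
    peak_time_s: float = float("nan")


@dataclass
class HemodynamicResponse:
    """Component decomposition of one ROI's response to one SD."""

    roi_id: str
    event_id: str
    animal_id: str
    hemisphere: Hemisphere
    components: list[Component]
    morphology: str
    baseline_value: float
    noise_sigma: float
    event_onset_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"unknown morphology {self.morphology!r}")
        onsets = [c.onset_s for c in self.components]
        if onsets != sorted(onsets):
            raise ValueError("component onsets must be increasing")
        for c in self.components:
            if c.peak_amplitude_pct != 0 and np.sign(c.peak_amplitude_pct) != KIND_SIGN[c.kind]:
                warnings.warn(
                    f"component {c.kind} amplitude sign inconsistent with kind", stacklevel=2
                )

    def component(self, kind: str) -> Component | None:
        for c in self.components:
            if c.kind == kind:
                return c
        return None


@dataclass
class PerfusionResponse:
    """Per-ROI LSCI characterization of one SD passage."""

    roi_id: str
    cbf_baseline_apu: float
    cbf_peak_apu: float
    percent_elevation: float
    oxy_sign: int
    deoxy_sign: int
    deoxy_lag_s: float
    onset_s: float  # s post-occlusion
    pattern: str  # "monophasic" | "other"
    returns_to_baseline: bool = True
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.cbf_baseline_apu <= 0:
            raise ValueError("CBF baseline must be positive")
        expected = 100.0 * (self.cbf_peak_apu - self.cbf_baseline_apu) / self.cbf_baseline_apu
        if abs(expected - self.percent_elevation) > 1e-6:
            raise ValueError("percent_elevation inconsistent with baseline/peak")
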