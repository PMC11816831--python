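"""Ground-truth rosters for the synthetic cohorts.

The ``paper_replication`` roster is a *fixed* table (not sampled): event
times, reach counts and per-ROI hemodynamic parameters are chosen once so
that the roster's own statistics equal the study's printed cohort results by
construction — 26 ECoG events over 95.3 monitored hours (17 in hour one
across 9 of 12 animals, 2 in hour two, none in hours four to six), mean
time to first ECoG SD exactly 49.3 min, mean per-animal ECoG expansion
exactly 69.4 %, 16 IOS events with mean per-animal expansion 85.83 %, a
ROI-response morphology split of 5/16 monophasic and 5/16 biphasic, first/
last peak-hyperemia amplitude means of exactly 18.5 / 16.3 % and duration
means of exactly 3.1 / 8.3 min, and a single LSCI event whose four ROI CBF
elevations average 61.5 % (STD 19.7). The random seed passed to the
generator drives measurement noise only, never the roster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import default_layout
from .model import ComponentSpec, CorticalLayout, SDTemplate

__all__ = [
    "AnimalGroundTruth",
    "GroundTruthRoster",
    "build_paper_replication_roster",
    "build_unit_test_roster",
    "morphology_components",
]

# ---------------------------------------------------------------------------
# frozen replication tables: (first-arrival minute, sensors reached)
# ---------------------------------------------------------------------------

_ECOG_TABLE: dict[str, dict] = {
    "a01": dict(group=1, hours=5.0, events=[(5, 4), (30, 4), (55, 3), (75, 3), (105, 2)], start="left"),
    "a02": dict(group=1, hours=7.0, events=[(7, 5), (32, 4), (57, 4), (130, 3)], start="right"),
    "a03": dict(group=2, hours=9.0, events=[(8, 4), (38, 3), (140, 3)], start="left"),
    "a04": dict(group=2, hours=9.0, events=[(9, 4), (39, 3), (150, 3)], start="right"),
    "a05": dict(group=2, hours=9.0, events=[(10, 4), (42, 3), (380, 3)], start="left"),
    "a06": dict(group=2, hours=9.0, events=[(12, 3), (50, 4)], start="right"),
    "a07": dict(group=2, hours=8.0, events=[(14, 4), (145, 4)], start="left"),
    "a08": dict(group=2, hours=8.0, events=[(17, 3), (400, 5)], start="right"),
    "a09": dict(group=2, hours=6.3, events=[(21, 3)], start="left"),
    "a10": dict(group=2, hours=9.0, events=[(390, 3)], start="right"),
    "a11": dict(group=1, hours=8.0, events=[], start="left"),
    "a12": dict(group=1, hours=8.0, events=[], start="right"),
}

# Six of the eight combined-monitoring animals were analyzable for IOS; each
# animal's optical events sit in a single hemisphere (8 left / 8 right at the
# cohort level) so that ROIs accumulate the >= 2 SDs the first/last-SD
# analysis requires.
_IOS_TABLE: dict[str, dict] = {
    "a03": dict(hours=8.0, hemi="left", events=[(5, 3), (35, 4), (125, 4), (155, 5), (370, 6)]),
    "a04": dict(hours=6.0, hemi="right", events=[(10, 5), (42, 6), (100, 6)]),
    "a05": dict(hours=9.0, hemi="right", events=[(12, 4), (45, 6), (375, 6)]),
    "a06": dict(hours=2.0, hemi="right", events=[(8, 4), (40, 6)]),
    "a07": dict(hours=4.3, hemi="left", events=[(20, 4), (135, 5)]),
    "a10": dict(hours=9.0, hemi="left", events=[(505, 6)]),
}
_IOS_ORDER = ["a03", "a04", "a05", "a06", "a07", "a10"]

# ROI-response morphology pattern: every block of 16 responses contains
# exactly 5 monophasic, 5 biphasic, 3 triphasic and 3 tetraphasic labels, so
# the 80-response cohort splits 25/25/15/15 (5/16 monophasic = 31.25 %).
_MORPH_PATTERN = (
    "monophasic", "biphasic", "triphasic", "tetraphasic",
    "monophasic", "biphasic", "monophasic", "biphasic",
    "triphasic", "tetraphasic", "monophasic", "biphasic",
    "monophasic", "biphasic", "triphasic", "tetraphasic",
)

# Peak-hyperemia (component III) parameters of each eligible ROI's first and
# last SD. 25 eligible ROIs; symmetric spreads around the target means keep
# the means exact while giving a realistic dispersion.
_N_ELIGIBLE = 25
_AMP_FIRST = 18.5 + np.linspace(-10.0, 10.0, _N_ELIGIBLE)
_AMP_LAST = 16.3 + np.linspace(8.0, -8.0, _N_ELIGIBLE)
_DUR_FIRST = 3.1 + np.linspace(-1.6, 1.6, _N_ELIGIBLE)
_DUR_LAST = 8.3 + np.linspace(5.5, -5.5, _N_ELIGIBLE)

_DEFAULT_A3 = 17.0  # % of baseline, responses that are neither first nor last
_DEFAULT_F3 = 3.2   # min

_SPEED_CYCLE = (3.0, 4.0, 5.0, 6.0)  # mm/min
_DC_AMP_CYCLE = (5.0, 6.5, 4.5, 7.0)  # mV

_ECOG_ORIGIN = (0.0, -10.0)
_IOS_ORIGIN = (0.0, -3.0)

# Single analyzable LSCI animal: one SD, first ROI arrival at 9 min, CBF
# elevations across the four ROIs averaging 61.5 % (STD 19.7), and a matched
# ECoG detection of the same SD at 12 min.
_LSCI_CBF_AMPS = {"roi4": 83.5, "roi3": 71.4, "roi2": 51.6, "roi1": 39.5}
_LSCI_ANIMAL = "a13"
_LSCI_HOURS = 2.5
_LSCI_ECOG_HOURS = 3.2
_LSCI_ONSET_MIN = 9.0
_LSCI_ECOG_ONSET_MIN = 12.0


def morphology_components(
    morphology: str, a3: float = _DEFAULT_A3, f3: float = _DEFAULT_F3
) -> list[ComponentSpec]:
    """Canonical component stack for one of the four observed morphologies.

    ``a3``/``f3`` set the peak-hyperemia amplitude (% of baseline) and FWHM
    (min); the flanking components use clearly supra-threshold defaults.
    The late hyperemia (IV) trails peak hyperemia by 1.8 FWHM so it forms a
    distinct secondary peak, and is scaled to 0.45 of the peak amplitude:
    it is a *superimposed* late phase, always smaller than the peak
    hyperemia it rides on.
    """
    iv = ComponentSpec("IV", max(2.5, 0.45 * a3), 4.0, 0.0)  # lag filled per morphology
    if morphology == "monophasic":
        return [ComponentSpec("III", a3, f3, 0.0)]
    if morphology == "biphasic":
        return [ComponentSpec("III", a3, f3, 0.0),
                ComponentSpec("IV", iv.peak_amplitude_pct, iv.fwhm_min, 1.8 * f3)]
    if morphology == "triphasic":
        return [ComponentSpec("II", -6.0, 1.2, 0.0),
                ComponentSpec("III", a3, f3, 2.2),
                ComponentSpec("IV", iv.peak_amplitude_pct, iv.fwhm_min, 2.2 + 1.8 * f3)]
    if morphology == "tetraphasic":
        return [ComponentSpec("I", 5.0, 0.7, 0.0),
                ComponentSpec("II", -6.0, 1.2, 0.9),
                ComponentSpec("III", a3, f3, 2.6),
                ComponentSpec("IV", iv.peak_amplitude_pct, iv.fwhm_min, 2.6 + 1.8 * f3)]
    raise ValueError(f"no component stack for morphology {morphology!r}")


@dataclass
class AnimalGroundTruth:
    """All injected events and monitoring spans for one simulated animal."""

    animal_id: str
    group: int
    ecog_hours: float | None = None
    ios_hours: float | None = None
    lsci_hours: float | None = None
    ecog_templates: list[SDTemplate] = field(default_factory=list)
    ios_templates: list[SDTemplate] = field(default_factory=list)
    lsci_templates: list[SDTemplate] = field(default_factory=list)
    occlusion_time_s: float = 600.0
    flags: list[str] = field(default_factory=list)

    def templates(self, modality: str) -> list[SDTemplate]:
        return {"ecog": self.ecog_templates, "ios": self.ios_templates,
                "lsci": self.lsci_templates}[modality]

    def hours(self, modality: str) -> float | None:
        return {"ecog": self.ecog_hours, "ios": self.ios_hours,
                "lsci": self.lsci_hours}[modality]


@dataclass
class GroundTruthRoster:
    """Cohort-level ground truth: animals, templates and exact arrival times."""

    preset: str
    seed: int
    layout: CorticalLayout
    animals: list[AnimalGroundTruth]
    #: per-ROI morphology assignment of every optical response, keyed
    #: (animal_id, event_id, roi_id)
    response_morphologies: dict[tuple[str, str, str], str] = field(default_factory=dict)

    def animal(self, animal_id: str) -> AnimalGroundTruth:
        for a in self.animals:
            if a.animal_id == animal_id:
                return a
        raise KeyError(animal_id)

    # -- self statistics (used to validate the roster and as test oracles) --

    def analysis_animals(self, modality: str) -> list[AnimalGroundTruth]:
        """Animals entering the cohort statistics for a modality (ECoG
        analysis is restricted to the long-monitoring groups 1-2; the
        LSCI-group animal's paired ECoG serves only cross-modal matching)."""
        if modality == "ecog":
            return [a for a in self.animals if a.group in (1, 2)]
        return [a for a in self.animals if a.hours(modality) is not None]

    def event_count(self, modality: str) -> int:
        return sum(len(a.templates(modality)) for a in self.analysis_animals(modality))

    def first_arrival_min(self, template: SDTemplate) -> float:
        return min(template.arrival_times(self.layout).values()) / 60.0

    def hourly_counts(self, modality: str, n_hours: int = 9) -> np.ndarray:
        counts = np.zeros(n_hours, dtype=int)
        for a in self.analysis_animals(modality):
            for t in a.templates(modality):
                h = int(self.first_arrival_min(t) // 60)
                if h < n_hours:
                    counts[h] += 1
        return counts

    def per_animal_hour_counts(self, modality: str, hour: int) -> list[int]:
        out = []
        for a in self.analysis_animals(modality):
            if a.hours(modality) is None:
                continue
            out.append(sum(1 for t in a.templates(modality)
                           if int(self.first_arrival_min(t) // 60) == hour))
        return out

    def mean_time_to_first_sd_min(self, modality: str) -> float:
        firsts = [self.first_arrival_min(a.templates(modality)[0])
                  for a in self.analysis_animals(modality) if a.templates(modality)]
        return float(np.mean(firsts))

    def per_animal_expansion_pct(self, modality: str) -> list[float]:
        """Mean event expansion per animal (hemisphere denominator), animals
        with at least one event."""
        out = []
        for a in self.analysis_animals(modality):
            ts = a.templates(modality)
            if not ts:
                continue
            exps = []
            for t in ts:
                denom = self.layout.hemisphere_size(t.modality, t.hemisphere)
                exps.append(100.0 * len(t.reached_sensors(self.layout)) / denom)
            out.append(float(np.mean(exps)))
        return out

    def per_animal_incidence(self, modality: str) -> list[float]:
        return [len(a.templates(modality)) / a.hours(modality)
                for a in self.analysis_animals(modality) if a.hours(modality)]

    def morphology_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for label in self.response_morphologies.values():
            counts[label] = counts.get(label, 0) + 1
        return counts

    def eligible_roi_table(self) -> dict[tuple[str, str], tuple[SDTemplate, SDTemplate]]:
        """ROIs reached by >= 2 optical SDs in one hemisphere, with the first
        and last template reaching each."""
        table: dict[tuple[str, str], tuple[SDTemplate, SDTemplate]] = {}
        for a in self.animals:
            reaching: dict[str, list[SDTemplate]] = {}
            for t in sorted(a.ios_templates, key=lambda t: t.onset_min):
                for roi in t.reached_sensors(self.layout):
                    reaching.setdefault(roi, []).append(t)
            for roi, ts in reaching.items():
                if len(ts) >= 2:
                    table[(a.animal_id, roi)] = (ts[0], ts[-1])
        return table

    def first_last_truth(self) -> dict[str, float]:
        """Ground-truth first/last peak-hyperemia means over eligible ROIs."""
        amps_f, amps_l, durs_f, durs_l = [], [], [], []
        for (animal, roi), (first, last) in self.eligible_roi_table().items():
            c_f = [c for c in first.components_for(roi) if c.kind == "III"][0]
            c_l = [c for c in last.components_for(roi) if c.kind == "III"][0]
            amps_f.append(c_f.peak_amplitude_pct)
            amps_l.append(c_l.peak_amplitude_pct)
            durs_f.append(c_f.fwhm_min)
            durs_l.append(c_l.fwhm_min)
        return {
            "amp_first": float(np.mean(amps_f)), "amp_last": float(np.mean(amps_l)),
            "dur_first": float(np.mean(durs_f)), "dur_last": float(np.mean(durs_l)),
            "n_rois": len(amps_f),
        }

    def self_statistics(self) -> dict[str, float]:
        """Roster-level summary used by the replication acceptance surface."""
        hourly = self.hourly_counts("ecog")
        stats = {
            "ecog_event_count": self.event_count("ecog"),
            "ios_event_count": self.event_count("ios"),
            "ecog_hours": sum(a.ecog_hours for a in self.analysis_animals("ecog")
                              if a.ecog_hours),
            "ecog_mean_time_to_first_min": self.mean_time_to_first_sd_min("ecog"),
            "ecog_hour1_mean_per_animal": float(np.mean(self.per_animal_hour_counts("ecog", 0))),
            "ecog_hours4to6_count": int(self.hourly_counts("ecog")[3:6].sum()),
            "ecog_hour1_count": int(hourly[0]),
            "ecog_mean_expansion_pct": float(np.mean(self.per_animal_expansion_pct("ecog"))),
            "ecog_incidence_per_h": float(np.mean(self.per_animal_incidence("ecog"))),
            "ios_mean_expansion_pct": float(np.mean(self.per_animal_expansion_pct("ios"))),
            "ios_hours4to6_count": int(self.hourly_counts("ios")[3:6].sum()),
        }
        if self.response_morphologies:
            counts = self.morphology_counts()
            total = sum(counts.values())
            stats["monophasic_prevalence_pct"] = 100.0 * counts.get("monophasic", 0) / total
            stats.update(self.first_last_truth())
        lsci = [t for a in self.animals for t in a.lsci_templates]
        if lsci:
            amps = [comp.peak_amplitude_pct
                    for t in lsci for comps in t.roi_components.values()
                    for comp in comps if comp.kind == "III"]
            stats["lsci_mean_cbf_elevation_pct"] = float(np.mean(amps))
        return stats


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _first_arrival_to_onset(
    first_arrival_min: float, origin: tuple[float, float], speed: float,
    layout: CorticalLayout, modality: str, hemisphere: str, reach: int,
) -> float:
    """Template onset such that the nearest reached sensor's kinematic arrival
    equals ``first_arrival_min`` exactly (detection times anchor the printed
    hourly statistics)."""
    sensors = [pos for sid, (h, pos) in layout.sensors(modality).items() if h == hemisphere]
    d_min = min(np.hypot(p[0] - origin[0], p[1] - origin[1]) for p in sensors)
    onset = first_arrival_min - d_min / speed
    if onset < 0:
        raise ValueError("first arrival too early for kinematic onset")
    return onset


def build_paper_replication_roster(seed: int = 0) -> GroundTruthRoster:
    """Build the fixed replication roster (the seed tags the roster for the
    noise generator; the tables themselves never change)."""
    layout = default_layout()
    animals: dict[str, AnimalGroundTruth] = {}
    counter = 0  # global event counter driving the speed/amplitude cycles

    for aid, spec in _ECOG_TABLE.items():
        a = AnimalGroundTruth(animal_id=aid, group=spec["group"], ecog_hours=spec["hours"])
        hemi = spec["start"]
        for k, (t_min, reach) in enumerate(spec["events"]):
            speed = _SPEED_CYCLE[counter % len(_SPEED_CYCLE)]
            onset = _first_arrival_to_onset(
                t_min, _ECOG_ORIGIN, speed, layout, "ecog", hemi, reach)
            a.ecog_templates.append(SDTemplate(
                event_id=f"{aid}-ecog-{k + 1}",
                modality="ecog",
                hemisphere=hemi,
                origin_mm=_ECOG_ORIGIN,
                onset_min=onset,
                speed_mm_per_min=speed,
                target_expansion=reach / 5.0,
                dc_amplitude_mV=_DC_AMP_CYCLE[counter % len(_DC_AMP_CYCLE)],
            ))
            hemi = "right" if hemi == "left" else "left"
            counter += 1
        animals[aid] = a

    # --- IOS events, morphology assignment and first/last III parameters ---
    for aid in _IOS_ORDER:
        spec = _IOS_TABLE[aid]
        a = animals[aid]
        a.ios_hours = spec["hours"]
        for k, (t_min, reach) in enumerate(spec["events"]):
            speed = _SPEED_CYCLE[counter % len(_SPEED_CYCLE)]
            onset = _first_arrival_to_onset(
                t_min, _IOS_ORIGIN, speed, layout, "ios", spec["hemi"], reach)
            a.ios_templates.append(SDTemplate(
                event_id=f"{aid}-ios-{k + 1}",
                modality="ios",
                hemisphere=spec["hemi"],
                origin_mm=_IOS_ORIGIN,
                onset_min=onset,
                speed_mm_per_min=speed,
                target_expansion=reach / 6.0,
            ))
            counter += 1

    roster = GroundTruthRoster(
        preset="paper_replication", seed=seed, layout=layout,
        animals=[animals[aid] for aid in _ECOG_TABLE],
    )

    # per-ROI III parameter table for eligible (>= 2 SDs) ROIs
    eligible: list[tuple[str, str]] = []
    first_last: dict[tuple[str, str], tuple[SDTemplate, SDTemplate]] = {}
    for aid in _IOS_ORDER:
        a = animals[aid]
        reaching: dict[str, list[SDTemplate]] = {}
        for t in a.ios_templates:
            for roi in t.reached_sensors(layout):
                reaching.setdefault(roi, []).append(t)
        hemi_rois = sorted(
            (roi for roi, ts in reaching.items() if len(ts) >= 2),
            key=lambda roi: layout.rois_ios[roi][1][1],  # by y position = distance order
        )
        for roi in hemi_rois:
            eligible.append((aid, roi))
            ts = sorted(reaching[roi], key=lambda t: t.onset_min)
            first_last[(aid, roi)] = (ts[0], ts[-1])
    assert len(eligible) == _N_ELIGIBLE, f"eligible ROI count {len(eligible)} != {_N_ELIGIBLE}"

    iii_params: dict[tuple[str, str, str], tuple[float, float]] = {}
    for idx, (aid, roi) in enumerate(eligible):
        first, last = first_last[(aid, roi)]
        iii_params[(aid, first.event_id, roi)] = (float(_AMP_FIRST[idx]), float(_DUR_FIRST[idx]))
        iii_params[(aid, last.event_id, roi)] = (float(_AMP_LAST[idx]), float(_DUR_LAST[idx]))

    # morphology labels over the deterministic response order
    pattern_i = 0
    for aid in _IOS_ORDER:
        a = animals[aid]
        for t in a.ios_templates:
            for roi in t.reached_sensors(layout):
                label = _MORPH_PATTERN[pattern_i % len(_MORPH_PATTERN)]
                pattern_i += 1
                roster.response_morphologies[(aid, t.event_id, roi)] = label
                a3, f3 = iii_params.get((aid, t.event_id, roi), (_DEFAULT_A3, _DEFAULT_F3))
                t.roi_components[roi] = morphology_components(label, a3, f3)

    # --- single analyzable LSCI animal (group 3) with a paired ECoG SD ---
    lsci_animal = AnimalGroundTruth(
        animal_id=_LSCI_ANIMAL, group=3,
        ecog_hours=_LSCI_ECOG_HOURS, lsci_hours=_LSCI_HOURS,
    )
    speed = 3.5
    lsci_onset = _first_arrival_to_onset(
        _LSCI_ONSET_MIN, (0.0, 0.0), speed, layout, "lsci", "right", 4)
    lsci_t = SDTemplate(
        event_id=f"{_LSCI_ANIMAL}-lsci-1", modality="lsci", hemisphere="right",
        origin_mm=(0.0, 0.0), onset_min=lsci_onset, speed_mm_per_min=speed,
        target_expansion=1.0,
    )
    for roi, amp in _LSCI_CBF_AMPS.items():
        lsci_t.roi_components[roi] = [ComponentSpec("III", amp, 2.0, 0.0)]
    lsci_animal.lsci_templates.append(lsci_t)
    ecog_onset = _first_arrival_to_onset(
        _LSCI_ECOG_ONSET_MIN, _ECOG_ORIGIN, speed, layout, "ecog", "right", 5)
    lsci_animal.ecog_templates.append(SDTemplate(
        event_id=f"{_LSCI_ANIMAL}-ecog-1", modality="ecog", hemisphere="right",
        origin_mm=_ECOG_ORIGIN, onset_min=ecog_onset, speed_mm_per_min=speed,
        target_expansion=1.0,
    ))
    roster.animals.append(lsci_animal)
    return roster


def build_unit_test_roster(seed: int = 0) -> GroundTruthRoster:
    """Tiny fixed preset: one animal, 2 h of monitoring, exactly two injected
    SDs per modality pair (ECoG + IOS) and one LSCI SD."""
    layout = default_layout()
    a = AnimalGroundTruth(
        animal_id="u01", group=2, ecog_hours=2.0, ios_hours=2.0, lsci_hours=2.0)
    for k, (t_min, reach, hemi) in enumerate([(10.0, 5, "left"), (60.0, 3, "right")]):
        speed = 4.0
        a.ecog_templates.append(SDTemplate(
            event_id=f"u01-ecog-{k + 1}", modality="ecog", hemisphere=hemi,
            origin_mm=_ECOG_ORIGIN,
            onset_min=_first_arrival_to_onset(t_min, _ECOG_ORIGIN, speed, layout,
                                              "ecog", hemi, reach),
            speed_mm_per_min=speed, target_expansion=reach / 5.0,
        ))
    roster = GroundTruthRoster(preset="unit_test", seed=seed, layout=layout, animals=[a])
    for k, (t_min, reach, hemi, morph) in enumerate(
            [(10.0, 4, "left", "tetraphasic"), (60.0, 6, "left", "monophasic")]):
        speed = 4.0
        t = SDTemplate(
            event_id=f"u01-ios-{k + 1}", modality="ios", hemisphere=hemi,
            origin_mm=_IOS_ORIGIN,
            onset_min=_first_arrival_to_onset(t_min, _IOS_ORIGIN, speed, layout,
                                              "ios", hemi, reach),
            speed_mm_per_min=speed, target_expansion=reach / 6.0,
        )
        for roi in t.reached_sensors(layout):
            t.roi_components[roi] = morphology_components(morph)
            roster.response_morphologies[("u01", t.event_id, roi)] = morph
        a.ios_templates.append(t)
    lsci_t = SDTemplate(
        event_id="u01-lsci-1", modality="lsci", hemisphere="right",
        origin_mm=(0.0, 0.0),
        onset_min=_first_arrival_to_onset(12.0, (0.0, 0.0), 3.5, layout, "lsci", "right", 4),
        speed_mm_per_min=3.5, target_expansion=1.0,
    )
    for roi in lsci_t.reached_sensors(layout):
        lsci_t.roi_components[roi] = [ComponentSpec("III", 60.0, 2.0, 0.0)]
    a.lsci_templates.append(lsci_t)
    return roster
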