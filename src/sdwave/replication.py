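"""End-to-end replication run: simulate the fixed-roster cohort at one noise
seed and push every modality through its detection pipeline.

This is the package's main worked analysis: 12 ECoG animals (venous-occlusion
groups 1 and 2), 6 IOS animals, one LSCI animal, everything detected with
default settings and aggregated into the cohort statistics the study design
reports (event counts, expansion, incidence, hourly profile, first/last
hyperemia metrics, morphology prevalence, LSCI elevation).
"""

from __future__ import annotations

import numpy as np

from .cohort import GeneratorConfig, iter_animals
from .ecog import ECoGConfig, detect_sd_ecog
from .lsci import LSCIConfig, detect_sd_lsci, match_modalities
from .model import HemodynamicResponse, SDEvent
from .optical import OpticalConfig, analyze_responses, group_sd_ios
from .stats import first_last_comparison, summarize

__all__ = ["run_replication", "replication_statistics"]


def run_replication(
    seed: int,
    gen_config: GeneratorConfig | None = None,
    ecog_config: ECoGConfig | None = None,
    optical_config: OpticalConfig | None = None,
    lsci_config: LSCIConfig | None = None,
) -> dict:
    """Simulate + detect the full replication cohort at one noise seed.

    Returns a dict with detected events per modality, hemodynamic responses,
    per-animal monitored hours, LSCI perfusion responses and the cross-modal
    match for the speckle animal.
    """
    ecog_events: list[SDEvent] = []
    ios_events: list[SDEvent] = []
    lsci_events: list[SDEvent] = []
    responses: list[HemodynamicResponse] = []
    perfusion = []
    ecog_hours: dict[str, float] = {}
    ios_hours: dict[str, float] = {}
    lsci_match = []
    roster = None
    for animal, rec, ios, lsci in iter_animals("paper_replication", seed, config=gen_config):
        animal_ecog_events: list[SDEvent] = []
        if rec is not None:
            animal_ecog_events, _ = detect_sd_ecog(rec, _layout(animal, rec), ecog_config)
        if rec is not None and animal.group in (1, 2):
            # only the long-monitoring groups enter the ECoG cohort statistics
            ecog_hours[animal.animal_id] = animal.ecog_hours
            ecog_events.extend(animal_ecog_events)
        if ios is not None:
            events, windows = group_sd_ios(ios, _layout(animal, ios), optical_config)
            ios_hours[animal.animal_id] = animal.ios_hours
            ios_events.extend(events)
            responses.extend(analyze_responses(ios, events, windows, optical_config))
        if lsci is not None:
            events, perf = detect_sd_lsci(lsci, _layout(animal, lsci), lsci_config)
            lsci_events.extend(events)
            perfusion.extend(perf)
            lsci_match = match_modalities(events, animal_ecog_events)
    return {
        "ecog_events": ecog_events,
        "ios_events": ios_events,
        "lsci_events": lsci_events,
        "responses": responses,
        "perfusion": perfusion,
        "ecog_hours": ecog_hours,
        "ios_hours": ios_hours,
        "lsci_match": lsci_match,
    }


_LAYOUT_CACHE = {}


def _layout(animal, _obj):
    # one shared default layout per process; rosters are built on it
    from .layout import default_layout

    if "layout" not in _LAYOUT_CACHE:
        _LAYOUT_CACHE["layout"] = default_layout()
    return _LAYOUT_CACHE["layout"]


def _per_animal_mean_expansion(events: list[SDEvent]) -> float:
    by_animal: dict[str, list[float]] = {}
    for e in events:
        by_animal.setdefault(e.animal_id, []).append(e.expansion_pct)
    return float(np.mean([np.mean(v) for v in by_animal.values()]))


def replication_statistics(run: dict) -> dict[str, float]:
    """Reduce one replication run to the headline cohort statistics."""
    ecog_events = run["ecog_events"]
    ios_events = run["ios_events"]
    summary = summarize(
        {"ecog": ecog_events, "ios": ios_events},
        {"ecog": run["ecog_hours"], "ios": run["ios_hours"]},
        responses=run["responses"],
    )
    inc = summary.incidence_by_modality["ecog"]
    fl = first_last_comparison(run["responses"])
    stats = {
        "ecog_event_count": float(len(ecog_events)),
        "ios_event_count": float(len(ios_events)),
        "ecog_expansion_mean_pct": _per_animal_mean_expansion(ecog_events),
        "ios_expansion_mean_pct": _per_animal_mean_expansion(ios_events),
        "ecog_incidence_per_h": inc.cohort_rate_mean,
        "ecog_hour1_mean_per_animal": inc.hour_mean_per_animal(0),
        "amp_first_mean_pct": float(np.mean(fl.amp_first)) if fl.amp_first.size else float("nan"),
        "dur_last_mean_min": float(np.mean(fl.dur_last_min)) if fl.dur_last_min.size else float("nan"),
        "lsci_elevation_mean_pct": float(np.mean([p.percent_elevation for p in run["perfusion"]]))
        if run["perfusion"] else float("nan"),
        "n_eligible_rois": float(len(fl.rois)),
        "n_responses": float(len(run["responses"])),
    }
    prevalence = summary.morphology_prevalence_pct
    stats["monophasic_prevalence_pct"] = prevalence.get("monophasic", 0.0)
    return stats
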