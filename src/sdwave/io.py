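"""File formats: CSV time series, TIFF image stacks, JSON events and rosters.

Every artifact is plain text except IOS image stacks (multi-page 8-bit
grayscale TIFF). Time-series CSVs carry a JSON sidecar (same path with an
extra ``.json`` suffix) holding the metadata the detection code needs:
sampling rate, occlusion time and sensor geometry. All schemas are
versioned; readers refuse files written under a different major schema.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ComponentSpec, CorticalLayout, ROITraceSet, SDEvent, SDTemplate, TimeSeriesRecording
from .roster import AnimalGroundTruth, GroundTruthRoster

__all__ = [
    "SCHEMA_VERSION",
    "read_ecog", "write_ecog",
    "read_traces", "write_traces",
    "read_events", "write_events",
    "read_ios_stack", "write_ios_stack",
    "read_roster", "write_roster",
]

SCHEMA_VERSION = 1
_FLOAT_FMT = "%.17g"  # lossless round-trip for float64


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _require_keys(meta: dict, keys: list[str], where: str) -> None:
    missing = [k for k in keys if k not in meta]
    if missing:
        raise ValueError(f"{where}: metadata is missing required keys {missing}")


def _check_schema(meta: dict, where: str) -> None:
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"{where}: schema version {version!r} does not match reader version {SCHEMA_VERSION}"
        )


# ---------------------------------------------------------------------------
# ECoG
# ---------------------------------------------------------------------------


def write_ecog(recording: TimeSeriesRecording, path: str | Path) -> None:
    """Write a recording as CSV (one column per channel) + JSON sidecar."""
    path = Path(path)
    header = ",".join(["time_s"] + recording.channel_ids)
    t = np.arange(recording.n_samples) / recording.sampling_rate
    table = np.column_stack([t, recording.data.T])
    np.savetxt(path, table, delimiter=",", header=header, comments="", fmt=_FLOAT_FMT)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "kind": "ecog",
        "sampling_rate_hz": recording.sampling_rate,
        "occlusion_time_s": recording.occlusion_time_s,
        "animal_id": recording.animal_id,
        "channels": [
            {"id": c, "hemisphere": h, "x_mm": float(p[0]), "y_mm": float(p[1])}
            for c, h, p in zip(recording.channel_ids, recording.hemispheres,
                               recording.positions_mm)
        ],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_ecog(path: str | Path) -> TimeSeriesRecording:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    _check_schema(meta, str(sidecar))
    _require_keys(meta, ["sampling_rate_hz", "occlusion_time_s", "channels"], str(sidecar))
    frame = pd.read_csv(path, float_precision="round_trip")
    channel_ids = [c["id"] for c in meta["channels"]]
    missing = [c for c in channel_ids if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: CSV lacks channels {missing} declared in the sidecar")
    return TimeSeriesRecording(
        channel_ids=channel_ids,
        hemispheres=[c["hemisphere"] for c in meta["channels"]],
        positions_mm=np.array([[c["x_mm"], c["y_mm"]] for c in meta["channels"]]),
        sampling_rate=float(meta["sampling_rate_hz"]),
        data=frame[channel_ids].to_numpy().T,
        occlusion_time_s=float(meta["occlusion_time_s"]),
        animal_id=meta.get("animal_id", "animal"),
    )


# ---------------------------------------------------------------------------
# ROI traces (IOS / LSCI)
# ---------------------------------------------------------------------------


def write_traces(traceset: ROITraceSet, path: str | Path) -> None:
    """Write an ROI trace set as CSV; columns are ``roi:signal`` pairs."""
    path = Path(path)
    columns, arrays = ["time_s"], [traceset.times_s()]
    for name in sorted(traceset.signals):
        for i, roi in enumerate(traceset.roi_ids):
            columns.append(f"{roi}:{name}")
            arrays.append(traceset.signals[name][i])
    np.savetxt(path, np.column_stack(arrays), delimiter=",",
               header=",".join(columns), comments="", fmt=_FLOAT_FMT)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "kind": "roi_traces",
        "modality": traceset.modality,
        "sampling_interval_s": traceset.sampling_interval_s,
        "occlusion_time_s": traceset.occlusion_time_s,
        "animal_id": traceset.animal_id,
        "rois": [
            {"id": r, "hemisphere": h, "x_mm": float(p[0]), "y_mm": float(p[1])}
            for r, h, p in zip(traceset.roi_ids, traceset.hemispheres, traceset.positions_mm)
        ],
        "baseline_values": None if traceset.baseline_values is None
        else [float(b) for b in traceset.baseline_values],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_traces(path: str | Path) -> ROITraceSet:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    _check_schema(meta, str(sidecar))
    _require_keys(meta, ["modality", "sampling_interval_s", "occlusion_time_s", "rois"],
                  str(sidecar))
    frame = pd.read_csv(path, float_precision="round_trip")
    roi_ids = [r["id"] for r in meta["rois"]]
    signal_names = sorted({c.split(":", 1)[1] for c in frame.columns if ":" in c})
    signals = {
        name: np.stack([frame[f"{roi}:{name}"].to_numpy() for roi in roi_ids])
        for name in signal_names
    }
    baselines = meta.get("baseline_values")
    return ROITraceSet(
        roi_ids=roi_ids,
        hemispheres=[r["hemisphere"] for r in meta["rois"]],
        positions_mm=np.array([[r["x_mm"], r["y_mm"]] for r in meta["rois"]]),
        modality=meta["modality"],
        signals=signals,
        sampling_interval_s=float(meta["sampling_interval_s"]),
        occlusion_time_s=float(meta["occlusion_time_s"]),
        animal_id=meta.get("animal_id", "animal"),
        baseline_values=None if baselines is None else np.asarray(baselines, dtype=float),
    )


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


def write_events(events: list[SDEvent], path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "events": [
            {
                "event_id": e.event_id, "modality": e.modality,
                "animal_id": e.animal_id, "hemisphere": e.hemisphere,
                "onsets_s": e.onsets_s, "expansion_pct": e.expansion_pct,
                "summary_amplitude": None if np.isnan(e.summary_amplitude)
                else e.summary_amplitude,
                "flags": e.flags,
            }
            for e in events
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_events(path: str | Path) -> list[SDEvent]:
    payload = json.loads(Path(path).read_text())
    _check_schema(payload, str(path))
    return [
        SDEvent(
            event_id=e["event_id"], modality=e["modality"], animal_id=e["animal_id"],
            hemisphere=e["hemisphere"], onsets_s=e["onsets_s"],
            expansion_pct=e["expansion_pct"],
            summary_amplitude=float("nan") if e["summary_amplitude"] is None
            else e["summary_amplitude"],
            flags=list(e.get("flags", [])),
        )
        for e in payload["events"]
    ]


# ---------------------------------------------------------------------------
# IOS image stacks
# ---------------------------------------------------------------------------


def write_ios_stack(
    traceset: ROITraceSet,
    path: str | Path,
    shape: tuple[int, int] = (48, 64),
    background: int = 128,
) -> dict[str, list[tuple[int, int]]]:
    """Render an IOS trace set as an 8-bit multi-page TIFF.

    Each ROI becomes a 5-pixel cross whose pixels carry the (rounded) trace
    value; the rest of the frame is flat background. Returns the pixel map
    so the stack can be read back with :func:`read_ios_stack`.
    """
    import tifffile

    if traceset.modality != "IOS":
        raise ValueError("image stacks are an IOS artifact")
    n_rois = len(traceset.roi_ids)
    rows = np.linspace(8, shape[0] - 8, n_rois).astype(int)
    cols = np.linspace(8, shape[1] - 8, n_rois).astype(int)
    pixel_map = {
        roi: [(int(r), int(c)), (int(r) - 1, int(c)), (int(r) + 1, int(c)),
              (int(r), int(c) - 1), (int(r), int(c) + 1)]
        for roi, r, c in zip(traceset.roi_ids, rows, cols)
    }
    intensity = traceset.signals["intensity"]
    frames = np.full((traceset.n_samples, *shape), background, dtype=np.uint8)
    for i, roi in enumerate(traceset.roi_ids):
        values = np.clip(np.round(intensity[i]), 0, 255).astype(np.uint8)
        for r, c in pixel_map[roi]:
            frames[:, r, c] = values
    tifffile.imwrite(Path(path), frames, photometric="minisblack")
    return pixel_map


def read_ios_stack(
    path: str | Path,
    rois: dict[str, dict],
    sampling_interval_s: float = 1.0,
    occlusion_time_s: float = 0.0,
    animal_id: str = "animal",
) -> ROITraceSet:
    """Extract per-ROI mean-intensity traces from a TIFF stack.

    ``rois`` maps roi id -> ``{"hemisphere", "position_mm", "pixels"}`` where
    ``pixels`` is a list of (row, col) indices (the small ~5-pixel ROI masks
    used at 564 nm).
    """
    import tifffile

    frames = tifffile.imread(Path(path))
    if frames.ndim == 2:
        frames = frames[None]
    n_frames, height, width = frames.shape
    traces = {}
    for roi, spec in rois.items():
        pixels = np.asarray(spec["pixels"], dtype=int)
        if (pixels[:, 0].min() < 0 or pixels[:, 0].max() >= height
                or pixels[:, 1].min() < 0 or pixels[:, 1].max() >= width):
            raise ValueError(f"ROI {roi!r} has pixels outside the {height}x{width} frame")
        traces[roi] = frames[:, pixels[:, 0], pixels[:, 1]].mean(axis=1)
    roi_ids = list(rois)
    return ROITraceSet(
        roi_ids=roi_ids,
        hemispheres=[rois[r]["hemisphere"] for r in roi_ids],
        positions_mm=np.array([rois[r]["position_mm"] for r in roi_ids]),
        modality="IOS",
        signals={"intensity": np.stack([traces[r] for r in roi_ids])},
        sampling_interval_s=sampling_interval_s,
        occlusion_time_s=occlusion_time_s,
        animal_id=animal_id,
    )


# ---------------------------------------------------------------------------
# rosters
# ---------------------------------------------------------------------------


def _template_to_dict(t: SDTemplate) -> dict:
    return {
        "event_id": t.event_id, "modality": t.modality, "hemisphere": t.hemisphere,
        "origin_mm": list(t.origin_mm), "onset_min": t.onset_min,
        "speed_mm_per_min": t.speed_mm_per_min, "target_expansion": t.target_expansion,
        "dc_amplitude_mV": t.dc_amplitude_mV, "dc_duration_s": t.dc_duration_s,
        "depression_fraction": t.depression_fraction,
        "depression_duration_min": t.depression_duration_min,
        "components": [vars(c) for c in t.components],
        "roi_components": {roi: [dict(kind=c.kind, peak_amplitude_pct=c.peak_amplitude_pct,
                                      fwhm_min=c.fwhm_min, lag_min=c.lag_min)
                                 for c in comps]
                           for roi, comps in t.roi_components.items()},
        "oxy_gain": t.oxy_gain, "deoxy_gain": t.deoxy_gain, "deoxy_lag_s": t.deoxy_lag_s,
    }


def _template_from_dict(d: dict) -> SDTemplate:
    return SDTemplate(
        event_id=d["event_id"], modality=d["modality"], hemisphere=d["hemisphere"],
        origin_mm=tuple(d["origin_mm"]), onset_min=d["onset_min"],
        speed_mm_per_min=d["speed_mm_per_min"], target_expansion=d["target_expansion"],
        dc_amplitude_mV=d["dc_amplitude_mV"], dc_duration_s=d["dc_duration_s"],
        depression_fraction=d["depression_fraction"],
        depression_duration_min=d["depression_duration_min"],
        components=[ComponentSpec(**c) for c in d["components"]],
        roi_components={roi: [ComponentSpec(**c) for c in comps]
                        for roi, comps in d["roi_components"].items()},
        oxy_gain=d["oxy_gain"], deoxy_gain=d["deoxy_gain"], deoxy_lag_s=d["deoxy_lag_s"],
    )


def _layout_to_dict(layout: CorticalLayout) -> dict:
    def sensors(d):
        return {sid: {"hemisphere": h, "x_mm": p[0], "y_mm": p[1]}
                for sid, (h, p) in d.items()}

    return {
        "contacts": sensors(layout.contacts),
        "rois_ios": sensors(layout.rois_ios),
        "rois_lsci": sensors(layout.rois_lsci),
        "occlusion_site": list(layout.occlusion_site),
        "contact_spacing_mm": layout.contact_spacing_mm,
    }


def _layout_from_dict(d: dict) -> CorticalLayout:
    def sensors(dd):
        return {sid: (s["hemisphere"], (s["x_mm"], s["y_mm"])) for sid, s in dd.items()}

    return CorticalLayout(
        contacts=sensors(d["contacts"]), rois_ios=sensors(d["rois_ios"]),
        rois_lsci=sensors(d["rois_lsci"]), occlusion_site=tuple(d["occlusion_site"]),
        contact_spacing_mm=d["contact_spacing_mm"],
    )


def write_roster(roster: GroundTruthRoster, path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "preset": roster.preset,
        "seed": roster.seed,
        "layout": _layout_to_dict(roster.layout),
        "animals": [
            {
                "animal_id": a.animal_id, "group": a.group,
                "ecog_hours": a.ecog_hours, "ios_hours": a.ios_hours,
                "lsci_hours": a.lsci_hours, "occlusion_time_s": a.occlusion_time_s,
                "flags": a.flags,
                "ecog_templates": [_template_to_dict(t) for t in a.ecog_templates],
                "ios_templates": [_template_to_dict(t) for t in a.ios_templates],
                "lsci_templates": [_template_to_dict(t) for t in a.lsci_templates],
            }
            for a in roster.animals
        ],
        "response_morphologies": {
            "|".join(key): label for key, label in roster.response_morphologies.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_roster(path: str | Path) -> GroundTruthRoster:
    payload = json.loads(Path(path).read_text())
    _check_schema(payload, str(path))
    roster = GroundTruthRoster(
        preset=payload["preset"], seed=payload["seed"],
        layout=_layout_from_dict(payload["layout"]),
        animals=[
            AnimalGroundTruth(
                animal_id=a["animal_id"], group=a["group"],
                ecog_hours=a["ecog_hours"], ios_hours=a["ios_hours"],
                lsci_hours=a["lsci_hours"], occlusion_time_s=a["occlusion_time_s"],
                flags=list(a["flags"]),
                ecog_templates=[_template_from_dict(t) for t in a["ecog_templates"]],
                ios_templates=[_template_from_dict(t) for t in a["ios_templates"]],
                lsci_templates=[_template_from_dict(t) for t in a["lsci_templates"]],
            )
            for a in payload["animals"]
        ],
        response_morphologies={
            tuple(key.split("|")): label
            for key, label in payload["response_morphologies"].items()
        },
    )
    return roster
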