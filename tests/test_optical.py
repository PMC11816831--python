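"""IOS pipeline: sign convention, robust baseline, deviation detection, the
>= 2-ROI rule, component decomposition/classification and motion QC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sdwave
from sdwave import (
    OpticalConfig,
    classify_morphology,
    decompose_components,
    detect_deviations,
    establish_baseline,
    hyperemia_metrics,
    morphology_components,
    motion_qc,
    to_cbv,
)
from sdwave.model import Component, HemodynamicResponse, ROITraceSet
from sdwave.pulses import component_pulse
from sdwave.optical import group_sd_ios


def _pulse_trace(comps, n=3600, dt=1.0, noise=0.0, at=600.0, seed=0):
    t = np.arange(n) * dt
    cbv = np.zeros(n)
    for c in comps:
        cbv += component_pulse(t - at - c.lag_min * 60.0, c.peak_amplitude_pct,
                               c.fwhm_min * 60.0)
    if noise:
        cbv += np.random.default_rng(seed).standard_normal(n) * noise
    return cbv


# ---------------------------------------------------------------------------
# CBV conversion and baseline
# ---------------------------------------------------------------------------


def test_to_cbv_sign_convention():
    trace = np.array([120.0, 120.0, 98.4, 120.0])  # 18 % intensity dip
    cbv = to_cbv(trace, 120.0)
    assert cbv[2] == pytest.approx(18.0)
    assert np.all(to_cbv(np.full(10, 7.0), 7.0) == 0.0)
    with pytest.raises(ValueError):
        to_cbv(trace, 0.0)


def test_baseline_median_immune_to_spikes():
    trace = np.full(600, 100.0)
    trace[::50] = 500.0
    i0, sigma = establish_baseline(trace)
    assert i0 == 100.0


def test_baseline_sigma_estimate_unbiased():
    """Robust scale (1.4826 MAD) recovers a known white-noise sigma within
    10 % at n = 300 (Monte-Carlo oracle)."""
    rng = np.random.default_rng(42)
    estimates = [establish_baseline(100.0 + rng.standard_normal(300) * 2.0)[1]
                 for _ in range(200)]
    assert np.mean(estimates) == pytest.approx(2.0, rel=0.1)


def test_baseline_short_mask_widens_with_warning():
    trace = np.full(1000, 50.0)
    mask = np.zeros(1000, dtype=bool)
    mask[:60] = True  # only 1 min of event-free data
    with pytest.warns(UserWarning, match="widening"):
        i0, _ = establish_baseline(trace, mask, dt_s=1.0)
    assert i0 == 50.0


# ---------------------------------------------------------------------------
# deviation segments
# ---------------------------------------------------------------------------


def test_deviations_flat_and_threshold_limit():
    assert detect_deviations(np.zeros(3600), sigma_pct=0.5) == []
    comps = [sdwave.ComponentSpec("III", 18.0, 3.0, 0.0)]
    cbv = _pulse_trace(comps, noise=0.5)
    devs = detect_deviations(cbv, 0.5)
    assert len(devs) == 1 and devs[0].polarity == 1
    assert devs[0].peak_pct == pytest.approx(18.0, abs=2.0)
    assert detect_deviations(cbv, sigma_pct=1e9) == []  # k*sigma -> infinity


def test_opposite_polarity_segments_kept_separate():
    comps = morphology_components("triphasic", 18.0, 3.0)
    devs = detect_deviations(_pulse_trace(comps), 0.5)
    polarities = [d.polarity for d in devs]
    assert polarities[0] == -1 and 1 in polarities  # II trough then hyperemia


# ---------------------------------------------------------------------------
# >= 2 ROI rule
# ---------------------------------------------------------------------------


def _traceset(layout, cbv_by_roi, dt=1.0, occ=600.0):
    roi_ids = list(layout.rois_ios)
    n = len(next(iter(cbv_by_roi.values())))
    baselines = np.full(len(roi_ids), 120.0)
    intensity = np.tile(120.0, (len(roi_ids), n))
    for roi, cbv in cbv_by_roi.items():
        i = roi_ids.index(roi)
        intensity[i] = 120.0 * (1 - cbv / 100.0)
    rng = np.random.default_rng(0)
    intensity = intensity + rng.standard_normal(intensity.shape) * 0.6
    return ROITraceSet(
        roi_ids=roi_ids, hemispheres=[layout.rois_ios[r][0] for r in roi_ids],
        positions_mm=np.array([layout.rois_ios[r][1] for r in roi_ids]),
        modality="IOS", signals={"intensity": intensity},
        sampling_interval_s=dt, occlusion_time_s=occ, animal_id="t",
        baseline_values=baselines)


def test_single_roi_deviation_is_not_an_event(layout):
    comps = [sdwave.ComponentSpec("III", 18.0, 3.0, 0.0)]
    ts = _traceset(layout, {"iosL1": _pulse_trace(comps, at=1800)})
    events, _ = group_sd_ios(ts, layout)
    assert events == []


def test_two_roi_propagating_deviation_is_an_event(layout):
    comps = [sdwave.ComponentSpec("III", 18.0, 3.0, 0.0)]
    ts = _traceset(layout, {
        "iosL1": _pulse_trace(comps, at=1800.0),
        "iosL2": _pulse_trace(comps, at=1875.0),  # 5 mm at 4 mm/min
    })
    events, _ = group_sd_ios(ts, layout)
    assert len(events) == 1
    assert set(events[0].onsets_s) == {"iosL1", "iosL2"}
    assert events[0].expansion_pct == pytest.approx(100.0 * 2 / 6)


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------


def test_decompose_recovers_kinds_in_order():
    comps = morphology_components("triphasic", 18.0, 3.0)
    cbv = _pulse_trace(comps)  # noiseless
    out = decompose_components(cbv, 1.0, (300.0, 3000.0), sigma_pct=0.5)
    assert [c.kind for c in out] == ["II", "III", "IV"]


def test_decompose_recovers_amplitude_and_duration():
    comps = [sdwave.ComponentSpec("III", 18.0, 3.1, 0.0)]
    cbv = _pulse_trace(comps, noise=0.5)
    out = decompose_components(cbv, 1.0, (300.0, 2400.0), sigma_pct=0.5)
    amp, dur = out[0].peak_amplitude_pct, out[0].duration_min
    assert amp == pytest.approx(18.0, abs=0.5)
    assert dur == pytest.approx(3.1, abs=0.2)


def test_decompose_pure_noise_is_empty():
    rng = np.random.default_rng(3)
    cbv = rng.standard_normal(3600) * 0.5
    assert decompose_components(cbv, 1.0, (300.0, 3000.0), sigma_pct=0.5) == []


def test_resynthesis_rmse_below_one_percent():
    """Summing the fitted pulses reproduces the noiseless trace to < 1 % of
    baseline (decomposition -> re-synthesis invariant)."""
    comps = morphology_components("tetraphasic", 20.0, 4.0)
    cbv = _pulse_trace(comps, n=4800)
    out = decompose_components(cbv, 1.0, (300.0, 4500.0), sigma_pct=0.5)
    assert [c.kind for c in out] == ["I", "II", "III", "IV"]
    t = np.arange(4800.0)
    synth = np.zeros_like(t)
    for c in out:
        synth += component_pulse(t - c.onset_s, c.peak_amplitude_pct,
                                 c.duration_min * 60.0)
    rmse = np.sqrt(np.mean((synth - cbv) ** 2))
    assert rmse < 1.0


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("kinds,label", [
    (("III",), "monophasic"),
    (("III", "IV"), "biphasic"),
    (("II", "III", "IV"), "triphasic"),
    (("I", "II", "III", "IV"), "tetraphasic"),
    (("V",), "other"),
    (("I", "III"), "other"),
    (("II", "III", "IV", "V"), "other"),
])
def test_classification_table(kinds, label):
    assert classify_morphology(list(kinds)) == label


def test_classification_empty_is_an_error():
    with pytest.raises(ValueError):
        classify_morphology([])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from(["I", "II", "III", "IV", "V"]), min_size=1, max_size=5))
def test_classification_pure_function_of_kind_sequence(kinds):
    table = {("III",): "monophasic", ("III", "IV"): "biphasic",
             ("II", "III", "IV"): "triphasic",
             ("I", "II", "III", "IV"): "tetraphasic"}
    expected = table.get(tuple(kinds), "other")
    assert classify_morphology(kinds) == expected
    # invariance to representation: Component objects give the same answer
    as_components = [Component(kind=k, onset_s=float(i * 100),
                               peak_amplitude_pct=1.0 if k in "I III IV".split() else -1.0,
                               duration_min=1.0)
                     for i, k in enumerate(kinds)]
    assert classify_morphology(as_components) == expected


# ---------------------------------------------------------------------------
# hyperemia metrics
# ---------------------------------------------------------------------------


def test_triangular_pulse_half_max_width_is_half_base():
    """Symmetric triangular pulse of base b: width at half maximum = b / 2."""
    t = np.arange(3600.0)
    b, h = 480.0, 12.0
    tri = np.clip(h * (1 - np.abs(t - 1200.0) / (b / 2)), 0.0, None)
    cfg = OpticalConfig(refine_fit=False, smooth_s=1.0)
    out = decompose_components(tri, 1.0, (600.0, 2400.0), sigma_pct=0.5, config=cfg)
    assert len(out) == 1 and out[0].kind == "III"
    assert out[0].duration_min * 60.0 == pytest.approx(b / 2, abs=2.0)


def test_hyperemia_metrics_reads_component_iii():
    r = HemodynamicResponse(
        roi_id="r", event_id="e", animal_id="a", hemisphere="left",
        components=[Component("II", 0.0, -5.0, 1.0), Component("III", 60.0, 18.5, 3.1)],
        morphology="triphasic", baseline_value=120.0, noise_sigma=0.5)
    assert hyperemia_metrics(r) == (18.5, 3.1)
    r2 = HemodynamicResponse(
        roi_id="r", event_id="e", animal_id="a", hemisphere="left",
        components=[Component("V", 0.0, -4.0, 2.0)], morphology="other",
        baseline_value=120.0, noise_sigma=0.5)
    with pytest.raises(ValueError):
        hyperemia_metrics(r2)


def test_amplitude_invariant_to_intensity_rescaling(layout):
    comps = [sdwave.ComponentSpec("III", 18.0, 3.0, 0.0)]
    ts = _traceset(layout, {
        "iosL1": _pulse_trace(comps, at=1800.0),
        "iosL2": _pulse_trace(comps, at=1875.0),
    })
    amps = []
    for scale in (1.0, 7.3):
        scaled = ROITraceSet(
            roi_ids=ts.roi_ids, hemispheres=ts.hemispheres,
            positions_mm=ts.positions_mm, modality="IOS",
            signals={"intensity": ts.signals["intensity"] * scale},
            sampling_interval_s=1.0, occlusion_time_s=600.0, animal_id="t",
            baseline_values=ts.baseline_values * scale)
        events, windows = group_sd_ios(scaled, layout)
        responses = sdwave.analyze_responses(scaled, events, windows)
        amps.append(sorted(r.component("III").peak_amplitude_pct for r in responses))
    np.testing.assert_allclose(amps[0], amps[1], rtol=1e-9)


# ---------------------------------------------------------------------------
# motion QC
# ---------------------------------------------------------------------------


def test_motion_qc_static_stack_clean():
    frames = np.full((120, 16, 16), 100.0)
    assert not motion_qc(frames).any()


def test_motion_qc_flags_jump():
    rng = np.random.default_rng(0)
    frames = 100.0 + rng.standard_normal((120, 16, 16))
    frames[60:] = np.roll(frames[60:], 10, axis=2) + 30.0  # bulk shift
    flags = motion_qc(frames)
    assert flags[60]
    assert not flags[:40].any()


def test_motion_flags_suppress_detection(layout):
    comps = [sdwave.ComponentSpec("III", 18.0, 3.0, 0.0)]
    ts = _traceset(layout, {
        "iosL1": _pulse_trace(comps, at=1800.0),
        "iosL2": _pulse_trace(comps, at=1875.0),
    })
    exclude = np.zeros(ts.n_samples, dtype=bool)
    exclude[1700:2600] = True  # motion over the event window
    events, _ = group_sd_ios(ts, layout, exclude_mask=exclude)
    assert events == []
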