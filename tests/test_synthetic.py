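"""Synthetic-cohort generator: ground-truth arithmetic, determinism, sign
conventions and the fixed replication roster's self-statistics."""

import hashlib

import numpy as np
import pytest

import sdwave
from sdwave import (
    ComponentSpec,
    GeneratorConfig,
    SDTemplate,
    build_paper_replication_roster,
    simulate_cohort,
)
from sdwave.cohort import synthesize_animal
from sdwave.roster import AnimalGroundTruth, GroundTruthRoster


def _hash_bundle(bundle):
    h = hashlib.md5()
    for store in (bundle.ecog, bundle.ios, bundle.lsci):
        for aid in sorted(store):
            obj = store[aid]
            if hasattr(obj, "data"):
                h.update(obj.data.tobytes())
            else:
                for name in sorted(obj.signals):
                    h.update(obj.signals[name].tobytes())
    return h.hexdigest()


def test_unit_preset_contents(unit_bundle):
    bundle, roster = unit_bundle
    assert len(roster.animals) == 1
    a = roster.animals[0]
    assert len(a.ecog_templates) == 2
    assert a.ecog_hours == 2.0
    assert bundle.ecog["u01"].monitored_post_occlusion_h == pytest.approx(2.0)


def test_same_seed_identical_different_seed_not():
    b1, _ = simulate_cohort("unit_test", 7)
    b2, _ = simulate_cohort("unit_test", 7)
    b3, _ = simulate_cohort("unit_test", 8)
    assert _hash_bundle(b1) == _hash_bundle(b2)
    assert _hash_bundle(b1) != _hash_bundle(b3)


def test_written_files_byte_identical(tmp_path):
    d1, d2 = tmp_path / "r1", tmp_path / "r2"
    simulate_cohort("unit_test", 3, out_dir=d1)
    simulate_cohort("unit_test", 3, out_dir=d2)
    files = sorted(p.name for p in d1.iterdir())
    assert files == sorted(p.name for p in d2.iterdir()) and files
    for name in files:
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_unknown_preset_and_bad_seed():
    with pytest.raises(ValueError):
        simulate_cohort("nope", 1)
    with pytest.raises(TypeError):
        simulate_cohort("unit_test", 1.5)


def test_arrival_times_are_exact_kinematics(layout):
    t = SDTemplate(
        event_id="e", modality="ecog", hemisphere="left", origin_mm=(0.0, -10.0),
        onset_min=10.0, speed_mm_per_min=3.0, target_expansion=1.0)
    for ch, arrival in t.arrival_times(layout).items():
        pos = layout.contacts[ch][1]
        dist = np.hypot(pos[0], pos[1] + 10.0)
        assert arrival == 600.0 + dist / 3.0 * 60.0  # exact, no tolerance


def test_collinear_strip_lag_is_exactly_200s():
    """Contacts collinear with the origin at 10 mm spacing and 3 mm/min give
    inter-contact onset lags of exactly 200 s in the roster arithmetic."""
    from sdwave.model import CorticalLayout

    contacts = {f"C{i}": ("right", (0.0, 10.0 + 10.0 * i)) for i in range(5)}
    rois = {"iL": ("left", (-5.0, 0.0)), "iR": ("right", (5.0, 0.0))}
    lay = CorticalLayout(contacts=contacts, rois_ios=rois,
                         rois_lsci={"roi1": ("right", (5.0, 5.0))},
                         occlusion_site=(0.0, 0.0))
    t = SDTemplate(event_id="e", modality="ecog", hemisphere="right",
                   origin_mm=(0.0, 0.0), onset_min=5.0, speed_mm_per_min=3.0,
                   target_expansion=1.0)
    arr = t.arrival_times(lay)
    lags = np.diff([arr[f"C{i}"] for i in range(5)])
    assert np.allclose(lags, 200.0, atol=0.0)  # exact arithmetic


def test_speed_outside_band_rejected():
    with pytest.raises(ValueError):
        SDTemplate(event_id="e", modality="ecog", hemisphere="left",
                   origin_mm=(0.0, 0.0), onset_min=1.0, speed_mm_per_min=50.0,
                   target_expansion=1.0)


def test_component_lag_order_enforced():
    with pytest.raises(ValueError):
        SDTemplate(
            event_id="e", modality="ios", hemisphere="left", origin_mm=(0.0, 0.0),
            onset_min=1.0, speed_mm_per_min=3.0, target_expansion=1.0,
            components=[ComponentSpec("II", -5.0, 1.0, 0.5),
                        ComponentSpec("I", 4.0, 0.7, 1.0)])


def test_optical_sign_convention_round_trip(layout):
    """Injected CBV pulses invert into intensity; converting back recovers
    the component sum exactly on a noiseless trace."""
    roster = _noise_free_roster(layout, components=[ComponentSpec("III", 18.0, 3.0, 0.0)])
    _, ios, _ = synthesize_animal(roster.animals[0], roster, seed=0,
                                  config=_noise_free_config())
    t = roster.animals[0].ios_templates[0]
    roi = t.reached_sensors(layout)[0]
    arrival = t.arrival_times(layout)[roi]
    trace = ios.trace(roi)
    i0 = ios.baseline_values[ios.roi_index(roi)]
    cbv = sdwave.to_cbv(trace, i0)
    tt = ios.times_s() - ios.occlusion_time_s - arrival
    expected = sdwave.component_pulse(tt, 18.0, 180.0)
    assert np.allclose(cbv, expected, atol=1e-9)
    # an 18 % CBV pulse is an 18 % intensity dip (up to the sampling grid)
    assert cbv.max() == pytest.approx(18.0, abs=0.01)


def test_hypoperfusion_then_hyperemia_baseline_transitions(layout):
    """A [II, III, IV] stack leaves the baseline upward (hypoperfusion =
    brighter) and then crosses it once downward into the main hyperemic
    intensity dip (numeric oracle on the noiseless trace)."""
    comps = sdwave.morphology_components("triphasic", 18.0, 3.0)
    roster = _noise_free_roster(layout, components=comps)
    _, ios, _ = synthesize_animal(roster.animals[0], roster, seed=0,
                                  config=_noise_free_config())
    t = roster.animals[0].ios_templates[0]
    roi = t.reached_sensors(layout)[0]
    trace = ios.trace(roi)
    i0 = ios.baseline_values[ios.roi_index(roi)]
    delta = trace - i0
    i_dip = int(np.argmin(delta))  # main hyperemic dip
    # hypoperfusion phase: intensity rises by ~6 % of baseline first
    assert delta[:i_dip].max() == pytest.approx(0.06 * i0, rel=0.01)
    signs = np.sign(delta[:i_dip])
    crossings = np.sum(np.abs(np.diff(signs[signs != 0])) > 0)
    assert crossings == 1  # one strict sign change between phases II and III


def test_zero_amplitude_lsci_template_is_noop(layout):
    roster = _noise_free_roster(layout, lsci=True,
                                components=[ComponentSpec("III", 0.0, 2.0, 0.0)])
    _, _, lsci = synthesize_animal(roster.animals[0], roster, seed=0,
                                   config=_noise_free_config())
    for name, base in (("CBF", 250.0), ("OxyHb", 80.0), ("deOxyHb", 40.0)):
        assert np.allclose(lsci.signals[name], base)


def test_truncated_event_flagged(layout):
    roster = _noise_free_roster(layout, onset_min=119.0)
    with pytest.warns(UserWarning, match="truncat"):
        synthesize_animal(roster.animals[0], roster, seed=0,
                          config=_noise_free_config())
    assert "truncated" in roster.animals[0].flags


# ---------------------------------------------------------------------------
# replication roster self-statistics (the acceptance surface, by construction)
# ---------------------------------------------------------------------------


def test_replication_roster_matches_printed_statistics():
    stats = build_paper_replication_roster().self_statistics()
    assert stats["ecog_event_count"] == 26
    assert stats["ios_event_count"] == 16
    assert stats["ecog_hours"] == pytest.approx(95.3)
    assert stats["ecog_hour1_count"] == 17
    assert stats["ecog_hours4to6_count"] == 0
    assert stats["ios_hours4to6_count"] == 0
    assert stats["ecog_mean_time_to_first_min"] == pytest.approx(49.3, abs=1e-9)
    assert stats["ecog_mean_expansion_pct"] == pytest.approx(69.4, abs=1e-9)
    assert abs(stats["ecog_incidence_per_h"] - 0.3) <= 0.05
    assert stats["ios_mean_expansion_pct"] == pytest.approx(85.8, abs=0.05)
    assert stats["monophasic_prevalence_pct"] == pytest.approx(31.25)
    assert stats["amp_first"] == pytest.approx(18.5, abs=1e-9)
    assert stats["amp_last"] == pytest.approx(16.3, abs=1e-9)
    assert stats["dur_first"] == pytest.approx(3.1, abs=1e-9)
    assert stats["dur_last"] == pytest.approx(8.3, abs=1e-9)
    assert stats["lsci_mean_cbf_elevation_pct"] == pytest.approx(61.5)
    assert stats["n_rois"] == 25


def test_replication_morphology_split_exact():
    counts = build_paper_replication_roster().morphology_counts()
    assert counts == {"monophasic": 25, "biphasic": 25,
                      "triphasic": 15, "tetraphasic": 15}


def test_replication_hour_profile():
    roster = build_paper_replication_roster()
    hourly = roster.hourly_counts("ecog")
    assert hourly[0] == 17 and hourly[1] == 2
    assert hourly[3:6].sum() == 0
    assert hourly.sum() == 26
    per_animal_h1 = roster.per_animal_hour_counts("ecog", 0)
    assert sum(1 for c in per_animal_h1 if c > 0) == 9  # SDs in 9/12 animals in hour 1


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _noise_free_config():
    return GeneratorConfig(ecog_broadband_sigma_mV=0.0, ecog_drift_amplitude_mV=0.0,
                           ios_noise_pct=0.0, ios_drift_pct_per_h=0.0, lsci_noise_pct=0.0)


def _noise_free_roster(layout, components=None, onset_min=10.0, lsci=False):
    a = AnimalGroundTruth(animal_id="x01", group=2, ios_hours=2.0,
                          lsci_hours=2.0 if lsci else None)
    kwargs = dict(origin_mm=(0.0, -3.0), onset_min=onset_min, speed_mm_per_min=4.0,
                  target_expansion=0.5)
    if lsci:
        t = SDTemplate(event_id="x01-lsci-1", modality="lsci", hemisphere="right",
                       origin_mm=(0.0, 0.0), onset_min=onset_min,
                       speed_mm_per_min=4.0, target_expansion=1.0,
                       components=components or [])
        a.lsci_templates.append(t)
    else:
        a.ios_templates.append(SDTemplate(
            event_id="x01-ios-1", modality="ios", hemisphere="left",
            components=components or [], **kwargs))
    return GroundTruthRoster(preset="custom", seed=0, layout=layout, animals=[a])
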