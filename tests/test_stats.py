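"""Cohort statistics: rank tests against brute-force enumeration oracles,
incidence bookkeeping, first/last comparison and summary invariants."""

from itertools import combinations, product

import numpy as np
import pytest

from sdwave import (
    SDEvent,
    incidence,
    first_last_comparison,
    mann_whitney_u,
    summarize,
    wilcoxon_signed_rank,
)
from sdwave.model import Component, HemodynamicResponse


# ---------------------------------------------------------------------------
# enumeration oracles (independent of scipy)
# ---------------------------------------------------------------------------


def wilcoxon_exact_oracle(d):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = [np.sum(ranks[np.array(signs, dtype=bool)])
          for signs in product([0, 1], repeat=d.size)]
    ws = np.array(ws)
    p_lo = np.mean(ws <= w_obs)
    p_hi = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(p_lo, p_hi))


def mannwhitney_exact_oracle(a, b):
    """Two-sided rank-sum p by enumerating all label assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n_a = a.size

    def u_of(idx):
        x = pooled[list(idx)]
        y = np.delete(pooled, list(idx))
        return sum((xi > y).sum() + 0.5 * (xi == y).sum() for xi in x)

    u_obs = u_of(range(n_a))
    us = np.array([u_of(idx) for idx in combinations(range(pooled.size), n_a)])
    p_lo = np.mean(us <= u_obs)
    p_hi = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_lo, p_hi))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def test_wilcoxon_all_zero_differences():
    with pytest.warns(UserWarning, match="zero"):
        w, p = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == 1.0


def test_wilcoxon_three_pairs_exact():
    # pairs (2,0), (1,0), (3,0): all eight sign assignments enumerable by hand
    w, p = wilcoxon_signed_rank([2.0, 1.0, 3.0], [0.0, 0.0, 0.0])
    assert p == pytest.approx(wilcoxon_exact_oracle([2.0, 1.0, 3.0]))
    assert p == pytest.approx(0.25)


def test_wilcoxon_sign_flip_antisymmetry():
    rng = np.random.default_rng(1)
    d = rng.normal(0.3, 1.0, 10)
    _, p_pos = wilcoxon_signed_rank(d)
    _, p_neg = wilcoxon_signed_rank(-d)
    assert p_pos == pytest.approx(p_neg)


@pytest.mark.parametrize("n", [4, 6, 8])
def test_wilcoxon_matches_enumeration_oracle(n):
    rng = np.random.default_rng(n)
    for _ in range(5):
        d = rng.normal(0.5, 1.0, n)
        _, p = wilcoxon_signed_rank(d)
        assert p == pytest.approx(wilcoxon_exact_oracle(d), abs=1e-12)


def test_wilcoxon_exact_vs_normal_approx_at_crossover():
    rng = np.random.default_rng(5)
    d = rng.normal(0.4, 1.0, 15)
    _, p_exact = wilcoxon_signed_rank(d)  # n = 15: exact path
    from scipy.stats import wilcoxon as scipy_wilcoxon

    p_approx = scipy_wilcoxon(d, method="approx", correction=True).pvalue
    assert abs(p_exact - p_approx) <= 0.02


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def test_mannwhitney_identical_groups():
    u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert u == pytest.approx(4.5)  # n_a * n_b / 2 under full ties
    assert p == pytest.approx(1.0)


def test_mannwhitney_separated_groups_exact_third():
    u, p = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
    assert u == 0.0
    assert p == pytest.approx(1.0 / 3.0)
    assert p == pytest.approx(mannwhitney_exact_oracle([1, 2], [3, 4]))


def test_mannwhitney_label_swap():
    a, b = [1.0, 5.0, 2.5], [3.0, 4.0, 0.5, 6.0]
    u_ab, p_ab = mann_whitney_u(a, b)
    u_ba, p_ba = mann_whitney_u(b, a)
    assert u_ab + u_ba == len(a) * len(b)
    assert p_ab == pytest.approx(p_ba)


@pytest.mark.parametrize("na,nb", [(3, 3), (4, 4), (3, 5)])
def test_mannwhitney_matches_enumeration_oracle(na, nb):
    rng = np.random.default_rng(na * 10 + nb)
    for _ in range(5):
        a = rng.normal(0.5, 1.0, na)
        b = rng.normal(0.0, 1.0, nb)
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(mannwhitney_exact_oracle(a, b), abs=1e-12)


def test_mannwhitney_exact_vs_asymptotic_at_crossover():
    rng = np.random.default_rng(5)
    rng.normal(size=15)  # advance the stream; keep values moderate
    a = rng.normal(0.5, 1.0, 6)
    b = rng.normal(0.0, 1.0, 6)
    _, p_exact = mann_whitney_u(a, b)  # n_a + n_b = 12: exact path
    from scipy.stats import mannwhitneyu as scipy_mwu

    p_approx = scipy_mwu(a, b, method="asymptotic", use_continuity=True).pvalue
    assert abs(p_exact - p_approx) <= 0.02


# ---------------------------------------------------------------------------
# incidence
# ---------------------------------------------------------------------------


def _events(spec):
    out = []
    for aid, onsets_min in spec.items():
        for k, onset in enumerate(onsets_min):
            out.append(SDEvent(
                event_id=f"{aid}-{k}", modality="ecog", animal_id=aid,
                hemisphere="left", onsets_s={"L1": onset * 60.0, "L2": onset * 60.0 + 100},
                expansion_pct=60.0))
    return out


def test_incidence_hour1_mean():
    # 17 events in hour one over 12 monitored animals -> 1.4167 per animal
    spec = {f"a{i:02d}": [] for i in range(1, 13)}
    h1 = [3, 3, 2, 2, 2, 2, 1, 1, 1]
    for aid, c in zip(list(spec)[:9], h1):
        spec[aid] = [5.0 + 2 * j for j in range(c)]
    res = incidence(_events(spec), {aid: 8.0 for aid in spec})
    assert res.hour_mean_per_animal(0) == pytest.approx(17 / 12)
    assert res.hourly_total[0] == 17


def test_incidence_zero_events_and_bookkeeping():
    res = incidence([], {"a1": 5.0, "a2": 7.0})
    assert res.cohort_rate_mean == 0.0
    spec = {"a1": [10.0, 70.0, 130.0], "a2": [30.0]}
    res = incidence(_events(spec), {"a1": 8.0, "a2": 4.0})
    assert res.hourly_total.sum() == 4  # hourly counts sum to the total
    assert res.per_animal_rate["a1"] == pytest.approx(3 / 8)
    with pytest.raises(KeyError):
        incidence(_events({"ghost": [10.0]}), {"a1": 8.0})


# ---------------------------------------------------------------------------
# first/last comparison and summary
# ---------------------------------------------------------------------------


def _response(aid, roi, onset_s, amp, dur):
    return HemodynamicResponse(
        roi_id=roi, event_id=f"{aid}-{onset_s}", animal_id=aid, hemisphere="left",
        components=[Component("III", onset_s, amp, dur)], morphology="monophasic",
        baseline_value=120.0, noise_sigma=0.5, event_onset_s=onset_s)


def test_first_last_pairs_and_identical_sets():
    responses = []
    for roi in ("r1", "r2", "r3"):
        responses.append(_response("a1", roi, 600.0, 18.0, 3.0))
        responses.append(_response("a1", roi, 7200.0, 18.0, 3.0))
    res = first_last_comparison(responses)
    assert len(res.rois) == 3
    assert res.amp_test[1] == pytest.approx(1.0)  # identical sets: p = 1 (ties)


def test_first_last_requires_two_events_per_roi():
    responses = [_response("a1", "r1", 600.0, 18.0, 3.0),
                 _response("a1", "r2", 600.0, 18.0, 3.0),
                 _response("a1", "r2", 900.0, 16.0, 8.0)]
    res = first_last_comparison(responses)
    assert res.rois == [("a1", "r2")]
    assert res.amp_first[0] == 18.0 and res.amp_last[0] == 16.0


def test_summary_totals_and_permutation_invariance():
    spec = {"a1": [10.0, 70.0], "a2": [30.0], "a3": []}
    events = _events(spec)
    hours = {"a1": 8.0, "a2": 6.0, "a3": 7.0}
    s1 = summarize({"ecog": events}, {"ecog": hours})
    s2 = summarize({"ecog": list(reversed(events))}, {"ecog": dict(reversed(hours.items()))})
    assert s1.event_counts == s2.event_counts == {"ecog": 3}
    assert s1.incidence_by_modality["ecog"].cohort_rate_mean == pytest.approx(
        s2.incidence_by_modality["ecog"].cohort_rate_mean)
    assert s1.as_dict()["ecog_hourly_total"] == s2.as_dict()["ecog_hourly_total"]


def test_summary_empty_inputs_are_valid():
    s = summarize({"ecog": []}, {"ecog": {"a1": 5.0}})
    d = s.as_dict()
    assert d["event_counts"] == {"ecog": 0}
    assert d["pooled_incidence_per_h"]["ecog"] == 0.0


def test_summary_morphology_prevalence_sums_to_100():
    responses = [_response("a1", f"r{i}", 600.0 * (i + 1), 18.0, 3.0) for i in range(4)]
    responses[0].morphology = "biphasic"
    s = summarize({"ios": _events({"a1": [10.0, 40.0]})},
                  {"ios": {"a1": 8.0}}, responses=responses)
    assert sum(s.morphology_prevalence_pct.values()) == pytest.approx(100.0)
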