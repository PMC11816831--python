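"""Cohort metrics: incidence, expansion, hourly profiles, first-vs-last SD
comparisons and the study's nonparametric tests.

Conventions follow the exploratory-study design: two-sided p-values, no
multiple-testing correction, means reported with across-animal (or
across-ROI, for first/last response metrics) standard deviations. Rank
tests use exact null enumeration at small sample sizes and the tie-corrected
normal approximation above (delegated to scipy.stats).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .model import HemodynamicResponse, SDEvent
from .optical import hyperemia_metrics

__all__ = [
    "wilcoxon_signed_rank", "mann_whitney_u",
    "incidence", "IncidenceResult",
    "first_last_comparison", "FirstLastResult",
    "summarize", "CohortSummary", "write_summary",
]

#: largest n for exact signed-rank enumeration (2^n sign patterns)
WILCOXON_EXACT_N = 15
#: largest n_a + n_b for exact rank-sum enumeration
MANNWHITNEY_EXACT_N = 12


def wilcoxon_signed_rank(x, y=None) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples (or differences).

    Zero differences are dropped; if every difference is zero the test is
    degenerate and (0, p=1) is returned with a warning. Exact enumeration up
    to n = 15 non-zero differences, normal approximation with continuity
    correction above.
    """
    d = np.asarray(x, dtype=float) - (0.0 if y is None else np.asarray(y, dtype=float))
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; signed-rank test degenerate",
                      stacklevel=2)
        return 0.0, 1.0
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= WILCOXON_EXACT_N and not ties) else "approx"
    res = sstats.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    Exact enumeration when n_a + n_b <= 12 and no ties cross the groups,
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= MANNWHITNEY_EXACT_N and not ties) else "asymptotic"
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                              use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class IncidenceResult:
    per_animal_rate: dict[str, float]  # SDs per monitored hour
    per_animal_count: dict[str, int]
    hourly_counts: dict[str, np.ndarray]  # per animal, binned from occlusion
    cohort_rate_mean: float
    cohort_rate_std: float
    hourly_total: np.ndarray

    def hour_mean_per_animal(self, hour: int) -> float:
        return float(np.mean([c[hour] for c in self.hourly_counts.values()]))


def incidence(
    events: list[SDEvent],
    monitored_hours: dict[str, float],
    n_hours: int | None = None,
) -> IncidenceResult:
    """Per-animal incidence (SDs/h) and hourly event profile.

    ``monitored_hours`` must list *every* monitored animal (zero-event
    animals count in the cohort mean). Hour bins are anchored at the
    occlusion time; an event is binned by its earliest sensor onset.
    """
    if n_hours is None:
        n_hours = max(1, int(np.ceil(max(monitored_hours.values(), default=1.0))))
    counts = {aid: 0 for aid in monitored_hours}
    hourly = {aid: np.zeros(n_hours, dtype=int) for aid in monitored_hours}
    for e in events:
        if e.animal_id not in counts:
            raise KeyError(f"event {e.event_id}: animal {e.animal_id} not in monitored_hours")
        counts[e.animal_id] += 1
        h = int(e.onset_s // 3600)
        if h < n_hours:
            hourly[e.animal_id][h] += 1
    rates = {aid: counts[aid] / monitored_hours[aid] for aid in monitored_hours}
    rate_values = np.array(list(rates.values()))
    return IncidenceResult(
        per_animal_rate=rates,
        per_animal_count=counts,
        hourly_counts=hourly,
        cohort_rate_mean=float(rate_values.mean()),
        cohort_rate_std=float(rate_values.std(ddof=1)) if rate_values.size > 1 else 0.0,
        hourly_total=np.sum(list(hourly.values()), axis=0),
    )


@dataclass
class FirstLastResult:
    """Per-ROI first-vs-last SD hyperemia comparison.

    Restricted to ROIs observing at least two SDs within one hemisphere;
    amplitude/duration sets are compared with the Mann-Whitney U test.
    """

    rois: list[tuple[str, str]]  # (animal, roi)
    amp_first: np.ndarray
    amp_last: np.ndarray
    dur_first_min: np.ndarray
    dur_last_min: np.ndarray
    amp_test: tuple[float, float] = (float("nan"), float("nan"))
    dur_test: tuple[float, float] = (float("nan"), float("nan"))

    def means(self) -> dict[str, float]:
        out = {}
        for name, v in (("amp_first", self.amp_first), ("amp_last", self.amp_last),
                        ("dur_first_min", self.dur_first_min),
                        ("dur_last_min", self.dur_last_min)):
            out[f"{name}_mean"] = float(np.mean(v)) if v.size else float("nan")
            out[f"{name}_std"] = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return out


def first_last_comparison(responses: list[HemodynamicResponse]) -> FirstLastResult:
    """Build the per-ROI (first, last) hyperemia table and run the tests."""
    by_roi: dict[tuple[str, str], list[HemodynamicResponse]] = {}
    for r in responses:
        by_roi.setdefault((r.animal_id, r.roi_id), []).append(r)
    rois, af, al, df, dl = [], [], [], [], []
    for key, rs in sorted(by_roi.items()):
        hemis = {r.hemisphere for r in rs}
        if len(rs) < 2 or len(hemis) != 1:
            continue
        rs = sorted(rs, key=lambda r: r.event_onset_s)
        first, last = rs[0], rs[-1]
        if first.component("III") is None or last.component("III") is None:
            continue
        a1, d1 = hyperemia_metrics(first)
        a2, d2 = hyperemia_metrics(last)
        rois.append(key)
        af.append(a1)
        al.append(a2)
        df.append(d1)
        dl.append(d2)
    result = FirstLastResult(
        rois=rois, amp_first=np.array(af), amp_last=np.array(al),
        dur_first_min=np.array(df), dur_last_min=np.array(dl),
    )
    if len(rois) >= 2:
        result.amp_test = mann_whitney_u(result.amp_first, result.amp_last)
        result.dur_test = mann_whitney_u(result.dur_first_min, result.dur_last_min)
    return result


@dataclass
class CohortSummary:
    """Pooled cohort report across modalities."""

    n_animals: dict[str, int] = field(default_factory=dict)
    event_counts: dict[str, int] = field(default_factory=dict)
    incidence_by_modality: dict[str, IncidenceResult] = field(default_factory=dict)
    expansion_by_modality: dict[str, dict[str, float]] = field(default_factory=dict)
    pooled_incidence: dict[str, float] = field(default_factory=dict)
    morphology_prevalence_pct: dict[str, float] = field(default_factory=dict)
    first_last: FirstLastResult | None = None
    tests: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "n_animals": self.n_animals,
            "event_counts": self.event_counts,
            "pooled_incidence_per_h": self.pooled_incidence,
            "morphology_prevalence_pct": self.morphology_prevalence_pct,
            "tests": {k: {"statistic": v[0], "p": v[1]} for k, v in self.tests.items()},
        }
        for mod, inc in self.incidence_by_modality.items():
            out[f"{mod}_incidence_mean_per_h"] = inc.cohort_rate_mean
            out[f"{mod}_incidence_std_per_h"] = inc.cohort_rate_std
            out[f"{mod}_hourly_total"] = [int(c) for c in inc.hourly_total]
        for mod, exp in self.expansion_by_modality.items():
            out[f"{mod}_expansion"] = exp
        if self.first_last is not None:
            out["first_last"] = self.first_last.means()
            out["first_last"]["n_rois"] = len(self.first_last.rois)
            out["first_last"]["amp_p"] = self.first_last.amp_test[1]
            out["first_last"]["dur_p"] = self.first_last.dur_test[1]
        return out


def _per_animal_expansion(events: list[SDEvent]) -> dict[str, float]:
    by_animal: dict[str, list[float]] = {}
    for e in events:
        by_animal.setdefault(e.animal_id, []).append(e.expansion_pct)
    return {aid: float(np.mean(v)) for aid, v in by_animal.items()}


def summarize(
    events_by_modality: dict[str, list[SDEvent]],
    monitored_hours_by_modality: dict[str, dict[str, float]],
    responses: list[HemodynamicResponse] | None = None,
) -> CohortSummary:
    """Aggregate detections into the cohort summary.

    Expansion means average within animal first, then across animals with at
    least one event; incidence is reported both as the mean of per-animal
    rates and pooled (total events / total hours).
    """
    summary = CohortSummary()
    for mod, events in events_by_modality.items():
        hours = monitored_hours_by_modality[mod]
        summary.n_animals[mod] = len(hours)
        summary.event_counts[mod] = len(events)
        inc = incidence(events, hours)
        summary.incidence_by_modality[mod] = inc
        total_h = sum(hours.values())
        summary.pooled_incidence[mod] = len(events) / total_h if total_h else 0.0
        exp = _per_animal_expansion(events)
        values = np.array(list(exp.values()))
        summary.expansion_by_modality[mod] = {
            "per_animal_mean_pct": float(values.mean()) if values.size else float("nan"),
            "per_animal_std_pct": float(values.std(ddof=1)) if values.size > 1 else 0.0,
            "n_animals_with_events": int(values.size),
        }
        # first vs second hour, per animal (the study's paired comparison)
        h1 = [inc.hourly_counts[a][0] for a in hours]
        h2 = [inc.hourly_counts[a][1] if inc.hourly_counts[a].size > 1 else 0 for a in hours]
        if any(np.asarray(h1) != np.asarray(h2)):
            summary.tests[f"{mod}_incidence_h1_vs_h2"] = wilcoxon_signed_rank(h1, h2)
        # hemisphere comparison on per-event expansion
        left = [e.expansion_pct for e in events if e.hemisphere == "left"]
        right = [e.expansion_pct for e in events if e.hemisphere == "right"]
        if left and right:
            summary.tests[f"{mod}_expansion_left_vs_right"] = mann_whitney_u(left, right)
    if responses:
        counts: dict[str, int] = {}
        for r in responses:
            counts[r.morphology] = counts.get(r.morphology, 0) + 1
        total = sum(counts.values())
        summary.morphology_prevalence_pct = {
            m: 100.0 * c / total for m, c in sorted(counts.items())
        }
        summary.first_last = first_last_comparison(responses)
        if len(summary.first_last.rois) >= 2:
            summary.tests["hyperemia_amp_first_vs_last"] = summary.first_last.amp_test
            summary.tests["hyperemia_dur_first_vs_last"] = summary.first_last.dur_test
    return summary


def write_summary(summary: CohortSummary, path) -> None:
    """Write the summary as JSON plus a CSV table of per-animal rates."""
    import json
    from pathlib import Path

    path = Path(path)
    path.write_text(json.dumps(summary.as_dict(), indent=1, sort_keys=True))
    rows = ["modality,animal_id,events,rate_per_h"]
    for mod, inc in summary.incidence_by_modality.items():
        for aid in sorted(inc.per_animal_rate):
            rows.append(f"{mod},{aid},{inc.per_animal_count[aid]},"
                        f"{inc.per_animal_rate[aid]:.6g}")
    path.with_suffix(".csv").write_text("\n".join(rows) + "\n")
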