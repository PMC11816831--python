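# sdwave

Detection and hemodynamic characterization of **spreading depolarizations
(SDs)** in multimodal cortical recordings from gyrencephalic (swine)
venous-occlusion experiments:

* **ECoG** — DC-coupled electrocorticography from two 5-contact subdural
  strips: SDs appear as negative slow potential changes (SPCs) of a few mV
  with depression of spontaneous activity, propagating across contacts at
  mm/min speeds;
* **IOS** — intrinsic optical signal imaging at 564 nm (total-hemoglobin
  isosbestic point), a cerebral blood volume surrogate where an intensity
  *decrease* means hyperemia;
* **LSCI** — laser speckle contrast imaging with oxygenation estimation
  (CBF / OxyHb / deOxyHb in arbitrary perfusion units).

The package is aimed at experimental neurophysiology groups analyzing
post-occlusion recordings: it detects SD events per modality, computes
incidence (SDs/h) and expansion (% of channels/ROIs reached), decomposes
each IOS response into the canonical vasomotor components — I brief
hyperemia, II initial hypoperfusion, III peak hyperemia, IV late hyperemia,
V post-SD oligemia — classifies the four observed morphologies
(monophasic `[III]`, biphasic `[III,IV]`, triphasic `[II,III,IV]`,
tetraphasic `[I,II,III,IV]`), and runs the cohort statistics (Wilcoxon
signed-rank for first-vs-second-hour comparisons, Mann-Whitney U for
hemisphere and first-vs-last-SD comparisons, two-sided, uncorrected).

Core quantities, in the field's notation:

* CBV percent scale: `cbv(t) = -(I(t) - I0)/I0 * 100`, `I0` the robust
  (median/MAD) event-free baseline; deviations are segments with
  `|cbv| >= 3 sigma` for >= 20 s, and an SD requires such deviations on
  >= 2 ROIs with pairwise onset lags consistent with a 1-10 mm/min wave.
* Expansion: `100 * reached / hemisphere sensors`; incidence: per-animal
  `count / monitored hours`, averaged across animals.
* Peak-hyperemia amplitude and duration: the amplitude and width at half
  maximum of component III's own fitted pulse.
* LSCI percent elevation: `100 * (peak - baseline) / baseline` per ROI.

Because no public SD recordings of this preparation exist, the package
ships a first-class synthetic-data module: kinematic SD waves (arrival at a
sensor is exactly `onset + distance/speed`) injected into realistic noise,
with a fixed `paper_replication` cohort whose ground truth encodes the
study's printed results, and full ground-truth rosters for every run.

## Worked example

```
$ python examples/replication_cohort_summary.py
Replication cohort, seed 1
  ECoG SDs detected:          26
  IOS SDs detected:           16
  ECoG expansion (per-animal mean): 69.4%
  IOS expansion (per-animal mean):  85.8%
  incidence (mean of per-animal rates): 0.30 SDs/h
  hour-1 mean SDs/animal:     1.42
  first-SD peak hyperemia:    18.5% of baseline
  last-SD hyperemia duration: 8.3 min
  LSCI CBF elevation (4-ROI mean): 61.3%
  monophasic responses:       31.25% of 80

Hourly ECoG profile (events per hour post-occlusion): [17, 2, 4, 0, 0, 0, 3, 0, 0]
  ecog_incidence_h1_vs_h2: statistic=0.0, p=0.008
  ecog_expansion_left_vs_right: statistic=86.5, p=0.909
  ios_incidence_h1_vs_h2: statistic=0.0, p=0.053
  ios_expansion_left_vs_right: statistic=19.0, p=0.162
  hyperemia_amp_first_vs_last: statistic=380.0, p=0.194
  hyperemia_dur_first_vs_last: statistic=39.0, p=0.000
```

Reading the output: all 26 injected ECoG and 16 IOS SDs are recovered with
no false positives; events cluster in the first post-occlusion hour and
vanish in hours 4–6; SD incidence drops significantly from hour 1 to hour 2
(p = 0.008) while expansion does not differ between hemispheres; and from
each ROI's first to last SD the peak-hyperemia *amplitude* is statistically
unchanged (p = 0.19) while its *duration* lengthens markedly (p < 0.001) —
the qualitative signature of SDs under venous congestion rather than
arterial ischemia.

Smaller examples, one per capability:

* `examples/detect_ecog_events.py` — slow-potential-change scoring and
  propagation grouping on one animal;
* `examples/classify_ios_morphologies.py` — component decomposition and
  morphology classification of IOS responses;
* `examples/lsci_perfusion_response.py` — CBF elevation, oxygenation
  coupling and chronological LSCI-ECoG matching.

The library surface mirrors the pipeline: `simulate_cohort` /
`iter_animals` (synthesis), `detect_sd_ecog`, `group_sd_ios` +
`analyze_responses`, `detect_sd_lsci`, `match_modalities`, and
`summarize`. File I/O (CSV time series with JSON sidecars, multi-page TIFF
stacks, JSON events/rosters) lives in `sdwave.io`.

## Layout

```
src/sdwave/     model, layout, pulses, noise, inject, roster, cohort  (synthesis)
                grouping, ecog, optical, lsci                         (detection)
                stats, replication, io                                (aggregation, I/O)
tests/          unit + property suites, replication acceptance suite
examples/       narrative scripts (see above)
docs/methods.md model assumptions, parameter defaults, design choices, limits
```
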