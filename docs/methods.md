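# Methods

`sdwave` detects and characterizes spreading depolarizations (SDs) in three
kinds of cortical recordings made after experimental occlusion of the
superior sagittal sinus in a gyrencephalic (swine) preparation: DC-coupled
electrocorticography (ECoG) from two parasagittal 5-contact subdural strips,
intrinsic optical signal (IOS) imaging at the 564 nm hemoglobin isosbestic
wavelength, and laser speckle contrast imaging with oxygenation estimation
(LSCI). A synthetic-data module simulates the whole post-occlusion
experiment with exact ground truth, so every pipeline stage is testable
without animal data.

## Signal model and conventions

Time is seconds from recording start; events are reported in minutes
post-occlusion. Sensor coordinates are millimetres in a craniotomy plane
with the midline at x = 0 and the occlusion site on the midline.

An SD is modelled kinematically: it starts at an origin near the occlusion
site at a given onset and travels at a constant speed of a few mm/min
(plausibility band 1–10 mm/min, defaults 3–6 in the synthetic cohort). A
sensor at distance *d* is reached at exactly `onset + d / speed`; the
wavefront stops after reaching a target fraction of the hemisphere's
sensors, which defines the event's *expansion* (percentage of channels/ROIs
reached; the default denominator is the event's hemisphere).

Signatures per modality:

* **ECoG** — a negative slow potential change (SPC): fast fall (10 s) to a
  depth of several mV, plateau, slower recovery; total duration ~90 s.
  Superimposed broadband activity (pink-noise surrogate) is suppressed to a
  residual fraction (default 0.2) for ~3 min — the spreading depression of
  activity.
* **IOS** — at 564 nm, reflected intensity tracks total hemoglobin, so
  intensity is converted to a CBV-positive percent scale,
  `cbv = -(I - I0)/I0 * 100` (hyperemia positive). Responses are sums of
  vasomotor component pulses: I brief initial hyperemia, II initial
  hypoperfusion, III peak hyperemia, IV late hyperemia, V post-SD oligemia.
* **LSCI** — a monophasic CBF rise returning to baseline, with OxyHb
  co-varying positively and deOxyHb negatively with a small (10 s) lag.
  Perfusion units are arbitrary (APU), so only per-animal percentages are
  reported.

### Component pulse shape

Hemodynamic component pulses are a linear rise (default 10 s) followed by a
half-Gaussian decay, parameterized by signed peak amplitude (% of baseline)
and full width at half maximum (FWHM). The shape is smooth, asymmetric
(fast rise, slow return) and strictly causal, and two properties hold in
closed form: the foot sits exactly at the component onset, and the FWHM
equals the requested value (`rise/2` up + `tau*sqrt(2 ln 2)` down). The
linear foot is what lets onset estimators recover arrival times to a
fraction of a sample; a log-normal-like shape with an asymptotic foot has no
well-defined arrival to recover. The late hyperemia (IV) is generated at
0.45× the amplitude of the peak hyperemia it is superimposed on, lagging it
by 1.8 FWHM — a late phase larger than the peak would contradict the
morphology taxonomy in which component III is by definition the dominant
peak.

## Detection

### ECoG

Slow-potential scoring runs on a near-DC trace: zero-phase 0.5 Hz low-pass,
decimation to 2 Hz, minus a 10-minute rolling-median baseline. The median
window is long relative to the deflection (a 90 s pulse occupies ~15 % of
it), so the baseline tracks slow electrode drift without eating the pulse.
We deliberately do *not* score on the 0.05–0.5 Hz display band used for
visual figures: a zero-phase 0.05 Hz high-pass reduces a 90 s, 5 mV
deflection to ~0.6 mV, which is incompatible with any mV-scale sustained
criterion. `slow_band` still provides that display band (0.2 Hz gain
≥ 0.9, ≥ 20 dB attenuation at 5 Hz, DC removed).

An SPC candidate is a negative deflection ≥ 2 mV sustained 30 s–5 min.
Published consortium scoring recommendations define the signature verbally;
these numeric defaults make them explicit and tunable. Each candidate is
annotated with concurrent depression of 0.5–45 Hz activity power (binned at
10 s, compared with its 10-min rolling median; depression = ≤ 50 % for
≥ 2 min). By default candidates without confirmed depression are kept as
"possible" events (`strictness="confirmed"` drops them). The activity-band
upper edge is capped at 0.4 fs so the same code handles decimated
recordings.

Onsets are recovered by leading-edge extrapolation: a line fitted to the
20–80 % section of the leading edge, extrapolated to zero. The fit is
restricted to the first crossing of the 80 % level so post-peak samples
cannot flatten the edge.

### Optical traces (IOS, LSCI)

Per-ROI baselines are the median and robust scale (1.4826·MAD) over
event-free samples (default: the pre-occlusion window; a too-short window
widens to the whole trace with a warning — the median is robust to the
events themselves). Deviations are maximal contiguous segments with
|cbv| ≥ kσ (k = 3) for ≥ 20 s; opposite polarities are kept separate.
Segments separated by < 7 min are merged into one *response*; each
response's onset is sharpened by a local least-squares fit of one pulse per
leading segment (the first two segments jointly, so an adjacent opposite-
polarity phase is modeled rather than contaminating the tail; the edge
extrapolation alone is noise-limited for small components).

### Propagation grouping (shared)

Per-sensor detections are merged greedily in onset order: a candidate joins
an event only if, against every current member, the implied speed
`distance/lag` lies in the 1–10 mm/min band, the hemisphere matches (SDs do
not cross the midline), and the sensor is unused. Events require ≥ 2
sensors; leftovers are reported as orphans. Because grouping uses
sensor-to-sensor distances while the wave travels from an origin, near-
equidistant sensor pairs would imply unphysically high speeds; the synthetic
geometry places origins behind the sensor arrays so distance differences
approximate sensor separations (worst-case inflation ×1.22, still inside
the band at the simulated 3–6 mm/min).

### Decomposition and classification

Within each response window, local extrema of a 15 s-smoothed CBV trace
with height ≥ 3σ, prominence ≥ max(2σ, 5 % of the response magnitude) and
≥ 60 s separation are labeled by ordered rules: the largest positive peak
is III; a positive peak before any trough and before III is I; a trough
before III is II; a positive peak after III is IV; a sustained terminal
trough is V. A sum of component pulses (kinds fixed, onset/amplitude/FWHM
free, plus a constant offset absorbing residual drift) is then jointly
least-squares fitted; components whose fitted amplitude drops below the
deviation threshold are pruned and the rest refitted. Each component
therefore carries its *own* peak amplitude and half-maximum duration — a
superimposed late hyperemia does not inflate the peak-hyperemia duration.
"Duration" is width at half maximum throughout (the generator uses the same
definition, keeping synthetic targets self-consistent).

Morphology is a pure function of the component-kind sequence: [III]
monophasic, [III,IV] biphasic, [II,III,IV] triphasic, [I,II,III,IV]
tetraphasic, anything else "other". The first/last-SD comparison uses only
ROIs observing ≥ 2 SDs within one hemisphere.

### Statistics

Incidence is reported both as the mean of per-animal rates (counts /
monitored hours, zero-event animals included) and pooled; per-animal
expansion is the mean over that animal's events, averaged across animals
with ≥ 1 event. First-vs-second-hour comparisons use the Wilcoxon
signed-rank test; hemisphere and first-vs-last comparisons use the
Mann-Whitney U test. Both are two-sided with no multiple-testing
correction (the analysis is exploratory), use exact enumeration at small n
(≤ 15 non-zero pairs; ≤ 12 pooled, no ties) and the tie-corrected normal
approximation above, delegated to scipy.stats; brute-force enumeration
oracles in the test suite verify the exact path.

## Synthetic cohort

The generator's defaults *are* the study conditions. The
`paper_replication` roster is a fixed table — onsets, reach counts and
per-ROI component parameters are not sampled — constructed so the roster's
own statistics equal the reported cohort results:

* 12 ECoG animals (groups 1–2), 95.3 monitored hours, 26 SDs; 17 in hour
  one across 9 animals, 2 in hour two, none in hours 4–6; mean time to
  first SD exactly 49.3 min; per-animal expansion mean exactly 69.4 %;
  per-animal incidence mean 0.297 SDs/h.
* 6 IOS animals, 38.3 h, 16 SDs summing to 80 ROI-level responses with a
  25/25/15/15 morphology split (monophasic and biphasic 5/16 each
  = 31.25 %); per-animal expansion mean 85.83 %; per-eligible-ROI first/
  last peak-hyperemia amplitudes with means exactly 18.5 / 16.3 % and
  half-maximum durations exactly 3.1 / 8.3 min (symmetric spreads around
  the means give realistic dispersion).
* one analyzable LSCI animal (2.5 h): a single SD at 9 min post-occlusion
  crossing roi4→roi1, per-ROI CBF elevations (83.5, 71.4, 51.6, 39.5) %
  with mean 61.5 and STD 19.7, and a paired ECoG detection at 12 min for
  cross-modal matching.

The user seed drives measurement noise only (one substream per animal);
the roster never changes. Noise: pink (1/f) broadband ECoG noise
(σ = 0.05 mV) via the classic three-pole pinking filter, bounded-slope
sinusoidal drift (≤ 0.2 mV/min); white optical noise (σ = 0.5 % of
baseline) with ≤ 0.1 %/h linear drift per ROI; 1 % white LSCI noise. The
decomposition's per-window constant offset absorbs the optical drift.

Conventions the roster fixes where the study design leaves freedom: contact
spacing 10 mm and all coordinates (only counts are reported); ECoG events
alternate hemispheres within an animal while each animal's IOS events sit in
one hemisphere (3 left / 3 right animals, 8/8 events) so ROIs accumulate
the ≥ 2 SDs the first/last analysis needs; the morphology-prevalence
denominator is ROI-level responses; the expansion denominator is the
event's hemisphere. The 61.5 %/49.3-min/69.4 %-style quantities are exact
by construction; the IOS mean time to first SD is the one printed quantity
a 9 h recording cap cannot reproduce (roster value ≈ 93 min), and it enters
no recovery target. ECoG and IOS ground-truth event streams are generated
independently per animal: the reported cohort statistics are
modality-specific, and nothing in the analysis couples the streams (LSCI↔
ECoG matching gets its own paired templates).

### Problem sizes

The synthetic ECoG is generated at 20 Hz — all analysis bands sit below
8 Hz, and detection further decimates to 2 Hz — which keeps a ~100
channel-hour cohort comfortably simulable; real 1000 Hz recordings are
handled by the identical code path. A full replication run (simulate +
detect + aggregate, all modalities) takes ~20 s; recovery statistics are
averaged over 20 noise seeds.

## What the synthetic data do and do not show

The generator exercises baseline estimation, thresholding, propagation
grouping, decomposition and the cohort statistics under realistic noise,
drift and event geometry. It does **not** emulate: breathing/pulsation
motion and its elastic-registration residuals (a motion-QC stage flags bulk
shifts and excludes intervals, but compensation itself is out of scope),
electrode artifacts beyond drift, seizure activity, vascular heterogeneity
across ROIs, or model mismatch between real vasomotor transients and the
rise/decay pulse family (the decomposition fit is exact on synthetic pulses
by construction; on real data the fitted FWHM depends on that family being
adequate). Passing recovery on this cohort shows the pipeline is correct
and self-consistent, not that its thresholds are optimal for any particular
laboratory's recordings — all thresholds are exposed in the config objects.

## Degenerate inputs and numerical choices

Readers reject NaN/Inf with located errors; CSV round-trips are bit-exact
(`%.17g`); IOS TIFF stacks quantize to 8 bits. Zero-length candidate sets,
empty event lists and all-zero paired differences produce valid empty
outputs (p = 1 with a warning for the degenerate test). Events whose
arrivals fall beyond the recorded span are truncated and flagged, not
dropped silently. All fits are bounded least squares with analytic seeds;
failures fall back to the rule-based estimates.
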