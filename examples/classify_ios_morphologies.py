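"""Decompose and classify IOS hemodynamic responses to spreading depolarization.

Simulates one animal with a tetraphasic and a monophasic SD, detects both
with the >= 2-ROI rule, decomposes each ROI's response into vasomotor
components (I brief hyperemia, II initial hypoperfusion, III peak hyperemia,
IV late hyperemia) and classifies the morphology.
"""

import sdwave

bundle, roster = sdwave.simulate_cohort("unit_test", seed=1)
ios = bundle.ios["u01"]
events, windows = sdwave.group_sd_ios(ios, roster.layout)
responses = sdwave.analyze_responses(ios, events, windows)

print(f"{len(events)} IOS SD events, {len(responses)} ROI-level responses\n")
for r in responses:
    amp, dur = sdwave.hyperemia_metrics(r)
    comps = " ".join(f"{c.kind}({c.peak_amplitude_pct:+.1f}%)" for c in r.components)
    print(f"{r.event_id} {r.roi_id}: {r.morphology:12s} [{comps}]")
    print(f"    peak hyperemia {amp:.1f}% of baseline, "
          f"half-maximum duration {dur:.1f} min")

# Amplitudes are percent CBV change (positive = hyperemia, i.e. an intensity
# *decrease* at 564 nm); the duration is the width at half maximum of the
# peak-hyperemia component's own fitted pulse, so a superimposed late
# hyperemia does not inflate it.
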