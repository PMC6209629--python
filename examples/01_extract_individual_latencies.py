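"""Extract per-subject component latencies from a synthetic group.

Builds a 12-subject group whose averages contain a broad positive component
near 600 ms (with latency jitter and noise), then extracts peak latency,
30%-amplitude onset, and 50%-area latency for every subject.
"""

import numpy as np

from erplatency import ComponentSpec, LatencyConfig, extract_group, generate_group

groups, truth = generate_group(
    n_subjects=12,
    components=[ComponentSpec("gaussian", center=0.60, width=0.12, amplitude=6.0)],
    noise_sd=0.5,
    jitter_sd=0.04,
    sfreq=500.0,
    seed=7,
)
group = groups["A"]

cfg = LatencyConfig(
    sign=1,                      # positive deflection
    extract=["peakLat", "onset", "areaLat"],
    peak_win=(0.4, 1.0),         # search the late window only
    perc_amp=0.3,                # onset = 30% of peak amplitude
)
results = extract_group(group, cfg)
wide = results.wide()

print(wide.round(3))
print()
print(f"true component centers (s): {np.round(truth.centers['A'][:, 0], 3)}")
print(
    "\nEach row is one subject; latencies are in seconds. areaLat (the time "
    "splitting the component's area in half) tracks the true centers most "
    "tightly; onset sits systematically earlier, as it should."
)
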