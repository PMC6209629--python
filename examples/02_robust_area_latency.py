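"""Counter-peak baselines make area latency robust to slow drift.

A broad late component is generated once clean and once riding on a slow
half-cosine drift.  The naive zero-baseline area latency is biased by the
drift; anchoring the amplitude baseline to the adjacent opposite-polarity
peak (30% of the peak-to-peak distance) and bounding the area by the
on/offsets largely removes the bias.
"""

import numpy as np

from erplatency import ComponentSpec, LatencyConfig, extract_group, generate_group

common = dict(
    n_subjects=10,
    components=[
        ComponentSpec("gaussian", center=0.30, width=0.04, amplitude=-4.0, polarity=1),
        ComponentSpec("gaussian", center=0.60, width=0.10, amplitude=8.0),
    ],
    noise_sd=0.3,
    jitter_sd=0.02,
    sfreq=500.0,
    seed=42,
)
clean, _ = generate_group(drift_amplitude=0.0, **common)
drifting, _ = generate_group(drift_amplitude=2.0, **common)

naive = LatencyConfig(
    sign=1, extract=["areaLat"], peak_win=(0.45, 0.95), area_win="fullRange"
)
anchored = LatencyConfig(
    sign=1,
    extract=["areaLat"],
    peak_win=(0.45, 0.95),
    c_win_width=-0.25,     # adjacent negative peak before the search window
    perc_amp=0.3,          # baseline at 30% of the peak-to-peak distance
    area_win="ampLat",     # area bounded by the on/offsets
    area_base="percAmp",
)

for label, cfg in (("zero baseline ", naive), ("counter anchor", anchored)):
    lat_clean = extract_group(clean["A"], cfg).values("areaLat").mean()
    lat_drift = extract_group(drifting["A"], cfg).values("areaLat").mean()
    print(
        f"{label}: mean areaLat clean = {lat_clean * 1e3:6.1f} ms, "
        f"with drift = {lat_drift * 1e3:6.1f} ms, "
        f"drift-induced shift = {abs(lat_drift - lat_clean) * 1e3:5.1f} ms"
    )

print(
    "\nThe true median latency is 600 ms. With the zero baseline the drift "
    "drags the estimate toward the middle of the analysis window; the "
    "peak-to-peak anchored, on/offset-bounded area stays close to 600 ms "
    "in both regimes."
)
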