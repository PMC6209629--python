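# erplatency

Component-latency extraction for group-level evoked (ERP/ERF) time series.

MEG/EEG's main asset is temporal resolution: the latency of a well-studied
component can time-stamp a cognitive operation in a way reaction times
cannot. Yet latency is measured far less often than amplitude, largely
because the easy measure — peak latency — is fragile under noise, and the
robust alternatives take parametrizing. This package implements the three
standard families of latency measures for groups of per-subject averaged
waveforms, together with the robustness adaptations, aggregation schemes,
and statistical tests needed to run a complete group analysis:

* **Peak latency** — the time of the largest local maximum (in the
  component's polarity direction) inside a search window, with an explicit
  boundary-fallback flag when the window contains no local peak.
* **Percent-amplitude latency (onset/offset)** — the first time before /
  after the peak where the waveform falls to a fraction *p* of the peak
  amplitude. Candidate amplitudes are running averages over ±`peakWidth`
  samples so single noise spikes cannot fake a crossing; crossings are
  linearly interpolated to sub-sample resolution.
* **Percent-area latency** — the time *t* at which the signed area
  ∫ max(x(τ) − b, 0) dτ accumulated from the window start reaches a
  fraction (typically 50%) of the total: a robust estimate of the median
  component latency.

Three adaptations make these measures usable on hard data: the amplitude
baseline *b* can be **raised** to *p*·peak, or anchored to an adjacent
opposite-polarity **counter peak** so thresholds reference the peak-to-peak
distance (immunizing them against slow drift); and the area's temporal
bounds can be set to the component's own **on/offsets** so neighbouring
components stay out of the integral.

Group-level machinery: `individual`, grand-average (`GA`), and jackknife
(`jackMiller`) aggregation — the latter extracting from each leave-one-out
average — plus Smulders retrieval (`jackSmulders`) of per-subject scores,
O_i = n·G − (n−1)·J_i. Because jackknifing shrinks between-estimate
variance by (n−1), the paired t on jackknife estimates is corrected as
t = t_naive / (n−1); for a linear statistic this equals the classical
paired t on individual values exactly. Reliability utilities include the
disattenuated correlation r_corr = r_xy / √(r_xx·r_yy).

A seeded synthetic-data generator (transient early + broad late component,
latency jitter, amplitude variation, half-cosine drift, white noise)
provides ground truth for every stage, so the whole pipeline is testable
without any recordings.

## Worked example

```python
from erplatency import ComponentSpec, LatencyConfig, extract_group, generate_group

groups, truth = generate_group(
    n_subjects=12,
    components=[ComponentSpec("gaussian", center=0.60, width=0.12, amplitude=6.0)],
    noise_sd=0.5, jitter_sd=0.04, sfreq=500.0, seed=7,
)
cfg = LatencyConfig(sign=1, extract=["peakLat", "onset", "areaLat"],
                    peak_win=(0.4, 1.0), perc_amp=0.3)
print(extract_group(groups["A"], cfg).wide().round(3))
```

```
measure  areaLat  onset  peakLat
unit_id
1          0.586  0.394    0.586
2          0.659  0.463    0.670
3          0.609  0.414    0.592
4          0.571  0.377    0.538
...
```

One row per subject, latencies in seconds (the units of the time axis).
For these data the true component centers of subjects 1–4 are 0.575,
0.656, 0.602, 0.559 s: the 50%-area latency tracks them most tightly, the
peak latency scatters more, and the 30%-amplitude onset sits ~190 ms
earlier — about μ − σ·√(−2 ln 0.3) for a Gaussian component, as it should.

The `examples/` directory holds one short script per capability
(individual extraction, drift-robust area latency, jackknife t-tests, file
formats and the CLI). A thin command line mirrors the configuration:

```bash
erplatency group.h5 -o results.tsv --sign pos --extract peakLat,areaLat \
    --peak-win 0.4,1.0 --aggregate jackMiller --fig
```

which writes a tidy TSV (`unit_id`, `measure`, `value`, `found`,
`aggregate`), a JSON run manifest with every effective parameter, and —
with `--fig` — one diagnostic image per subject showing the waveform,
windows, baselines, and every extracted marker.

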