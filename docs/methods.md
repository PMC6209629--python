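# Methods

## Data model and assumptions

The raw input is a Subjects × Channels × Time array of per-subject
*averaged* evoked responses. All preprocessing (filtering, artifact
rejection, baseline correction, condition differencing) is assumed done;
the package starts where a clean average ends. Channels are combined by an
unweighted mean, and the result is multiplied by the configured polarity
(`sign` ∈ {+1, −1}) so every algorithm can search for a positive
deflection. All amplitude outputs are reported in this sign-adjusted space,
which makes the sign-symmetry identity exact: negating the data and
flipping `sign` changes nothing.

Time handling: when a time axis is supplied (explicit vector or a
`(start, end, rate)` triple), every configured time and every returned
latency is in axis units; otherwise everything is in 0-based sample
indices. Internally windows are closed sample intervals; off-grid window
bounds round **inward** (start up, end down) so a requested window is never
exceeded. Point conversions round to the nearest sample. Note the 0-based
convention: MATLAB-style tooling in this field is 1-based, so positional
selectors differ by one.

## Measures

**Peak latency.** The largest local maximum inside `peakWin`. A sample (or
plateau run, located at its first sample) is a local maximum when both
flanking samples exist and are strictly smaller; equal-valued candidates
tie-break to the earliest. When the window holds no local maximum (e.g. a
monotone stretch), the window's argmax — necessarily a boundary — is
returned with `foundLocal = False` rather than failing, and a warning
fires when more than half of the included subjects hit this fallback.

**Peak amplitude and running averages.** Peak amplitude is the mean over
±`peakWidth` samples around the peak (default 5 samples ≈ 5 ms at 1 kHz),
truncated at the data edges. The same boxcar is applied to candidate
amplitudes during on/offset search, equivalent to pre-smoothing with an
edge-truncated boxcar of 2·`peakWidth`+1 samples (asserted in tests). Set
`peakWidth = 0` if the data are already low-passed.

**Counter peak and thresholds.** Without a counter peak the on/offset
threshold is `percAmp` × peak amplitude, referenced to zero (the
pre-stimulus baseline). With a counter peak — the opposite-polarity
extremum found in a window given either explicitly (`cWin`) or as a signed
extent (`cWinWidth`) from the peak-window border or the detected peak
(`cWinStart`) — the threshold becomes
counterAmp + `percAmp` · (peakAmp − counterAmp), i.e. a fraction of the
peak-to-peak distance. This anchoring is invariant to constant offsets and
slow drift. The counter-peak search mirrors the peak rule on the negated
waveform, including the boundary fallback (recorded in the annotation, not
an error, so anchoring degrades gracefully). A peak amplitude at or below
the counter amplitude raises a degenerate-component error: there is no
peak-to-peak distance to reference.

**On/offset.** Scanning outward from the peak, the on(off)set is the first
smoothed sample at or below threshold, linearly interpolated between the
bracketing smoothed samples. The search range is `ampLatWin` (default: the
full range), additionally clipped at the counter-peak latency on its side
of the peak when `cBound` is true. If no crossing exists within bounds the
bound itself is returned with `foundOn`/`foundOff` cleared; a >half-of-
subjects warning fires as for peaks.

**Signed area and percent-area latency.** The temporal bounds come from
`areaWin`: the peak window (default), the full range, an explicit window,
or the component's own on/offsets (`'ampLat'`, rounded outward to whole
samples). The amplitude baseline is zero (default) or the percent-
amplitude threshold (`areaBase = 'percAmp'`). Only excursions above the
baseline count; opposite-direction activity contributes nothing. The
reported *area* is the per-sample sum Σ max(x_k − b, 0) · Δt. The split
*latency* treats the waveform as piecewise linear between samples and
integrates the continuously rectified signal exactly — baseline crossings
split segments, each linear piece contributes a quadratic cumulative, and
the `percArea` point is solved in closed form. The two conventions were
chosen deliberately: the per-sample sum is the conventional area score,
while the continuous rule gives the latency sub-sample resolution, makes
it agree with dense-grid integration to machine precision, and preserves
the symmetric-component identity (areaLat = peak time exactly for
noiseless symmetric components). A window with no above-baseline activity
returns the window end with `foundArea = False` — a defined sentinel plus
a flag rather than a missing value mid-pipeline.

## Aggregation and inference

`individual` extracts per subject; `GA` from the grand average;
`jackMiller` from each leave-one-out average with the grand-average
estimate appended last (its final entry is bit-for-bit the `GA` output);
`jackSmulders` retrieves per-subject scores O_i = n·G − (n−1)·J_i. The
retrieval anchor G is the grand-average-based estimate (the appended
entry), not the mean of the jackknife values; for linear measures the two
coincide and retrieval is exact, for nonlinear latency measures they can
differ slightly. Subject exclusion is applied before leave-one-out
construction, so n always counts included subjects. Leave-one-out means
are unweighted (inputs are averages; trial counts are unknown).

The jackknife paired t divides the naive t on jackknife difference scores
by (n−1), undoing the (n−1)² variance shrinkage; df = n−1. The
linear-measure identity (corrected jackknife t ≡ classical paired t,
checked to 1e-10) independently validates the correction. The
disattenuated correlation r_xy/√(r_xx·r_yy) is capped at magnitude 1,
since noisy reliability estimates can push the raw ratio above 1; the
significance test attaches to the raw correlation only.

## Synthetic data

The generator emulates baseline-corrected group averages: a sum of
Gaussian (symmetric) or gamma-shaped (fast-rise/slow-decay) components
with per-subject center jitter ~ N(0, `jitter_sd`) and amplitude scale
~ N(1, `amplitude_jitter_sd`) — both shared across conditions, as in a
within-subject design — plus per-condition latency shifts and amplitude
scales, a half-cosine drift with random phase, and white Gaussian noise
per channel. Defaults (two components at 170 ms/σ 20 ms/amp 10 and
600 ms/σ 120 ms/amp 6; noise SD 0.5; jitter SD 30 ms; −0.1–1.0 s at
1 kHz) put the averaged-data SNR in the range where peak latency starts to
fail for the broad component but area latency does not, which is the
regime the measures were designed for. All randomness is spawned from one
master seed with per-subject substreams, so extending the group preserves
earlier subjects.

What the generator does **not** emulate: 1/f noise spectra, sensor
geometry and field spread, trial-count imbalance, or latency variability
*between* conditions (condition effects are fixed shifts). Passing tests
therefore demonstrate correctness of the algorithms under a controlled
noise model, not performance guarantees on arbitrary recordings; in
particular, paired contrasts on synthetic data understate between-
condition variability real designs can show.

## Numerical and design choices

* 0-based indexing internally; label-based selectors when metadata exists;
  boolean masks must match the dimension length exactly (silent recycling
  hides bugs).
* Windows: closed intervals; inward rounding of off-grid bounds; the
  `(start, end, rate)` triple must be self-consistent within one sample.
* Tie-breaks: earliest among equal local maxima; plateaus count once, at
  their first sample.
* Interpolation: linear for threshold crossings; exact piecewise-quadratic
  cumulative inversion for area splits.
* Edge handling: amplitude-averaging windows truncate at the data edges
  rather than padding (padding invents data).
* Warnings: the "more than half" rules are computed over included subjects
  after `subs` filtering; found-flags are always written to output
  regardless of the warnings setting, so downstream QC never depends on
  log capture.
* Effective-config resolution is idempotent and fully recorded (every
  parameter value plus the list of default-filled fields) in the results
  annotation and the run manifest.

## Problem sizes in the test suite

The analytic-oracle suite uses noiseless Gaussians at 1 kHz; the
brute-force area oracle checks 500 random piecewise-linear waveforms of
8–50 samples against 400× dense-grid integration; the type-I-error
harness runs 2000 replications of n = 16 subjects with a single Gaussian
component sampled at 250 Hz over 0.6 s (one channel), a size chosen to
make the Monte-Carlo standard error (≈0.005) small relative to the ±0.01
acceptance band while keeping the whole suite under a minute of compute.

## Known limitations

* Agreement with other implementations of these measures is expected only
  to within one sampling interval: whether crossings and area splits are
  interpolated or snapped to whole samples varies between codebases.
* The counter-peak local-extremum rule mirrors the peak rule by
  construction; other implementations may use a different extremum
  criterion in the counter window.
* No trial-level (within-subject) jackknife; inputs are subject averages.
* No filtering, multi-component decomposition, or segmented-regression
  onset methods; percent-amplitude onsets are biased toward the earliest
  single-subject onsets at the group level (demonstrated in the tests) —
  that bias is a property of the measure, not removed here.
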