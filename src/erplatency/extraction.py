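"""Per-waveform latency and amplitude measures.

All functions operate on 1-D *sign-adjusted* waveforms: the group data is
averaged over the selected channels and multiplied by the configured
component polarity, so the component of interest is always a positive
deflection.  Sample indices are 0-based; fractional indices denote
sub-sample positions obtained by linear interpolation.

The measures
------------
* **peak latency** — position of the largest local maximum inside the
  search window; falls back to the window boundary (flagged) when the
  window contains no local maximum, e.g. on a monotone stretch.
* **percent-amplitude on/offset** — first time before/after the peak where
  the running-averaged amplitude falls to a set fraction of the (optionally
  peak-to-peak-referenced) peak amplitude.  The running average (boxcar of
  ``2·half_width + 1`` samples, edge-truncated) keeps single noise spikes
  from faking an early offset.
* **percent-area latency** — time splitting the signed area (excursions
  above a baseline, within temporal bounds) at a set fraction, typically
  50%: a robust estimate of the median component latency.
* **counter peak** — an adjacent opposite-polarity extremum used to anchor
  thresholds to the peak-to-peak distance instead of the pre-stimulus
  baseline, which immunises on/offsets against slow drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ComponentMeasures,
    DegenerateComponentError,
    EffectiveConfig,
    GroupAverages,
    WindowRangeError,
)

__all__ = [
    "CrossingResult",
    "prepare_waveforms",
    "find_peak",
    "windowed_amplitude",
    "running_average",
    "find_counter_peak",
    "percent_amplitude_threshold",
    "find_crossings",
    "resolve_area_window",
    "signed_area_latency",
    "mean_amplitude",
    "extract_measures",
]


@dataclass
class CrossingResult:
    """Percent-amplitude on/offset in fractional sample indices."""

    onset: float
    offset: float
    found_on: bool
    found_off: bool
    threshold: float


def prepare_waveforms(group: GroupAverages, cfg: EffectiveConfig) -> np.ndarray:
    """Channel-averaged, sign-adjusted waveforms, one row per selected subject.

    Channels are combined by an unweighted mean; the result is multiplied by
    ``cfg.sign`` so downstream code can always search for a positive peak.
    """
    data = group.data[np.ix_(cfg.sub_idx, cfg.chan_idx)]
    return cfg.sign * data.mean(axis=1)


def _check_window(win: tuple[int, int], n: int, what: str = "window") -> None:
    lo, hi = int(win[0]), int(win[1])
    if not (0 <= lo <= hi <= n - 1):
        raise WindowRangeError(
            f"{what} [{lo}, {hi}] outside waveform of {n} samples"
        )


def _local_max_positions(w: np.ndarray, lo: int, hi: int) -> list[int]:
    """Positions in [lo, hi] that are local maxima of the full waveform.

    A maximal run of equal values counts as one local maximum at its first
    sample, and qualifies only when both flanking samples exist and are
    strictly smaller — so data-edge samples never count.
    """
    n = w.size
    out: list[int] = []
    i = lo
    while i <= hi:
        j = i
        while j + 1 < n and w[j + 1] == w[i]:
            j += 1  # run [run_start, j]; extend left edge too
        run_start = i
        while run_start - 1 >= 0 and w[run_start - 1] == w[i]:
            run_start -= 1
        if run_start - 1 >= 0 and j + 1 <= n - 1:
            if w[run_start - 1] < w[i] and w[j + 1] < w[i]:
                pos = max(run_start, lo)
                if pos <= hi and not (out and out[-1] == pos):
                    out.append(pos)
        i = j + 1
    return out


def find_peak(w: np.ndarray, window: tuple[int, int]) -> tuple[int, bool]:
    """Largest local maximum in ``window``; boundary fallback when none.

    Returns ``(index, found_local)``.  Among equal-valued local maxima the
    earliest wins.  When the window holds no local maximum (monotone data),
    the index of the window's largest value — necessarily a boundary — is
    returned with ``found_local=False``.
    """
    w = np.asarray(w, dtype=float)
    _check_window(window, w.size, "peak window")
    lo, hi = int(window[0]), int(window[1])
    candidates = _local_max_positions(w, lo, hi)
    if candidates:
        values = [w[i] for i in candidates]
        best = int(np.argmax(values))  # first occurrence on ties
        return candidates[best], True
    return lo + int(np.argmax(w[lo : hi + 1])), False


def windowed_amplitude(w: np.ndarray, index: int, half_width: int) -> float:
    """Mean amplitude over ``[index − half_width, index + half_width]``.

    The averaging window is truncated at the data edges; ``half_width=0``
    returns the single sample.
    """
    w = np.asarray(w, dtype=float)
    if not 0 <= index < w.size:
        raise WindowRangeError(f"index {index} outside waveform of {w.size} samples")
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    lo = max(0, index - half_width)
    hi = min(w.size - 1, index + half_width)
    return float(w[lo : hi + 1].mean())


def running_average(w: np.ndarray, half_width: int) -> np.ndarray:
    """Edge-truncated boxcar smooth: ``out[i] = windowed_amplitude(w, i, h)``."""
    w = np.asarray(w, dtype=float)
    if half_width == 0:
        return w.copy()
    n = w.size
    csum = np.concatenate(([0.0], np.cumsum(w)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - half_width)
    hi = np.minimum(n - 1, idx + half_width)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def resolve_counter_window(
    cfg: EffectiveConfig, peak_index: int, n: int
) -> tuple[int, int]:
    """Resolve the counter-peak search window to a sample interval."""
    if cfg.c_win is not None:
        lo, hi = cfg.c_win
    else:
        width = cfg.c_win_width
        assert width is not None
        if cfg.c_win_start == "peak":
            anchor = peak_index
        else:  # 'peakWin' border on the searched side
            anchor = cfg.peak_win[0] if width < 0 else cfg.peak_win[1]
        lo, hi = (anchor + width, anchor) if width < 0 else (anchor, anchor + width)
    clo, chi = max(0, lo), min(n - 1, hi)
    if clo > chi:
        raise WindowRangeError(
            f"counter-peak window [{lo}, {hi}] lies outside the data "
            f"(0..{n - 1})"
        )
    return clo, chi


def find_counter_peak(
    w: np.ndarray, peak_index: int, cfg: EffectiveConfig
) -> tuple[int, float, bool]:
    """Adjacent opposite-polarity extremum (minimum in sign-adjusted space).

    Uses the same local-extremum rule as :func:`find_peak` applied to the
    negated waveform; when the counter window holds no interior minimum the
    boundary minimum is used and flagged (``local=False``).  Returns
    ``(index, windowed amplitude, local)``.
    """
    w = np.asarray(w, dtype=float)
    win = resolve_counter_window(cfg, peak_index, w.size)
    idx, local = find_peak(-w, win)
    amp = windowed_amplitude(w, idx, cfg.peak_width)
    return idx, amp, local


def percent_amplitude_threshold(
    peak_amp: float, counter_amp: float | None, perc_amp: float
) -> float:
    """Amplitude threshold for on/offset detection.

    Without a counter peak the threshold is ``perc_amp × peak_amp``
    (relative to zero, i.e. the pre-stimulus baseline); with one it is
    referenced to the peak-to-peak distance:
    ``counter_amp + perc_amp × (peak_amp − counter_amp)``.
    """
    if counter_amp is None:
        return perc_amp * peak_amp
    if peak_amp <= counter_amp:
        raise DegenerateComponentError(
            f"peak amplitude ({peak_amp:g}) does not exceed the counter-peak "
            f"amplitude ({counter_amp:g}); no peak-to-peak distance to "
            f"reference the threshold to"
        )
    return counter_amp + perc_amp * (peak_amp - counter_amp)


def find_crossings(
    w: np.ndarray,
    peak_index: int,
    threshold: float,
    bounds: tuple[int, int],
    half_width: int,
) -> CrossingResult:
    """Scan outward from the peak for the threshold crossings.

    The candidate amplitude at each sample is the running average with the
    configured half-width; the crossing time is linearly interpolated
    between the bracketing smoothed samples.  When the smoothed waveform
    never falls to the threshold within ``bounds``, the bound itself is
    returned with the found flag cleared.
    """
    w = np.asarray(w, dtype=float)
    _check_window(bounds, w.size, "on/offset search window")
    lo, hi = int(bounds[0]), int(bounds[1])
    s = running_average(w, half_width)

    def scan(direction: int) -> tuple[float, bool]:
        bound = lo if direction < 0 else hi
        i = peak_index + direction
        while (i >= bound) if direction < 0 else (i <= bound):
            if s[i] <= threshold:
                prev = i - direction  # the sample nearer the peak, above thr
                denom = s[prev] - s[i]
                frac = (s[prev] - threshold) / denom if denom > 0 else 0.0
                return float(prev + direction * frac), True
            i += direction
        return float(bound), False

    onset, found_on = scan(-1)
    offset, found_off = scan(+1)
    return CrossingResult(onset, offset, found_on, found_off, threshold)


def resolve_area_window(
    cfg: EffectiveConfig, crossings: CrossingResult | None, n: int
) -> tuple[int, int]:
    """Temporal bounds of the component area, in whole samples.

    ``areaWin='ampLat'`` bounds the area by the on/offset crossings, rounded
    outward so the component is fully included.
    """
    spec = cfg.area_win
    if spec == "peakWin":
        return cfg.peak_win
    if spec == "fullRange":
        return 0, n - 1
    if spec == "ampLat":
        if crossings is None or not (crossings.found_on or crossings.found_off):
            raise DegenerateComponentError(
                "areaWin='ampLat' but neither onset nor offset was found; "
                "widen the on/offset search window (ampLatWin) or anchor the "
                "threshold to a counter peak"
            )
        lo = int(np.floor(crossings.onset))
        hi = int(np.ceil(crossings.offset))
        return max(0, lo), min(n - 1, hi)
    return int(spec[0]), int(spec[1])


def signed_area_latency(
    w: np.ndarray,
    window: tuple[int, int],
    baseline: float,
    perc_area: float,
) -> tuple[float, float, bool]:
    """Signed area above ``baseline`` and the latency splitting it.

    Only excursions above the baseline count (opposite-polarity activity is
    ignored).  The reported *area* is the per-sample sum
    ``Σ max(value − baseline, 0)`` in amplitude × sample units (the caller
    scales by the sampling interval).  The split *latency* treats the
    waveform as piecewise linear between samples and integrates the
    continuously rectified signal exactly, so it has sub-sample resolution
    and matches dense-grid integration to machine precision.

    Returns ``(area, latency, found)`` with the latency as a fractional
    sample index.  A window without any above-baseline excursion yields the
    window end with ``found=False``.
    """
    w = np.asarray(w, dtype=float)
    _check_window(window, w.size, "area window")
    lo, hi = int(window[0]), int(window[1])
    g = w[lo : hi + 1] - baseline
    area_sum = float(np.maximum(g, 0.0).sum())

    # rectified linear pieces (xa, xb, ga, gb) with ga, gb >= 0
    pieces: list[tuple[float, float, float, float]] = []
    for i in range(g.size - 1):
        g0, g1 = g[i], g[i + 1]
        if g0 <= 0.0 and g1 <= 0.0:
            continue
        if g0 < 0.0:  # upward baseline crossing inside the segment
            xc = i + g0 / (g0 - g1)
            pieces.append((xc, i + 1.0, 0.0, g1))
        elif g1 < 0.0:  # downward crossing
            xc = i + g0 / (g0 - g1)
            pieces.append((float(i), xc, g0, 0.0))
        else:
            pieces.append((float(i), i + 1.0, g0, g1))
    piece_areas = [(xb - xa) * (ga + gb) / 2.0 for xa, xb, ga, gb in pieces]
    total = float(sum(piece_areas))
    if total <= 0.0:
        return area_sum, float(hi), False

    target = perc_area * total
    acc = 0.0
    pos = float(hi)
    for (xa, xb, ga, gb), a in zip(pieces, piece_areas):
        if acc + a >= target:
            rem = target - acc
            length = xb - xa
            slope = (gb - ga) / length
            disc = ga * ga + 2.0 * slope * rem
            # stable root of ga·s + slope·s²/2 = rem on [0, length]
            denom = ga + np.sqrt(max(disc, 0.0))
            s = 0.0 if denom == 0.0 else 2.0 * rem / denom
            pos = xa + min(s, length)
            break
        acc += a
    return area_sum, float(np.clip(lo + pos, lo, hi)), True


def mean_amplitude(w: np.ndarray, window: tuple[int, int]) -> float:
    """Arithmetic mean over the closed sample interval."""
    w = np.asarray(w, dtype=float)
    _check_window(window, w.size, "mean window")
    lo, hi = int(window[0]), int(window[1])
    return float(w[lo : hi + 1].mean())


def _needs(cfg: EffectiveConfig, *measures: str) -> bool:
    return any(m in cfg.extract for m in measures)


def extract_measures(w: np.ndarray, cfg: EffectiveConfig) -> ComponentMeasures:
    """Extract every requested measure from one sign-adjusted waveform.

    Orchestrates peak detection, counter-peak search, threshold and
    crossings, area and split latency, and the derived measures
    (``width = offset − onset``, ``peak2peak = peakAmp − counterAmp``).
    Intermediates are computed whenever a requested measure depends on them.
    Latencies are returned in time-axis units (samples when no axis was
    supplied); amplitudes stay in sign-adjusted data units.
    """
    w = np.asarray(w, dtype=float)
    tm = cfg.timemap
    out = ComponentMeasures()

    peak_idx, found_local = find_peak(w, cfg.peak_win)
    out.found_local = found_local
    out.peak_lat = tm.to_units(peak_idx)
    peak_amp = windowed_amplitude(w, peak_idx, cfg.peak_width)
    out.peak_amp = peak_amp

    counter_amp = None
    if cfg.counter:
        c_idx, counter_amp, c_local = find_counter_peak(w, peak_idx, cfg)
        out.counter_lat = tm.to_units(c_idx)
        out.counter_amp = counter_amp
        out.counter_local = c_local
        out.peak2peak = peak_amp - counter_amp
    else:
        c_idx = None

    need_crossings = (
        _needs(cfg, "onset", "offset", "width") or cfg.area_win == "ampLat"
    )
    need_threshold = (
        need_crossings or _needs(cfg, "percAmp") or cfg.area_base == "percAmp"
    )

    threshold = None
    if need_threshold:
        threshold = percent_amplitude_threshold(peak_amp, counter_amp, cfg.perc_amp)
        out.perc_amp_value = threshold

    crossings = None
    if need_crossings:
        assert threshold is not None
        lo, hi = cfg.amp_lat_win
        if cfg.c_bound and c_idx is not None:
            # counter peak bounds the search on its side of the peak
            if c_idx < peak_idx:
                lo = max(lo, c_idx)
            else:
                hi = min(hi, c_idx)
        lo = min(lo, peak_idx)
        hi = max(hi, peak_idx)
        crossings = find_crossings(w, peak_idx, threshold, (lo, hi), cfg.peak_width)
        out.onset = tm.to_units(crossings.onset)
        out.offset = tm.to_units(crossings.offset)
        out.found_on = crossings.found_on
        out.found_off = crossings.found_off
        out.width = out.offset - out.onset

    if _needs(cfg, "areaLat", "area"):
        area_win = resolve_area_window(cfg, crossings, w.size)
        area_baseline = 0.0 if cfg.area_base == "zero" else float(threshold)
        out.baseline = area_baseline
        area_raw, pos, found_area = signed_area_latency(
            w, area_win, area_baseline, cfg.perc_area
        )
        out.area = area_raw * tm.dt
        out.area_lat = tm.to_units(pos)
        out.found_area = found_area

    if _needs(cfg, "mean"):
        out.mean = mean_amplitude(w, cfg.mean_win)

    return out
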