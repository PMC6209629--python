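"""Shared data model: group containers, configuration, time mapping.

The central raw-input type is :class:`GroupAverages`, a Subjects × Channels ×
Time array of per-subject averaged evoked responses (ERP/ERF), optionally
annotated with subject numbers, channel names, and a time axis.  Extraction
behaviour is controlled by :class:`LatencyConfig`; :func:`validate_and_fill`
resolves it against a concrete group into an :class:`EffectiveConfig` whose
windows are sample indices and whose selectors are index arrays.

Index convention
----------------
Internally everything is 0-based sample/array indexing (the original MATLAB
tooling this mirrors is 1-based — keep that in mind when porting parameter
sets).  User-facing selectors accept subject numbers, channel names, and time
units whenever the corresponding metadata is present.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ALL_MEASURES",
    "AGGREGATE_MODES",
    "ConfigError",
    "ConflictError",
    "WindowRangeError",
    "DegenerateComponentError",
    "DegenerateDataError",
    "LatencyWarning",
    "TimeMap",
    "GroupAverages",
    "LatencyConfig",
    "EffectiveConfig",
    "ComponentMeasures",
    "ResultsTable",
    "validate_and_fill",
]

#: Every measure the extractor can report, in canonical order.
ALL_MEASURES = (
    "mean",
    "peakLat",
    "onset",
    "offset",
    "width",
    "areaLat",
    "peakAmp",
    "peak2peak",
    "percAmp",
    "area",
)

#: Measures that are only defined when a counter peak is configured.
COUNTER_MEASURES = ("peak2peak", "counterAmp", "counterLat")

AGGREGATE_MODES = ("individual", "GA", "jackMiller", "jackSmulders")


class ConfigError(ValueError):
    """Invalid or inconsistent configuration."""


class ConflictError(ConfigError):
    """Mutually exclusive configuration fields were both set."""


class WindowRangeError(ConfigError):
    """A requested window or time point lies outside the data's time range."""


class DegenerateComponentError(ValueError):
    """The waveform has no usable component (e.g. peak below counter peak)."""


class DegenerateDataError(ValueError):
    """Statistical input with zero variance or too few observations."""


class LatencyWarning(UserWarning):
    """Quality warnings (boundary fallbacks affecting many subjects, ...)."""


# ---------------------------------------------------------------------------
# Time mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeMap:
    """Bidirectional map between time units and 0-based sample indices.

    ``t(i) = t0 + i * dt``.  When no time axis is supplied the map is the
    identity (``t0=0, dt=1``) and all latencies are expressed in samples.
    """

    t0: float
    dt: float
    n: int
    identity: bool = False

    @classmethod
    def from_axis(cls, times: np.ndarray) -> "TimeMap":
        times = np.asarray(times, dtype=float)
        if times.ndim != 1 or times.size < 2:
            raise ConfigError("time axis must be a 1-D vector of length >= 2")
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            raise ConfigError("time axis must be strictly increasing")
        dt = float(diffs.mean())
        if np.max(np.abs(diffs - dt)) > 1e-9 * max(abs(dt), 1.0):
            raise ConfigError("time axis must be uniformly spaced")
        return cls(t0=float(times[0]), dt=dt, n=times.size)

    @classmethod
    def make_identity(cls, n: int) -> "TimeMap":
        return cls(t0=0.0, dt=1.0, n=n, identity=True)

    @property
    def axis(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) * self.dt

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n - 1) * self.dt

    def to_samples(self, t: float, mode: str = "nearest") -> int:
        """Convert a time value to a sample index.

        ``mode`` controls off-grid rounding: "nearest" for point estimates,
        "ceil"/"floor" for window starts/ends so a requested window is never
        exceeded (inward rounding).  Values within half a sample of the axis
        ends are accepted; anything further out raises.
        """
        x = (float(t) - self.t0) / self.dt
        eps = 1e-6
        if x < -0.5 - eps or x > self.n - 0.5 + eps:
            raise WindowRangeError(
                f"time {t!r} outside the data range "
                f"[{self.t0!r}, {self.t_end!r}]"
            )
        # snap to grid before directional rounding
        if abs(x - round(x)) < eps:
            idx = int(round(x))
        elif mode == "nearest":
            idx = int(round(x))
        elif mode == "ceil":
            idx = int(np.ceil(x))
        elif mode == "floor":
            idx = int(np.floor(x))
        else:  # pragma: no cover - guarded by callers
            raise ValueError(f"unknown rounding mode {mode!r}")
        return int(np.clip(idx, 0, self.n - 1))

    def to_units(self, idx: float) -> float:
        """Time value at a (possibly fractional) sample index."""
        return self.t0 + float(idx) * self.dt

    def window_to_samples(self, win: Sequence[float]) -> tuple[int, int]:
        """Convert a (start, end) time window to a closed sample interval.

        Off-grid bounds round inward (start up, end down).
        """
        if len(win) != 2:
            raise ConfigError(f"window must have two elements, got {win!r}")
        lo = self.to_samples(win[0], mode="ceil")
        hi = self.to_samples(win[1], mode="floor")
        if lo > hi:
            raise ConfigError(f"window {win!r} is empty after conversion")
        return lo, hi

    def duration_to_samples(self, d: float) -> int:
        """Convert a signed duration to a whole number of samples (nearest)."""
        return int(round(float(d) / self.dt))


# ---------------------------------------------------------------------------
# Group container
# ---------------------------------------------------------------------------


def _expand_time_axis(times: Any, n_times: int) -> np.ndarray:
    """Expand the (start, end, rate) triple form; pass vectors through."""
    arr = np.asarray(times, dtype=float)
    if arr.ndim != 1:
        raise ConfigError("times must be a 1-D vector or a (start, end, rate) triple")
    if arr.size == 3 and n_times != 3:
        start, end, rate = arr
        if rate <= 0:
            raise ConfigError("sampling rate must be positive")
        expected = abs(end - start) * rate
        if abs(expected - (n_times - 1)) > 1.0:
            raise ConfigError(
                f"(start, end, rate) = {tuple(arr)} implies "
                f"{expected + 1:.1f} samples but the data has {n_times}"
            )
        return start + np.arange(n_times) * np.sign(end - start) / rate
    return arr


@dataclass
class GroupAverages:
    """Per-subject averaged evoked waveforms, Subjects × Channels × Time.

    Parameters
    ----------
    data
        Amplitude array indexed ``[subject, channel, time]`` in arbitrary
        units (µV, T/m, ...).  Must be finite.
    subject_ids
        Optional subject numbers (length = n subjects), in data order.
    channel_names
        Optional channel labels (length = n channels), in data order.
    time_axis
        Optional time points (length = n time samples), strictly increasing
        and uniformly spaced; alternatively a ``(start, end, rate)`` triple
        that is expanded to a full axis.  When present, all configuration
        times and all returned latencies are in these units; otherwise in
        sample indices.
    """

    data: np.ndarray
    subject_ids: Optional[Sequence[int]] = None
    channel_names: Optional[Sequence[str]] = None
    time_axis: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ConfigError(
                f"data must be 3-D [subject, channel, time], got shape "
                f"{self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ConfigError("data contains non-finite values")
        n_sub, n_chan, n_time = self.data.shape
        if self.subject_ids is not None:
            self.subject_ids = [int(s) for s in self.subject_ids]
            if len(self.subject_ids) != n_sub:
                raise ConfigError(
                    f"subject_ids has length {len(self.subject_ids)}, "
                    f"expected {n_sub} (subject dimension)"
                )
        if self.channel_names is not None:
            self.channel_names = [str(c) for c in self.channel_names]
            if len(self.channel_names) != n_chan:
                raise ConfigError(
                    f"channel_names has length {len(self.channel_names)}, "
                    f"expected {n_chan} (channel dimension)"
                )
        if self.time_axis is not None:
            axis = _expand_time_axis(self.time_axis, n_time)
            if axis.size != n_time:
                raise ConfigError(
                    f"time_axis has length {axis.size}, expected {n_time} "
                    f"(time dimension)"
                )
            TimeMap.from_axis(axis)  # validates monotone + uniform
            self.time_axis = axis

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def timemap(self) -> TimeMap:
        if self.time_axis is None:
            return TimeMap.make_identity(self.n_times)
        return TimeMap.from_axis(np.asarray(self.time_axis))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_UNSET = None

#: Mapping from the conventional config-file key names to dataclass fields.
_CONFIG_KEYS = {
    "sign": "sign",
    "extract": "extract",
    "aggregate": "aggregate",
    "aggregation": "aggregate",
    "fig": "fig",
    "subs": "subs",
    "subNum": "sub_num",
    "chans": "chans",
    "chanName": "chan_name",
    "chanNames": "chan_name",
    "peakWin": "peak_win",
    "meanTime": "mean_time",
    "times": "times",
    "peakWidth": "peak_width",
    "cWinStart": "c_win_start",
    "cWinWidth": "c_win_width",
    "cWin": "c_win",
    "percArea": "perc_area",
    "percAmp": "perc_amp",
    "areaWin": "area_win",
    "areaBase": "area_base",
    "ampLatWin": "amp_lat_win",
    "cBound": "c_bound",
    "warnings": "warnings",
}


@dataclass
class LatencyConfig:
    """Extraction configuration.

    Only ``sign`` is mandatory; every other field has a sensible default
    filled in by :func:`validate_and_fill`.  Times (windows, widths) are in
    the units of the time axis when one is present, otherwise in samples.

    Key fields
    ----------
    sign
        Component polarity: ``+1``/``'pos'`` or ``-1``/``'neg'``.
    extract
        Measure name, list of names, or ``'all'`` (default).
    aggregate
        ``'individual'`` (default), ``'GA'``, ``'jackMiller'``,
        ``'jackSmulders'``.
    peak_win
        ``(start, end)`` peak-search window; default: whole time range.
    peak_width
        Half-width of the running-average window for peak / on- / offset
        amplitudes; default 5 samples (~5 ms at 1 kHz).  Set 0 to disable
        smoothing.
    c_win_start, c_win_width, c_win
        Counter-peak (adjacent opposite-polarity peak) search: either an
        explicit window ``c_win`` or a signed extent ``c_win_width`` before
        (<0) / after (>0) the anchor (``c_win_start``: ``'peakWin'`` border,
        default, or the detected ``'peak'``).
    perc_area, perc_amp
        Fractions for percent-area latency (default 0.5) and for the
        percent-amplitude threshold (default 0.5; peak-to-peak referenced
        when a counter peak is configured).
    area_win, area_base, amp_lat_win, c_bound
        Area bounds in time ('peakWin' default, 'ampLat', 'fullRange', or
        explicit), area baseline in amplitude ('zero' default or 'percAmp'),
        on/offset search range ('fullRange' default), and whether the
        counter peak bounds the on/offset search (default True).
    """

    sign: Union[int, str, None] = _UNSET
    extract: Union[str, Sequence[str], None] = _UNSET
    aggregate: Optional[str] = _UNSET
    fig: Optional[bool] = _UNSET
    subs: Any = _UNSET
    sub_num: Optional[Sequence[int]] = _UNSET
    chans: Any = _UNSET
    chan_name: Optional[Sequence[str]] = _UNSET
    peak_win: Optional[Sequence[float]] = _UNSET
    mean_time: Optional[Sequence[float]] = _UNSET
    times: Optional[Sequence[float]] = _UNSET
    peak_width: Optional[float] = _UNSET
    c_win_start: Optional[str] = _UNSET
    c_win_width: Optional[float] = _UNSET
    c_win: Optional[Sequence[float]] = _UNSET
    perc_area: Optional[float] = _UNSET
    perc_amp: Optional[float] = _UNSET
    area_win: Union[str, Sequence[float], None] = _UNSET
    area_base: Optional[str] = _UNSET
    amp_lat_win: Union[str, Sequence[float], None] = _UNSET
    c_bound: Optional[bool] = _UNSET
    warnings: Optional[bool] = _UNSET

    @classmethod
    def from_dict(cls, d: dict) -> "LatencyConfig":
        """Build a config from a mapping using the conventional key names

        (``peakWin``, ``percAmp``, ...); snake_case field names are accepted
        too.  Unknown keys raise :class:`ConfigError`.
        """
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in d.items():
            if key in _CONFIG_KEYS:
                kwargs[_CONFIG_KEYS[key]] = value
            elif key in fields:
                kwargs[key] = value
            else:
                raise ConfigError(f"unknown configuration key {key!r}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        """Set fields only, under the conventional key names."""
        reverse = {}
        for key, attr in _CONFIG_KEYS.items():
            reverse.setdefault(attr, key)
        out = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if value is not None:
                if isinstance(value, np.ndarray):
                    value = value.tolist()
                out[reverse[f.name]] = value
        return out


@dataclass
class EffectiveConfig:
    """A :class:`LatencyConfig` resolved against a concrete group.

    Windows are closed 0-based sample intervals, selectors are index arrays,
    and every unset field carries its default.  ``filled`` lists the fields
    that were defaulted (for the run annotation); ``config`` is the filled
    user-facing configuration (re-resolving it reproduces this object).
    """

    sign: int
    extract: tuple[str, ...]
    aggregate: str
    fig: bool
    sub_idx: np.ndarray
    chan_idx: np.ndarray
    peak_win: tuple[int, int]
    mean_win: tuple[int, int]
    peak_width: int
    counter: bool
    c_win_start: str
    c_win_width: Optional[int]
    c_win: Optional[tuple[int, int]]
    perc_area: float
    perc_amp: float
    area_win: Union[str, tuple[int, int]]
    area_base: str
    amp_lat_win: tuple[int, int]
    c_bound: bool
    warnings: bool
    timemap: TimeMap
    subject_labels: list
    filled: tuple[str, ...]
    config: LatencyConfig

    def describe(self) -> str:
        """Human-readable account of the effective extraction settings."""
        tm = self.timemap
        unit = "samples" if tm.identity else "time-axis units"
        lines = [
            f"sign={self.sign:+d}; aggregate={self.aggregate}; "
            f"measures={', '.join(self.extract)}",
            f"latencies reported in {unit}",
            f"peak search window: samples {self.peak_win} "
            f"(= {tm.to_units(self.peak_win[0]):g}..{tm.to_units(self.peak_win[1]):g})",
            f"mean-amplitude window: samples {self.mean_win}",
            f"running-average half-width: {self.peak_width} samples",
            f"percent-amplitude fraction: {self.perc_amp}; "
            f"percent-area fraction: {self.perc_area}",
            f"area window: {self.area_win}; area baseline: {self.area_base}",
            f"on/offset search window: samples {self.amp_lat_win}; "
            f"counter peak bounds search: {self.c_bound}",
        ]
        if self.counter:
            if self.c_win is not None:
                lines.append(f"counter-peak window: samples {self.c_win}")
            else:
                lines.append(
                    f"counter-peak search: {self.c_win_width:+d} samples "
                    f"from {self.c_win_start!r}"
                )
        else:
            lines.append("no counter peak (thresholds relative to zero)")
        if self.filled:
            lines.append("defaulted fields: " + ", ".join(self.filled))
        return "\n".join(lines)

    def annotation(self) -> dict:
        """Every effective parameter value, for the run manifest."""
        return {
            "sign": self.sign,
            "extract": list(self.extract),
            "aggregate": self.aggregate,
            "fig": self.fig,
            "subjects": [int(i) for i in self.sub_idx],
            "subject_labels": list(self.subject_labels),
            "channels": [int(i) for i in self.chan_idx],
            "peakWin_samples": list(self.peak_win),
            "meanTime_samples": list(self.mean_win),
            "peakWidth_samples": self.peak_width,
            "counter_peak": self.counter,
            "cWinStart": self.c_win_start,
            "cWinWidth_samples": self.c_win_width,
            "cWin_samples": list(self.c_win) if self.c_win else None,
            "percArea": self.perc_area,
            "percAmp": self.perc_amp,
            "areaWin": self.area_win
            if isinstance(self.area_win, str)
            else list(self.area_win),
            "areaBase": self.area_base,
            "ampLatWin_samples": list(self.amp_lat_win),
            "cBound": self.c_bound,
            "warnings": self.warnings,
            "time_units": "samples" if self.timemap.identity else "axis units",
            "t0": self.timemap.t0,
            "dt": self.timemap.dt,
            "defaulted_fields": list(self.filled),
            "description": self.describe(),
        }


def _resolve_sign(sign: Any) -> int:
    if sign is _UNSET:
        raise ConfigError(
            "the component polarity (sign) must be set: +1/'pos' or -1/'neg'"
        )
    if isinstance(sign, str):
        s = sign.strip().lower()
        if s in ("1", "+1", "pos", "positive"):
            return 1
        if s in ("-1", "neg", "negative"):
            return -1
        raise ConfigError(f"sign must be +1/-1/'pos'/'neg', got {sign!r}")
    if sign in (1, -1):
        return int(sign)
    raise ConfigError(f"sign must be +1/-1/'pos'/'neg', got {sign!r}")


def _resolve_selector(
    sel: Any, n: int, labels: Optional[Sequence], what: str
) -> np.ndarray:
    """Resolve a subject/channel selector to an index array."""
    if sel is None:
        return np.arange(n)
    sel_arr = np.asarray(sel)
    if sel_arr.ndim == 0:
        sel_arr = sel_arr.reshape(1)
    if sel_arr.dtype == bool:
        if sel_arr.size != n:
            raise ConfigError(
                f"boolean {what} mask has length {sel_arr.size}, expected {n}"
            )
        return np.flatnonzero(sel_arr)
    idx = []
    for item in sel_arr.tolist():
        if labels is not None and item in labels:
            idx.append(list(labels).index(item))
        elif isinstance(item, (int, np.integer)) and 0 <= item < n:
            idx.append(int(item))
        else:
            raise ConfigError(f"cannot resolve {what} selector entry {item!r}")
    if not idx:
        raise ConfigError(f"empty {what} selection")
    return np.asarray(idx, dtype=int)


def validate_and_fill(config: LatencyConfig, group: GroupAverages) -> EffectiveConfig:
    """Validate a configuration against a group and fill in all defaults.

    Returns an :class:`EffectiveConfig` with windows in 0-based sample
    indices, resolved subject/channel selections, the time map, and the list
    of default-filled fields.  Passing an :class:`EffectiveConfig` returns it
    unchanged (the operation is idempotent).
    """
    if isinstance(config, EffectiveConfig):
        return config

    n_time = group.n_times
    filled: list[str] = []

    def default(name: str, value):
        current = getattr(config, name)
        if current is _UNSET:
            filled.append(name)
            return value
        return current

    sign = _resolve_sign(config.sign)

    # --- time map (config.times overrides group metadata) ------------------
    if config.times is not None:
        axis = _expand_time_axis(config.times, n_time)
        if axis.size != n_time:
            raise ConfigError(
                f"times has length {axis.size}, expected {n_time}"
            )
        timemap = TimeMap.from_axis(axis)
    elif group.time_axis is not None:
        timemap = group.timemap()
    else:
        timemap = TimeMap.make_identity(n_time)

    # --- selectors ----------------------------------------------------------
    sub_labels_meta = (
        list(config.sub_num)
        if config.sub_num is not None
        else (list(group.subject_ids) if group.subject_ids is not None else None)
    )
    if sub_labels_meta is not None and len(sub_labels_meta) != group.n_subjects:
        raise ConfigError(
            f"subject-number list has length {len(sub_labels_meta)}, "
            f"expected {group.n_subjects}"
        )
    chan_labels = (
        list(config.chan_name)
        if config.chan_name is not None
        else (list(group.channel_names) if group.channel_names is not None else None)
    )
    if chan_labels is not None and len(chan_labels) != group.n_channels:
        raise ConfigError(
            f"channel-name list has length {len(chan_labels)}, "
            f"expected {group.n_channels}"
        )
    sub_idx = _resolve_selector(
        default("subs", None), group.n_subjects, sub_labels_meta, "subject"
    )
    chan_idx = _resolve_selector(
        default("chans", None), group.n_channels, chan_labels, "channel"
    )
    if sub_labels_meta is not None:
        subject_labels = [sub_labels_meta[i] for i in sub_idx]
    else:
        subject_labels = [int(i) for i in sub_idx]

    # --- windows ------------------------------------------------------------
    full_range_units = (timemap.to_units(0), timemap.to_units(n_time - 1))
    peak_win_u = default("peak_win", full_range_units)
    peak_win = timemap.window_to_samples(peak_win_u)
    if peak_win[0] >= peak_win[1]:
        raise ConfigError(f"peak window {peak_win_u!r} must span at least 2 samples")

    mean_time_u = default("mean_time", tuple(peak_win_u))
    mean_win = timemap.window_to_samples(mean_time_u)

    pw_raw = default("peak_width", None)
    if pw_raw is None:
        peak_width = 5
    elif timemap.identity:
        peak_width = int(pw_raw)
    else:
        peak_width = abs(timemap.duration_to_samples(pw_raw))
    if peak_width < 0 or (
        pw_raw is not None and timemap.identity and float(pw_raw) != int(pw_raw)
    ):
        raise ConfigError("peak_width must be a non-negative whole number of samples")

    # --- counter peak -------------------------------------------------------
    if config.c_win is not None and config.c_win_width is not None:
        raise ConflictError("c_win and c_win_width are mutually exclusive")
    c_win_start = default("c_win_start", "peakWin")
    if c_win_start not in ("peak", "peakWin"):
        raise ConfigError(f"c_win_start must be 'peak' or 'peakWin', got {c_win_start!r}")
    counter = config.c_win is not None or config.c_win_width is not None
    c_win = None
    c_win_width = None
    if config.c_win is not None:
        c_win = timemap.window_to_samples(config.c_win)
    elif config.c_win_width is not None:
        if timemap.identity:
            c_win_width = int(config.c_win_width)
        else:
            c_win_width = timemap.duration_to_samples(config.c_win_width)
        if c_win_width == 0:
            raise ConfigError("c_win_width must be non-zero")

    # --- fractions, modes ---------------------------------------------------
    perc_area = float(default("perc_area", 0.5))
    if not 0.0 < perc_area < 1.0:
        raise ConfigError(f"perc_area must be in (0, 1), got {perc_area}")
    perc_amp = float(default("perc_amp", 0.5))
    if not 0.0 < perc_amp <= 1.0:
        raise ConfigError(f"perc_amp must be in (0, 1], got {perc_amp}")

    area_win_raw = default("area_win", "peakWin")
    if isinstance(area_win_raw, str):
        if area_win_raw not in ("peakWin", "ampLat", "fullRange"):
            raise ConfigError(
                f"area_win must be 'peakWin', 'ampLat', 'fullRange' or an "
                f"explicit window, got {area_win_raw!r}"
            )
        area_win: Union[str, tuple[int, int]] = area_win_raw
    else:
        area_win = timemap.window_to_samples(area_win_raw)

    area_base = default("area_base", "zero")
    if area_base not in ("zero", "percAmp"):
        raise ConfigError(f"area_base must be 'zero' or 'percAmp', got {area_base!r}")

    amp_lat_raw = default("amp_lat_win", "fullRange")
    if isinstance(amp_lat_raw, str):
        if amp_lat_raw == "fullRange":
            amp_lat_win = (0, n_time - 1)
        elif amp_lat_raw == "peakWin":
            amp_lat_win = peak_win
        else:
            raise ConfigError(
                f"amp_lat_win must be 'fullRange', 'peakWin' or an explicit "
                f"window, got {amp_lat_raw!r}"
            )
    else:
        amp_lat_win = timemap.window_to_samples(amp_lat_raw)

    aggregate = default("aggregate", "individual")
    if aggregate not in AGGREGATE_MODES:
        raise ConfigError(
            f"aggregate must be one of {AGGREGATE_MODES}, got {aggregate!r}"
        )

    extract_raw = default("extract", "all")
    if isinstance(extract_raw, str):
        names = (
            list(ALL_MEASURES)
            if extract_raw == "all"
            else [s.strip() for s in extract_raw.split(",")]
        )
    else:
        names = list(extract_raw)
    for name in names:
        if name not in ALL_MEASURES:
            raise ConfigError(
                f"unknown measure {name!r}; choose from {ALL_MEASURES}"
            )
    if not counter and extract_raw == "all":
        names = [n for n in names if n != "peak2peak"]
    if "peak2peak" in names and not counter:
        raise ConfigError(
            "peak2peak requires a counter peak (set c_win or c_win_width)"
        )
    extract = tuple(dict.fromkeys(names))

    fig = bool(default("fig", False))
    c_bound = bool(default("c_bound", True))
    warn = bool(default("warnings", True))

    filled_cfg = dataclasses.replace(
        config,
        sign=sign,
        extract=extract,
        aggregate=aggregate,
        fig=fig,
        peak_win=tuple(peak_win_u),
        mean_time=tuple(mean_time_u),
        peak_width=peak_width if timemap.identity else peak_width * timemap.dt,
        c_win_start=c_win_start,
        perc_area=perc_area,
        perc_amp=perc_amp,
        area_win=area_win_raw,
        area_base=area_base,
        amp_lat_win=amp_lat_raw,
        c_bound=c_bound,
        warnings=warn,
    )

    return EffectiveConfig(
        sign=sign,
        extract=extract,
        aggregate=aggregate,
        fig=fig,
        sub_idx=sub_idx,
        chan_idx=chan_idx,
        peak_win=peak_win,
        mean_win=mean_win,
        peak_width=peak_width,
        counter=counter,
        c_win_start=c_win_start,
        c_win_width=c_win_width,
        c_win=c_win,
        perc_area=perc_area,
        perc_amp=perc_amp,
        area_win=area_win,
        area_base=area_base,
        amp_lat_win=amp_lat_win,
        c_bound=c_bound,
        warnings=warn,
        timemap=timemap,
        subject_labels=subject_labels,
        filled=tuple(filled),
        config=filled_cfg,
    )


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class ComponentMeasures:
    """All measures extracted from one waveform.

    Latencies are in the units of the time axis (samples when none was
    given); amplitudes are in sign-adjusted data units, i.e. the component
    of interest is a positive deflection regardless of its recorded
    polarity.
    """

    peak_lat: float = np.nan
    onset: float = np.nan
    offset: float = np.nan
    width: float = np.nan
    area_lat: float = np.nan
    counter_lat: float = np.nan
    peak_amp: float = np.nan
    mean: float = np.nan
    peak2peak: float = np.nan
    counter_amp: float = np.nan
    baseline: float = np.nan
    perc_amp_value: float = np.nan
    area: float = np.nan
    found_local: bool = True
    found_on: bool = True
    found_off: bool = True
    found_area: bool = True
    counter_local: bool = True

    _FIELD_FOR_MEASURE = {
        "mean": "mean",
        "peakLat": "peak_lat",
        "onset": "onset",
        "offset": "offset",
        "width": "width",
        "areaLat": "area_lat",
        "peakAmp": "peak_amp",
        "peak2peak": "peak2peak",
        "percAmp": "perc_amp_value",
        "area": "area",
        "counterAmp": "counter_amp",
        "counterLat": "counter_lat",
        "baseline": "baseline",
    }

    _FOUND_FOR_MEASURE = {
        "peakLat": "found_local",
        "onset": "found_on",
        "offset": "found_off",
        "width": "found_on",  # meaningful only with both crossings
        "areaLat": "found_area",
        "counterLat": "counter_local",
        "counterAmp": "counter_local",
    }

    def value(self, measure: str) -> float:
        return getattr(self, self._FIELD_FOR_MEASURE[measure])

    def found(self, measure: str) -> bool:
        flag = self._FOUND_FOR_MEASURE.get(measure)
        if flag is None:
            return True
        if measure == "width":
            return bool(self.found_on and self.found_off)
        return bool(getattr(self, flag))

    def as_dict(self) -> dict:
        out = {m: self.value(m) for m in self._FIELD_FOR_MEASURE}
        out.update(
            foundLocal=self.found_local,
            foundOn=self.found_on,
            foundOff=self.found_off,
            foundArea=self.found_area,
        )
        return out


@dataclass
class ResultsTable:
    """Tidy per-unit × measure results plus the run annotation.

    ``table`` has columns ``unit_id`` (subject number, leave-one-out index,
    or ``"GA"``), ``measure``, ``value``, ``found``, ``aggregate``.
    ``annotation`` records every effective parameter value plus which fields
    were default-filled.
    """

    table: pd.DataFrame
    annotation: dict = field(default_factory=dict)

    def wide(self) -> pd.DataFrame:
        """Pivot to one row per unit, one column per measure."""
        return self.table.pivot(index="unit_id", columns="measure", values="value")

    def values(self, measure: str) -> np.ndarray:
        sub = self.table[self.table["measure"] == measure]
        return sub["value"].to_numpy()
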