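"""Individual, grand-average, and jackknife latency estimates.

Jackknife (leave-one-out) estimation extracts latencies from the *n*
averages that each omit one subject: because n−1 subjects contribute to
every average, single-subject noise is strongly suppressed, at the price of
shrinking the between-estimate variance by a factor (n−1)² — which the
statistics module corrects for.  Smulders retrieval maps jackknife
estimates back to per-subject scores via ``O_i = n·G − (n−1)·J_i`` with the
grand-average estimate G as anchor, recovering individual values exactly
for linear measures.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extraction import extract_measures, prepare_waveforms
from .model import (
    ComponentMeasures,
    EffectiveConfig,
    GroupAverages,
    LatencyConfig,
    LatencyWarning,
    ResultsTable,
    validate_and_fill,
)

__all__ = [
    "AggregatedEstimates",
    "leave_one_out_averages",
    "smulders_retrieve",
    "aggregate_extract",
    "extract_group",
]


@dataclass
class AggregatedEstimates:
    """Per-measure estimate vectors for one aggregation mode.

    ``values[measure]`` has length n for ``individual``/``jackSmulders``,
    n+1 for ``jackMiller`` (the grand-average estimate last), and 1 for
    ``GA``.
    """

    mode: str
    n: int
    values: dict[str, np.ndarray] = field(default_factory=dict)
    unit_ids: list = field(default_factory=list)
    measures_per_unit: list = field(default_factory=list)

    def jack(self, measure: str) -> np.ndarray:
        """The n jackknife values, grand-average entry excluded."""
        if self.mode != "jackMiller":
            raise ValueError("jack values only exist in jackMiller mode")
        return self.values[measure][:-1]

    def ga(self, measure: str) -> float:
        if self.mode == "GA":
            return float(self.values[measure][0])
        if self.mode == "jackMiller":
            return float(self.values[measure][-1])
        raise ValueError(f"no grand-average entry in mode {self.mode!r}")


def leave_one_out_averages(waveforms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out means and the grand average of per-subject waveforms.

    ``waveforms`` is Subjects × Time (already channel-averaged and
    sign-adjusted).  Row i of the result omits subject i; subject order is
    preserved.  Requires n ≥ 3 — below that the jackknife variance is
    degenerate.
    """
    waveforms = np.asarray(waveforms, dtype=float)
    n = waveforms.shape[0]
    if n < 3:
        raise ValueError(f"jackknife requires at least 3 subjects, got {n}")
    total = waveforms.sum(axis=0)
    loo = (total[None, :] - waveforms) / (n - 1)
    return loo, total / n


def smulders_retrieve(
    jack_values: np.ndarray, grand_average_value: float, n: int | None = None
) -> np.ndarray:
    """Per-subject scores restored from jackknife estimates.

    ``O_i = n·G − (n−1)·J_i`` where G is the grand-average-based estimate.
    Exact inversion for linear statistics; for nonlinear latency measures an
    approximation that retains the jackknife's noise suppression.
    """
    jack_values = np.asarray(jack_values, dtype=float)
    if n is None:
        n = jack_values.size
    if n < 3:
        raise ValueError(f"retrieval requires at least 3 subjects, got {n}")
    if not np.all(np.isfinite(jack_values)):
        raise ValueError("jackknife values must be finite")
    return n * float(grand_average_value) - (n - 1) * jack_values


def _units_for_mode(
    waveforms: np.ndarray, mode: str, subject_labels: list
) -> tuple[list[np.ndarray], list[str]]:
    """The waveforms actually extracted from, per aggregation mode."""
    n = waveforms.shape[0]
    if mode == "individual":
        return list(waveforms), [str(lbl) for lbl in subject_labels]
    if mode == "GA":
        return [waveforms.mean(axis=0)], ["GA"]
    loo, ga = leave_one_out_averages(waveforms)
    return list(loo) + [ga], [str(i) for i in range(n)] + ["GA"]


def unit_waveforms(
    group: GroupAverages, cfg: EffectiveConfig
) -> tuple[list[np.ndarray], list[str]]:
    """Channel-averaged, sign-adjusted waveforms per extraction unit

    (subjects, leave-one-out averages + GA, or the grand average alone,
    depending on ``cfg.aggregate``) — what the diagnostics plot.
    """
    return _units_for_mode(
        prepare_waveforms(group, cfg), cfg.aggregate, cfg.subject_labels
    )


def _emit_quality_warnings(
    per_unit: list[ComponentMeasures], cfg: EffectiveConfig, what: str
) -> list[str]:
    """The >half-of-subjects fallback warnings; returns the messages.

    Silent (and empty) when warnings are disabled — the found-flags in the
    results table carry the same information either way.
    """
    if not cfg.warnings:
        return []
    n = len(per_unit)
    messages = []
    n_no_local = sum(not m.found_local for m in per_unit)
    if n_no_local > n / 2:
        messages.append(
            f"no local peak found for {n_no_local} of {n} {what}; the peak "
            f"search window is probably too narrow — consider widening peakWin"
        )
    n_on = sum(not m.found_on for m in per_unit)
    if n_on > n / 2:
        messages.append(
            f"onset pinned to the search boundary for {n_on} of {n} {what}; "
            f"consider a counter-peak anchor or a wider ampLatWin"
        )
    n_off = sum(not m.found_off for m in per_unit)
    if n_off > n / 2:
        messages.append(
            f"offset pinned to the search boundary for {n_off} of {n} {what}; "
            f"consider a counter-peak anchor or a wider ampLatWin"
        )
    for msg in messages:
        _warnings.warn(msg, LatencyWarning, stacklevel=3)
    return messages


def aggregate_extract(
    group: GroupAverages, config: LatencyConfig | EffectiveConfig
) -> tuple[AggregatedEstimates, ResultsTable]:
    """Extract the configured measures under the configured aggregation.

    * ``individual`` — one extraction per subject.
    * ``GA`` — one extraction from the grand average.
    * ``jackMiller`` — one extraction per leave-one-out average, plus the
      grand-average extraction as the final entry.
    * ``jackSmulders`` — jackMiller followed by per-measure retrieval of
      individual scores.
    """
    cfg = validate_and_fill(config, group)
    waveforms = prepare_waveforms(group, cfg)
    n = waveforms.shape[0]
    mode = cfg.aggregate
    units, unit_ids = _units_for_mode(waveforms, mode, cfg.subject_labels)

    per_unit = [extract_measures(w, cfg) for w in units]
    warn_units = per_unit[:-1] if mode in ("jackMiller", "jackSmulders") else per_unit
    what = "leave-one-out averages" if mode != "individual" else "subjects"
    messages = (
        _emit_quality_warnings(warn_units, cfg, what) if mode != "GA" else []
    )

    values = {
        m: np.array([u.value(m) for u in per_unit]) for m in cfg.extract
    }
    found = {m: [u.found(m) for u in per_unit] for m in cfg.extract}

    if mode == "jackSmulders":
        retrieved = {
            m: smulders_retrieve(v[:-1], v[-1], n) for m, v in values.items()
        }
        values = retrieved
        found = {m: f[:-1] for m, f in found.items()}
        per_unit = per_unit[:-1]
        unit_ids = [str(lbl) for lbl in cfg.subject_labels]

    est = AggregatedEstimates(
        mode=mode,
        n=n,
        values=values,
        unit_ids=unit_ids,
        measures_per_unit=per_unit,
    )

    rows = []
    for m in cfg.extract:
        for uid, val, fnd in zip(unit_ids, values[m], found[m]):
            rows.append(
                {
                    "unit_id": uid,
                    "measure": m,
                    "value": float(val),
                    "found": bool(fnd),
                    "aggregate": mode,
                }
            )
    annotation = cfg.annotation()
    annotation["warnings_emitted"] = messages
    table = ResultsTable(table=pd.DataFrame(rows), annotation=annotation)
    return est, table


def extract_group(
    group: GroupAverages, config: LatencyConfig | dict | EffectiveConfig
) -> ResultsTable:
    """Convenience wrapper: configuration (object or mapping) in, tidy table out."""
    if isinstance(config, dict):
        config = LatencyConfig.from_dict(config)
    _, table = aggregate_extract(group, config)
    return table
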