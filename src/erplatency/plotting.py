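"""Per-subject diagnostic figures.

One figure per extracted unit: the sign-adjusted waveform with the peak
search and area windows shaded, the component area filled, markers at the
peak, counter peak, on/offset, and area-split latency, and a horizontal
line at the effective threshold/baseline.  Inspecting these is the fastest
way to spot a mis-set window or an anomalous individual average.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .model import ComponentMeasures, EffectiveConfig

__all__ = ["plot_diagnostics", "save_diagnostics"]

logger = logging.getLogger(__name__)


def plot_diagnostics(
    w: np.ndarray,
    measures: ComponentMeasures,
    cfg: EffectiveConfig,
    ax: Optional[plt.Axes] = None,
    title: str = "",
) -> plt.Figure:
    """Render one waveform with all extracted measures overlaid."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(8, 4))
    else:
        fig = ax.figure
    tm = cfg.timemap
    t = tm.axis
    w = np.asarray(w, dtype=float)
    ax.plot(t, w, color="0.2", lw=1.0, label="waveform (sign-adjusted)")

    ax.axvspan(
        tm.to_units(cfg.peak_win[0]),
        tm.to_units(cfg.peak_win[1]),
        color="tab:blue",
        alpha=0.10,
        label="peak window",
    )

    if np.isfinite(measures.area_lat):
        base = measures.baseline if np.isfinite(measures.baseline) else 0.0
        # shade only above-baseline samples inside the effective area span
        if np.isfinite(measures.onset) and cfg.area_win == "ampLat":
            lo_t, hi_t = measures.onset, measures.offset
        elif cfg.area_win == "peakWin":
            lo_t, hi_t = tm.to_units(cfg.peak_win[0]), tm.to_units(cfg.peak_win[1])
        elif cfg.area_win == "fullRange":
            lo_t, hi_t = t[0], t[-1]
        else:
            lo_t, hi_t = tm.to_units(cfg.area_win[0]), tm.to_units(cfg.area_win[1])
        mask = (t >= lo_t) & (t <= hi_t) & (w > base)
        ax.fill_between(
            t, base, w, where=mask, color="tab:blue", alpha=0.35, label="component area"
        )
        ax.axhline(base, color="tab:orange", lw=0.8, ls="--", label="area baseline")
        ax.axvline(measures.area_lat, color="tab:blue", lw=1.2, label="areaLat")

    if np.isfinite(measures.perc_amp_value):
        ax.axhline(
            measures.perc_amp_value,
            color="tab:green",
            lw=0.8,
            ls=":",
            label="percAmp threshold",
        )

    def marker(x, label, color):
        if np.isfinite(x):
            y = float(np.interp(x, t, w))
            ax.plot([x], [y], "o", color=color, ms=6, label=label)

    marker(measures.peak_lat, "peak", "tab:red")
    marker(measures.counter_lat, "counter peak", "tab:purple")
    marker(measures.onset, "onset", "tab:green")
    marker(measures.offset, "offset", "tab:olive")

    ax.set_xlabel("samples" if tm.identity else "time")
    ax.set_ylabel("amplitude (sign-adjusted)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=7, ncol=2)
    fig.tight_layout()
    return fig


def save_diagnostics(
    waveforms: Sequence[np.ndarray],
    per_unit: Sequence[ComponentMeasures],
    cfg: EffectiveConfig,
    outdir: str | Path,
    unit_ids: Sequence[str],
    prefix: str = "diagnostic",
) -> list[Path]:
    """One image per unit; plotting failures are logged, never fatal."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for w, m, uid in zip(waveforms, per_unit, unit_ids):
        path = outdir / f"{prefix}_{uid}.png"
        try:
            fig = plot_diagnostics(w, m, cfg, title=f"unit {uid}")
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
        except Exception:  # noqa: BLE001 - diagnostics must not kill a run
            logger.exception("diagnostic figure for unit %s failed", uid)
    return written
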