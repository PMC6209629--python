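"""Statistical tests for latency estimates.

Jackknife estimates cannot be fed to an ordinary t-test: averaging over
n−1 subjects shrinks the between-estimate standard deviation by a factor
n−1, which would inflate the naive t by the same factor.
:func:`jackknife_paired_t` therefore divides the naive paired t on the
jackknife difference scores by n−1 — for a linear statistic this recovers
the classical paired t on the individual values exactly.

:func:`disattenuated_correlation` corrects an observed correlation between
two latency measures for their measurement unreliability,
``r_corr = r_xy / sqrt(r_xx · r_yy)``, capped at magnitude 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .model import DegenerateDataError

__all__ = [
    "PairedTestResult",
    "CorrelationResult",
    "paired_t",
    "jackknife_paired_t",
    "pearson_r",
    "disattenuated_correlation",
]


@dataclass
class PairedTestResult:
    """Paired-contrast result: mean difference, t, df = n−1, two-sided p."""

    mean_diff: float
    t: float
    df: int
    p: float
    n: int

    def report(self, unit: str = "ms", scale: float = 1.0) -> str:
        """Reporting-style string, e.g. ``t(15) = 3.39, p = 0.004, d = 90.2 ms``."""
        return (
            f"t({self.df}) = {abs(self.t):.2f}, p = {self.p:.3f}, "
            f"d = {self.mean_diff * scale:.1f} {unit}"
        )


@dataclass
class CorrelationResult:
    """Pearson correlation with its two-sided p (t-based, df = n−2)."""

    r: float
    p: float
    n: int

    def report(self) -> str:
        return f"r = {self.r:.2f}, p = {self.p:.3f}"


def _diffs(a, b) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D vectors of equal length")
    return a - b


def paired_t(a, b) -> PairedTestResult:
    """Classical paired t-test on per-subject values.

    Two-sided p from the t distribution with n−1 degrees of freedom.
    Raises :class:`DegenerateDataError` when the differences have zero
    variance (t undefined).
    """
    d = _diffs(a, b)
    n = d.size
    if n < 2:
        raise DegenerateDataError("paired t needs at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return PairedTestResult(0.0, 0.0, n - 1, 1.0, n)
        raise DegenerateDataError("differences have zero variance")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * _sps.t.sf(abs(t), n - 1))
    return PairedTestResult(float(d.mean()), t, n - 1, p, n)


def jackknife_paired_t(jack_a, jack_b) -> PairedTestResult:
    """Paired t-test on jackknife estimates with the shrinkage correction.

    Input vectors are the n leave-one-out estimates per condition
    (grand-average entries must be excluded beforehand).  The naive paired
    t on the jackknife difference scores is divided by n−1 to undo the
    jackknife's variance shrinkage; df = n−1; the reported mean difference
    is the mean jackknife difference.
    """
    d = _diffs(jack_a, jack_b)
    n = d.size
    if n < 3:
        raise DegenerateDataError("jackknife t needs at least 3 estimates")
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return PairedTestResult(0.0, 0.0, n - 1, 1.0, n)
        raise DegenerateDataError("jackknife differences have zero variance")
    t_naive = d.mean() / (sd / np.sqrt(n))
    t = float(t_naive / (n - 1))
    p = float(2 * _sps.t.sf(abs(t), n - 1))
    return PairedTestResult(float(d.mean()), t, n - 1, p, n)


def pearson_r(a, b) -> CorrelationResult:
    """Pearson correlation with a two-sided t-based p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("correlation needs paired 1-D vectors of length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateDataError("correlation undefined for constant input")
    res = _sps.pearsonr(a, b)
    return CorrelationResult(float(res.statistic), float(res.pvalue), a.size)


def disattenuated_correlation(
    r_xy: float, r_xx: float, r_yy: float
) -> tuple[float, float]:
    """Correlation corrected for attenuation by measurement unreliability.

    ``r_corr = r_xy / sqrt(r_xx · r_yy)`` with the reliabilities of the two
    measures, capped at magnitude 1 (the raw ratio can exceed 1 when
    reliabilities are themselves noisy estimates).  Returns
    ``(exact capped value, value rounded to 2 decimals)``.
    """
    if not (0.0 < r_xx <= 1.0 and 0.0 < r_yy <= 1.0):
        raise ValueError("reliabilities must lie in (0, 1]")
    if abs(r_xy) > 1.0:
        raise ValueError("|r_xy| must not exceed 1")
    raw = r_xy / np.sqrt(r_xx * r_yy)
    capped = float(np.clip(raw, -1.0, 1.0))
    return capped, round(capped, 2)
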