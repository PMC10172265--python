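"""Creep and recovery statistics for cyclic spine loading.

Within a 30-minute loading block the range of motion (RoM) at peak moment
creeps upward; across the 15-minute breaks it partially recovers.  Two ratios
summarize this:

* ``r_load = RoM_3,start / RoM_30min`` — third-cycle over last-cycle RoM of a
  block; values below 1 indicate creep.
* ``r_break = RoM_30min / RoM_3,break`` — last pre-break over third post-break
  RoM; values above 1 indicate partial recovery during the break.

The module also provides the Kendall-τ correlation against total testing
time, the Fisher z comparison of two correlations, the normalization of RoM
progressions to the third cycle of the first block, and the rank tests used
for group comparisons (Wilcoxon signed-rank, Mann–Whitney U, Shapiro–Wilk).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CreepRatios",
    "CorrelationResult",
    "compute_ratios",
    "kendall_tau",
    "fisher_compare",
    "normalize_progression",
    "rank_tests",
]

ALPHA = 0.05


@dataclass(frozen=True)
class CreepRatios:
    """Creep (r_load) and recovery (r_break) ratios of one loading block."""

    sequence_id: str
    r_load: float
    r_break: float | None
    rom_3_start: float
    rom_30min: float
    rom_3_break: float | None


@dataclass(frozen=True)
class CorrelationResult:
    """Kendall rank correlation with its two-sided p-value."""

    tau: float
    n: int
    p_value: float
    group_label: str = ""


def compute_ratios(
    rom_trace,
    rom_3_break: float | None = None,
    sequence_id: str = "",
) -> CreepRatios:
    """Creep ratios from a per-cycle trace of absolute RoM at +7.5 Nm.

    ``rom_trace`` is ordered by cycle; its 3rd entry is ``RoM_3,start`` and its
    last entry ``RoM_30min``.  ``rom_3_break`` (third cycle after the break)
    yields ``r_break`` when given.
    """
    trace = np.asarray(rom_trace, dtype=float)
    if trace.size < 3:
        raise ValueError("compute_ratios needs at least 3 cycles")
    if np.any(trace <= 0) or (rom_3_break is not None and rom_3_break <= 0):
        raise ValueError("RoM values must be positive")
    rom_3_start = float(trace[2])
    rom_30min = float(trace[-1])
    r_load = rom_3_start / rom_30min
    r_break = None if rom_3_break is None else rom_30min / float(rom_3_break)
    return CreepRatios(sequence_id, r_load, r_break, rom_3_start, rom_30min, rom_3_break)


def kendall_tau(x, y, group_label: str = "") -> CorrelationResult:
    """Tie-corrected Kendall τ-b with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("kendall_tau needs equal-length inputs with n ≥ 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for an all-tied variable")
    res = stats.kendalltau(x, y)
    return CorrelationResult(float(res.statistic), int(x.size), float(res.pvalue), group_label)


def fisher_compare(tau1: float, n1: int, tau2: float, n2: int) -> float:
    """Two-sided p-value for the difference of two rank correlations.

    Applies Fisher's transformation z = artanh(τ) with variance 1/(n−3) per
    group and compares Z = (z1 − z2)/sqrt(v1 + v2) against the standard
    normal.
    """
    for tau in (tau1, tau2):
        if abs(tau) >= 1.0:
            raise ValueError("Fisher transformation is infinite at |tau| = 1")
    if min(n1, n2) <= 4:
        raise ValueError("fisher_compare needs group sizes above 4")
    z1, z2 = np.arctanh(tau1), np.arctanh(tau2)
    z = (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * stats.norm.sf(abs(z)))


def normalize_progression(rom_trace):
    """Normalize a per-cycle RoM trace to its 3rd cycle (maps cycle 3 to 1)."""
    trace = np.asarray(rom_trace, dtype=float)
    if trace.size < 3:
        raise ValueError("normalization needs at least 3 cycles")
    ref = trace[2]
    if ref == 0:
        raise ValueError("third-cycle RoM is zero; normalization undefined")
    return trace / ref


def rank_tests(group_a, group_b, paired: bool = False) -> dict[str, float]:
    """Standard two-sided rank tests between two groups.

    Returns Wilcoxon signed-rank (paired) or Mann–Whitney U (unpaired)
    p-values plus Shapiro–Wilk normality p-values per group.  Delegates to
    scipy's reference implementations.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if min(a.size, b.size) < 3:
        raise ValueError("rank tests need group sizes ≥ 3")
    out: dict[str, float] = {}
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal-length groups")
        if np.all(a == b):
            # no nonzero differences: the signed-rank statistic is degenerate
            out["wilcoxon_p"] = 1.0
        else:
            out["wilcoxon_p"] = float(stats.wilcoxon(a, b).pvalue)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        out["mannwhitneyu_p"] = float(res.pvalue)
        out["mannwhitneyu_U"] = float(res.statistic)
    out["shapiro_p_a"] = float(stats.shapiro(a).pvalue)
    out["shapiro_p_b"] = float(stats.shapiro(b).pvalue)
    return out
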