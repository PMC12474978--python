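"""Shared 2x2 contingency machinery: exact tests, odds ratios, Woolf CIs.

The exact p-value is the two-sided Fisher test: the sum over hypergeometric
outcomes (at fixed margins) whose probability does not exceed that of the
observed table.  Point odds ratios use the sample (cross-product) estimate;
when any cell is zero a Haldane–Anscombe 0.5 is added to every cell for
the odds ratio and its Woolf log-normal confidence interval — the exact
p-value itself is never continuity-corrected.
"""
from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy.stats import fisher_exact, norm


class ZeroMarginError(ValueError):
    """A 2x2 margin is zero; the exact test is undefined."""


def validate_table(table: Sequence[Sequence[float]]) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table cells must be nonnegative integers")
    return t.astype(np.int64)


def check_margins(table: np.ndarray) -> None:
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ZeroMarginError(f"zero margin in table {table.tolist()}")


def fisher_two_sided_p(table: Sequence[Sequence[float]]) -> float:
    """Two-sided Fisher exact p by hypergeometric probability summation."""
    t = validate_table(table)
    check_margins(t)
    return float(fisher_exact(t, alternative="two-sided")[1])


def sample_odds_ratio(table: Sequence[Sequence[float]]) -> float:
    """(a*d)/(b*c), with +0.5 in every cell when any cell is zero."""
    t = validate_table(table).astype(float)
    if np.any(t == 0):
        t = t + 0.5
    return float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))


def woolf_ci(
    table: Sequence[Sequence[float]], alpha: float = 0.05
) -> Tuple[float, float]:
    """Woolf log-normal CI on the (possibly corrected) sample odds ratio."""
    t = validate_table(table).astype(float)
    if np.any(t == 0):
        t = t + 0.5
    log_or = np.log((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
    se = np.sqrt((1.0 / t).sum())
    z = norm.ppf(1 - alpha / 2)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))
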