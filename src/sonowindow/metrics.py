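"""Shared statistics and unit conversions.

One-sided pooled-variance two-sample t-tests (the MATLAB ``ttest2``
convention), median/range summaries for small samples, and the dB <->
percent-intensity conversions used when reporting clutter reductions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TTestResult",
    "one_sided_ttest",
    "db_to_percent_reduction",
    "percent_reduction_to_db",
    "percent_reflection_reduction",
    "median_range",
    "wavelength_mm",
]


@dataclass(frozen=True)
class TTestResult:
    """Result of a one-sided two-sample pooled-variance t-test.

    ``direction`` records which group was hypothesized to be lower
    (``"a_less"`` or ``"a_greater"``). ``flagged`` marks the degenerate
    zero-pooled-variance / equal-means case where p = 0.5 by convention.
    """

    t_statistic: float
    p_value: float
    df: int
    direction: str
    flagged: bool = False


def one_sided_ttest(group_a, group_b, direction: str = "a_less") -> TTestResult:
    """Pooled-variance (equal-variance) two-sample t-test, one-sided.

    Parameters
    ----------
    group_a, group_b : array-like
        Independent samples, each with at least two observations.
    direction : {"a_less", "a_greater"}
        Alternative hypothesis: whether ``group_a``'s mean is below or
        above ``group_b``'s.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if direction not in ("a_less", "a_greater"):
        raise ValueError(f"unknown direction {direction!r}")
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, 0.5, df, direction, flagged=True)
        t = np.inf if diff > 0 else -np.inf
    else:
        t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if direction == "a_less":
        p = stats.t.cdf(t, df)
    else:
        p = stats.t.sf(t, df)
    return TTestResult(float(t), float(p), df, direction)


def db_to_percent_reduction(delta_db: float) -> float:
    """Percent intensity reduction corresponding to a dB change.

    Uses the power convention 10^(dB/10): -2.0 dB -> 36.9 %.
    """
    return float((1.0 - 10.0 ** (np.asarray(delta_db, dtype=float) / 10.0)) * 100.0)


def percent_reduction_to_db(percent: float) -> float:
    """Inverse of :func:`db_to_percent_reduction`; defined for percent < 100."""
    p = np.asarray(percent, dtype=float)
    if np.any(p >= 100.0):
        raise ValueError("a 100 % reduction has no finite dB equivalent")
    return float(10.0 * np.log10(1.0 - p / 100.0))


def percent_reflection_reduction(gamma_material: float, gamma_glass: float = 0.797) -> float:
    """Percent reduction in amplitude reflection coefficient relative to glass."""
    if gamma_glass <= 0:
        raise ValueError("reference reflection coefficient must be positive")
    return float((1.0 - gamma_material / gamma_glass) * 100.0)


def median_range(values) -> tuple[float, float]:
    """Sample median and range (max - min); even-n median averages the middle two."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    return float(np.median(v)), float(v.max() - v.min())


def wavelength_mm(frequency_hz: float, c_mps: float = 1480.0) -> float:
    """Acoustic wavelength in mm for a frequency in Hz."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    return c_mps / frequency_hz * 1e3
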