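"""Downstream statistics: doubling time, t-test, Fisher's exact test,
and orientation-uniformity tests for folded axial angles."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ComputationError, ConfigurationError

__all__ = [
    "GrowthRecord", "doubling_time", "two_sample_t", "fisher_exact",
    "angle_uniformity_test", "star_bin",
]


@dataclass
class GrowthRecord:
    n1: float
    n2: float
    dt_hours: float
    td_hours: float


def doubling_time(n1: float, n2: float, dt_hours: float) -> float:
    """Exponential doubling time ``dt * ln 2 / ln(n2 / n1)`` in hours.

    Negative (a halving time) when the population declines; infinite with a
    warning when the counts are equal.
    """
    if n1 <= 0 or n2 <= 0:
        raise ConfigurationError(
            f"counts must be positive, got n1={n1}, n2={n2}"
        )
    if dt_hours <= 0:
        raise ConfigurationError(f"dt_hours must be > 0, got {dt_hours}")
    if n2 == n1:
        warnings.warn(
            "doubling time undefined for equal counts; returning inf",
            stacklevel=2,
        )
        return math.inf
    return dt_hours * math.log(2.0) / math.log(n2 / n1)


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float],
                 variant: str = "pooled") -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns ``(t, df, p)``.

    ``variant='pooled'`` is the classic equal-variance Student test,
    ``'welch'`` the unequal-variance form.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError(
            f"each group needs n >= 2, got {len(a)} and {len(b)}"
        )
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ComputationError(
            "both groups have zero variance; the t statistic is undefined"
        )
    if variant == "pooled":
        res = sps.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    elif variant == "welch":
        res = sps.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
    else:
        raise ConfigurationError(f"unknown t-test variant {variant!r}")
    p = min(max(float(res.pvalue), np.nextafter(0.0, 1.0)), 1.0)
    return float(res.statistic), float(df), p


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums hypergeometric probabilities, at fixed margins, of every table at
    most as probable as the observed one.  Probabilities share the
    denominator C(n, row1), so the comparison is done on exact integer
    numerators and is immune to floating-point ties.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ConfigurationError(
            f"need a 2x2 table of non-negative integers, got {table!r}"
        )
    if t.sum() == 0:
        raise ConfigurationError("table must have at least one positive cell")
    a, b, c, d = int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    k_lo = max(0, r1 + c1 - n)
    k_hi = min(r1, c1)
    weights = [
        math.comb(c1, k) * math.comb(n - c1, r1 - k)
        for k in range(k_lo, k_hi + 1)
    ]
    observed = weights[a - k_lo]
    p = sum(w for w in weights if w <= observed) / math.comb(n, r1)
    return min(float(p), 1.0)


def _rayleigh_axial_p(angles_deg: np.ndarray) -> float:
    """Rayleigh-style test for axial angles folded to [0, 90].

    The folded angle is doubled, so concentration about the reference axis
    shows up as a positive mean cosine; the one-sided V-test normal
    approximation gives the p-value.  Uniform folded angles give a mean
    cosine of zero.
    """
    n = len(angles_deg)
    cbar = float(np.mean(np.cos(np.radians(2.0 * angles_deg))))
    u = cbar * math.sqrt(2.0 * n)
    return float(sps.norm.sf(u))


def angle_uniformity_test(angles_deg: Sequence[float],
                          method: str = "ks") -> float:
    """Test folded axial angles (degrees, [0, 90]) against uniformity.

    ``method='ks'`` is a one-sample Kolmogorov-Smirnov test against
    Uniform(0, 90); ``'rayleigh_axial'`` a Rayleigh/V-test on the doubled
    folded angles, sensitive to concentration near 0.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if len(angles) < 5:
        raise ConfigurationError(
            f"need at least 5 angles, got {len(angles)}"
        )
    if np.any(angles < 0) or np.any(angles > 90):
        raise ConfigurationError("angles must lie in [0, 90] degrees")
    if method == "ks":
        p = float(sps.kstest(angles, sps.uniform(loc=0, scale=90).cdf).pvalue)
    elif method == "rayleigh_axial":
        p = _rayleigh_axial_p(angles)
    else:
        raise ConfigurationError(f"unknown uniformity method {method!r}")
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def star_bin(p: float) -> str:
    """Render a p-value as the figure-legend star convention."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
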