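"""Two-sample Kolmogorov–Smirnov comparison of sensitivity samples.

Used to decide whether the measured-based and extrapolation-based species
sensitivity samples could come from the same distribution.  The statistic
D is the supremum distance between the two empirical CDFs (right-
continuous convention, F(x) = #{values <= x}/n), computed by a pooled
sweep over the sample points.  Alongside D the scaled statistic

    Z = D * sqrt(n1*n2 / (n1 + n2))

is reported, because statistical packages often print Z where papers say
"ks"; reporting both avoids the ambiguity.  The p-value is exact (network
enumeration, via scipy) when n1*n2 <= 10^4, otherwise the asymptotic
Kolmogorov tail Q(z) = 2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 z^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .exceptions import InsufficientDataError

__all__ = ["KSResult", "ks_two_sample"]

#: largest n1*n2 for which the exact p-value is used by default
EXACT_LIMIT = 10_000


@dataclass(frozen=True)
class KSResult:
    d_stat: float
    z_stat: float
    p_value: float
    n1: int
    n2: int
    method: str


def _ks_statistic(s1: np.ndarray, s2: np.ndarray) -> float:
    # sweep of |ECDF1 - ECDF2| over the pooled sorted points
    pooled = np.sort(np.concatenate([s1, s2]))
    cdf1 = np.searchsorted(np.sort(s1), pooled, side="right") / s1.size
    cdf2 = np.searchsorted(np.sort(s2), pooled, side="right") / s2.size
    return float(np.max(np.abs(cdf1 - cdf2)))


def ks_two_sample(sample1, sample2, method: str = "auto") -> KSResult:
    """Two-sample two-sided Kolmogorov–Smirnov test.

    Parameters
    ----------
    sample1, sample2 : array-like of float
        Non-empty, finite samples (any common monotone transform of both
        leaves the result unchanged).
    method : {"auto", "exact", "asymptotic"}
        "auto" uses the exact p-value when n1*n2 <= 10^4.
    """
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    if not (np.all(np.isfinite(s1)) and np.all(np.isfinite(s2))):
        raise ValueError("samples must be finite")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    n1, n2 = int(s1.size), int(s2.size)
    if method == "auto":
        method = "exact" if n1 * n2 <= EXACT_LIMIT else "asymptotic"

    d = _ks_statistic(s1, s2)
    z = d * np.sqrt(n1 * n2 / (n1 + n2))
    if method == "exact":
        p = float(stats.ks_2samp(s1, s2, method="exact").pvalue)
    else:
        p = float(min(1.0, special.kolmogorov(z)))
    return KSResult(d_stat=d, z_stat=float(z), p_value=p, n1=n1, n2=n2, method=method)
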