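"""Log-logistic species sensitivity distributions and hazardous concentrations.

The SSD models the fraction of species affected at a concentration
``10**X`` (X in log10 μg/L) as a logistic curve

    Y(X) = 1 / (1 + exp((alpha - X) / beta))

with location ``alpha`` (log10 μg/L; the concentration affecting half the
species) and slope ``beta > 0``.  Species-level toxicity values are ranked
ascending and assigned empirical cumulative probabilities by a plotting
position (Weibull ``i/(N+1)`` by default); ``(alpha, beta)`` minimize the
squared deviation of the curve from those probabilities.  The hazardous
concentration HC_p inverts the curve analytically:

    HC_p = 10 ** (alpha + beta * ln(p / (1 - p))).

Two fitting variants beyond the default least squares are provided:

``method="mle"``
    Maximum likelihood of the logistic distribution on the log10 values.

``asymptotes="free"``
    A four-parameter sigmoid whose lower/upper plateaus are estimated
    rather than pinned at 0 and 1 — the default behavior of the
    point-and-click curve-fitting software used in much of the published
    SSD literature, retained here so that such analyses can be reproduced
    exactly.  Because an unconstrained sigmoid is no longer a distribution
    function, HC_p then solves ``Y(X) = p`` on the absolute scale, which
    requires ``lower < p < upper``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .core_data import SpeciesToxicity
from .exceptions import DegenerateDesignError, InsufficientDataError

__all__ = [
    "SSDPoint",
    "SSDFit",
    "HCEstimate",
    "LogLogisticSSD",
    "plotting_positions",
    "fit_loglogistic",
    "hcp",
    "bootstrap_hcp",
]


@dataclass(frozen=True)
class SSDPoint:
    """One ranked species on the SSD: log10 value vs. cumulative probability."""

    species_name: str
    log10_value: float
    cumulative_probability: float
    rank: int


@dataclass(frozen=True)
class SSDFit:
    """Fitted SSD parameters plus the points they were fitted to.

    ``lower``/``upper`` are the curve asymptotes: 0 and 1 for a proper
    distribution (the default), estimated values in ``asymptotes="free"``
    mode.
    """

    alpha: float
    beta: float
    points: tuple[SSDPoint, ...]
    rss: float
    converged: bool
    lower: float = 0.0
    upper: float = 1.0

    def cdf(self, x: float | np.ndarray) -> float | np.ndarray:
        """Fraction of species affected at log10 concentration ``x``."""
        x = np.asarray(x, dtype=float)
        out = self.lower + (self.upper - self.lower) / (
            1.0 + np.exp((self.alpha - x) / self.beta)
        )
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class HCEstimate:
    """Hazardous concentration for a fraction ``p`` of species, in μg/L."""

    p: float
    hc_ugL: float
    ci_low_ugL: float | None = None
    ci_high_ugL: float | None = None
    n_boot: int = 0

    def __post_init__(self) -> None:
        if self.ci_low_ugL is not None and self.ci_high_ugL is not None:
            if not (self.ci_low_ugL <= self.hc_ugL <= self.ci_high_ugL):
                raise ValueError("confidence interval does not bracket the estimate")


_POSITIONS = ("weibull", "hazen")


def plotting_positions(n: int, kind: str = "weibull") -> np.ndarray:
    """Empirical cumulative probabilities for ranks 1..n.

    ``weibull``: i/(n+1) (the default; for n = 19 the smallest point sits
    exactly at 0.05).  ``hazen``: (i − 0.5)/n.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if kind not in _POSITIONS:
        raise ValueError(f"unknown plotting position {kind!r}")
    i = np.arange(1, n + 1, dtype=float)
    return i / (n + 1) if kind == "weibull" else (i - 0.5) / n


def _as_log10(values) -> tuple[np.ndarray, list[str]]:
    vals = list(values)
    if vals and isinstance(vals[0], SpeciesToxicity):
        names = [v.species_name for v in vals]
        x = np.array([v.log10_value for v in vals], dtype=float)
    else:
        x = np.log10(np.asarray(vals, dtype=float))
        names = [f"species_{i+1}" for i in range(x.size)]
    if not np.all(np.isfinite(x)):
        raise ValueError("toxicity values must be positive and finite")
    return x, names


class LogLogisticSSD(BaseEstimator):
    """Log-logistic SSD estimator with scikit-learn conventions.

    Parameters
    ----------
    plotting_position : {"weibull", "hazen"}, default "weibull"
        Rank-to-probability convention.
    method : {"ls", "mle"}, default "ls"
        Least squares of the curve against the plotting positions
        (regression of the Y-vs-X curve), or maximum likelihood on the
        log10 values.
    asymptotes : {"fixed", "free"}, default "fixed"
        Pin the curve at 0/1 (a proper CDF) or estimate both plateaus
        (legacy curve-fitting behavior; least squares only).

    Attributes
    ----------
    alpha_, beta_ : float
        Location (log10 μg/L) and slope; ``beta_ > 0``.
    lower_, upper_ : float
        Curve asymptotes (0 and 1 unless ``asymptotes="free"``).
    rss_ : float
        Residual sum of squares against the plotting positions.
    converged_ : bool
    points_ : tuple of SSDPoint
        Ranked species with their assigned probabilities.
    """

    def __init__(
        self,
        plotting_position: str = "weibull",
        method: str = "ls",
        asymptotes: str = "fixed",
    ):
        self.plotting_position = plotting_position
        self.method = method
        self.asymptotes = asymptotes

    # ------------------------------------------------------------------ fit
    def fit(self, values: Iterable[SpeciesToxicity] | Sequence[float], y=None):
        if self.method not in ("ls", "mle"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.asymptotes not in ("fixed", "free"):
            raise ValueError(f"unknown asymptote mode {self.asymptotes!r}")
        if self.method == "mle" and self.asymptotes == "free":
            raise ValueError("free asymptotes are only available with method='ls'")

        x_raw, names = _as_log10(values)
        n = x_raw.size
        if n < 3:
            raise InsufficientDataError(f"need at least 3 species, got {n}")
        if np.ptp(x_raw) == 0:
            raise DegenerateDesignError("all toxicity values are identical")

        order = np.argsort(x_raw, kind="stable")
        x = x_raw[order]
        p = plotting_positions(n, self.plotting_position)
        self.points_ = tuple(
            SSDPoint(names[j], float(x[i]), float(p[i]), i + 1)
            for i, j in enumerate(order)
        )

        alpha0 = float(np.median(x))
        iqr = float(np.subtract(*np.percentile(x, [75, 25])))
        beta0 = max(iqr / math.log(9), 1e-3)

        if self.method == "mle":
            loc, scale = stats.logistic.fit(x, loc=alpha0, scale=beta0)
            self.alpha_, self.beta_ = float(loc), float(max(scale, 1e-6))
            self.lower_, self.upper_ = 0.0, 1.0
            self.converged_ = True
        elif self.asymptotes == "fixed":
            def resid(theta):
                a, b = theta
                return 1.0 / (1.0 + np.exp((a - x) / b)) - p

            sol = least_squares(
                resid,
                x0=[alpha0, beta0],
                bounds=([-np.inf, 1e-6], [np.inf, np.inf]),
            )
            self.alpha_, self.beta_ = map(float, sol.x)
            self.lower_, self.upper_ = 0.0, 1.0
            self.converged_ = bool(sol.success)
        else:
            def resid(theta):
                a, b, lo, hi = theta
                return lo + (hi - lo) / (1.0 + np.exp((a - x) / b)) - p

            sol = least_squares(
                resid,
                x0=[alpha0, beta0, 0.0, 1.0],
                bounds=([-np.inf, 1e-6, -np.inf, -np.inf], np.inf),
                max_nfev=20000,
            )
            self.alpha_, self.beta_, self.lower_, self.upper_ = map(float, sol.x)
            self.converged_ = bool(sol.success)

        fitted = self.lower_ + (self.upper_ - self.lower_) / (
            1.0 + np.exp((self.alpha_ - x) / self.beta_)
        )
        self.rss_ = float(np.sum((fitted - p) ** 2))
        self.n_species_ = n
        if not self.converged_:
            warnings.warn("SSD fit did not converge; parameters returned as-is")
        return self

    # ------------------------------------------------------- derived output
    def to_fit(self) -> SSDFit:
        return SSDFit(
            alpha=self.alpha_,
            beta=self.beta_,
            points=self.points_,
            rss=self.rss_,
            converged=self.converged_,
            lower=self.lower_,
            upper=self.upper_,
        )

    def hcp(self, p: float) -> HCEstimate:
        return hcp(self.to_fit(), p)


def fit_loglogistic(
    values: Iterable[SpeciesToxicity] | Sequence[float],
    plotting_position: str = "weibull",
    method: str = "ls",
    asymptotes: str = "fixed",
) -> SSDFit:
    """Fit the log-logistic SSD and return the parameter record."""
    est = LogLogisticSSD(
        plotting_position=plotting_position, method=method, asymptotes=asymptotes
    ).fit(values)
    return est.to_fit()


def hcp(fit: SSDFit, p: float) -> HCEstimate:
    """Invert the fitted curve at cumulative probability ``p``.

    For the 0/1-asymptote fit this is the closed form
    ``10**(alpha + beta*ln(p/(1-p)))``; with estimated asymptotes the same
    closed form applies to the rescaled odds ``(p - lower)/(upper - p)``,
    defined only for ``lower < p < upper``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if not fit.beta > 0:
        raise ValueError("fit must have beta > 0")
    if not fit.lower < p < fit.upper:
        raise ValueError(
            f"p={p} outside the fitted curve range ({fit.lower:.3f}, {fit.upper:.3f})"
        )
    x_p = fit.alpha + fit.beta * math.log((p - fit.lower) / (fit.upper - p))
    return HCEstimate(p=p, hc_ugL=float(10**x_p))


def bootstrap_hcp(
    values: Sequence[SpeciesToxicity] | Sequence[float],
    p: float = 0.05,
    n_boot: int = 1000,
    seed: int | None = None,
    plotting_position: str = "weibull",
    method: str = "ls",
    asymptotes: str = "fixed",
    max_retries: int = 100,
) -> HCEstimate:
    """Nonparametric bootstrap percentile CI for HC_p.

    Species are resampled with replacement, the SSD refit and re-inverted
    per replicate; the 2.5/97.5 percentiles of the replicate HC_p values
    form the 95 % interval.  Replicates with fewer than three distinct
    values (or with ``p`` outside the refitted curve range) are redrawn up
    to ``max_retries`` times, then skipped with a warning.  Deterministic
    for a given ``seed``.
    """
    values = list(values)
    if len(values) < 3:
        raise InsufficientDataError("need at least 3 species to bootstrap")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    kw = dict(plotting_position=plotting_position, method=method, asymptotes=asymptotes)
    point = hcp(fit_loglogistic(values, **kw), p)
    rng = np.random.default_rng(seed)
    n = len(values)
    replicates: list[float] = []
    skipped = 0
    for _ in range(n_boot):
        est = None
        for _try in range(max_retries):
            idx = rng.integers(0, n, size=n)
            sample = [values[i] for i in idx]
            x, _ = _as_log10(sample)
            if np.unique(x).size < 3:
                continue
            try:
                est = hcp(fit_loglogistic(sample, **kw), p)
            except (ValueError, DegenerateDesignError):
                continue
            break
        if est is None:
            skipped += 1
            continue
        replicates.append(est.hc_ugL)
    if skipped:
        warnings.warn(f"{skipped} bootstrap replicates skipped after retries")
    lo, hi = np.percentile(replicates, [2.5, 97.5])
    lo = min(float(lo), point.hc_ugL)
    hi = max(float(hi), point.hc_ugL)
    return HCEstimate(
        p=p, hc_ugL=point.hc_ugL, ci_low_ugL=lo, ci_high_ugL=hi,
        n_boot=len(replicates),
    )
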