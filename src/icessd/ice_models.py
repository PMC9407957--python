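"""Interspecies correlation estimation (ICE).

An ICE model is an ordinary least-squares regression of the log10 acute
toxicity of a *predicted* species on the log10 acute toxicity of a
*surrogate* species, trained across chemicals.  Seeding a fitted model with
a measured surrogate value extrapolates toxicity to the untested species.

Model adoption follows the six-criterion screen used for regulatory ICE
work: mean squared error, taxonomic distance between surrogate and
predicted species, leave-one-out cross-validation success rate, residual
degrees of freedom, R², and the p-value of the slope.  Published diagnostic
tables usually omit df and p; the filter therefore supports an
``allow_unknown`` policy that passes such rows with a warning instead of
inventing numbers.

The estimator :class:`ICERegressor` follows scikit-learn conventions
(``fit``/``predict``, fitted attributes with trailing underscores) so it
composes with sklearn tooling; :func:`fit_ice_model` is the thin functional
wrapper producing the :class:`ICEModel` record.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .core_data import (
    Taxonomy,
    ToxicityRecord,
    load_table1,
    load_toxicity_table,
    normalize_name,
    table2_path,
)
from .exceptions import (
    DegenerateDesignError,
    IncompleteTaxonomyError,
    InsufficientDataError,
)

__all__ = [
    "ICEModel",
    "FilterCriteria",
    "ICERegressor",
    "taxonomic_distance",
    "fit_ice_model",
    "loo_cross_validation",
    "predict_toxicity",
    "filter_models",
    "load_published_models",
]

#: rank ladder and the distance attached to sharing that rank
_RANK_LADDER = (("genus", 1), ("family", 2), ("order", 3), ("class", 4), ("phylum", 5))
_KINGDOM_DISTANCE = 6


def taxonomic_distance(a: Taxonomy, b: Taxonomy) -> int:
    """Steps up the rank ladder to the lowest rank shared by two species.

    0 = same species, 1 = same genus, 2 = same family, 3 = same order,
    4 = same class, 5 = same phylum, 6 = related only at kingdom level.
    Symmetric by construction.  A rank that is empty on either side before
    a shared rank is found makes the distance undecidable and raises
    :class:`IncompleteTaxonomyError`.
    """
    if normalize_name(a.species) and normalize_name(a.species) == normalize_name(b.species):
        return 0
    for rank, dist in _RANK_LADDER:
        ra, rb = a.rank(rank), b.rank(rank)
        if not ra.strip() or not rb.strip():
            raise IncompleteTaxonomyError(
                f"rank {rank!r} missing for {a.species!r} or {b.species!r}"
            )
        if normalize_name(ra) == normalize_name(rb):
            return dist
    return _KINGDOM_DISTANCE


@dataclass(frozen=True)
class ICEModel:
    """A surrogate→predicted log–log regression with its diagnostics.

    ``df`` and ``p_value`` may be ``None`` for models taken from published
    tables that do not print them.
    """

    surrogate: Taxonomy
    predicted: Taxonomy
    intercept: float
    slope: float
    mse: float
    r2: float
    df: int | None
    p_value: float | None
    cv_success_pct: float
    taxonomic_distance: int
    n_chemicals: int | None = None


@dataclass(frozen=True)
class FilterCriteria:
    """Adoption thresholds for ICE predictions.

    Defaults are the regulatory screen: MSE < 0.22, taxonomic distance ≤ 4,
    cross-validation success > 85 %, df > 8, R² > 0.6, slope p < 0.01.
    With ``inclusive=True`` (default) the comparisons are non-strict at the
    printed precision, which is the reading consistent with published
    adopted sets that contain boundary rows (e.g. MSE exactly 0.22).
    """

    max_mse: float = 0.22
    max_taxonomic_distance: int = 4
    min_cv_success_pct: float = 85.0
    min_df: int = 8
    min_r2: float = 0.6
    max_p: float = 0.01
    inclusive: bool = True

    def strict(self) -> "FilterCriteria":
        return replace(self, inclusive=False)


def _as_pairs(pairs: Iterable[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (surrogate, predicted) tuples")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs must be finite")
    return arr[:, 0], arr[:, 1]


class ICERegressor(RegressorMixin, BaseEstimator):
    """OLS regression of predicted log10 toxicity on surrogate log10 toxicity.

    Parameters
    ----------
    fold : float, default 5
        Leave-one-out predictions within this factor of the observed value
        (|Δ log10| ≤ log10(fold)) count as cross-validation successes.

    Attributes
    ----------
    slope_, intercept_ : float
        OLS coefficients in log10 space.
    mse_ : float
        Residual sum of squares / (n − 2).
    r2_ : float
        Squared Pearson correlation.
    df_ : int
        n − 2.
    p_value_ : float
        Two-sided t-test of slope = 0 with ``df_`` degrees of freedom.
    cv_success_pct_ : float
        Leave-one-out success rate (percent).
    """

    def __init__(self, fold: float = 5.0):
        self.fold = fold

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("ICERegressor expects a single surrogate feature")
        y = np.asarray(y, dtype=float)
        x = X[:, 0]
        if x.shape != y.shape:
            raise ValueError("X and y lengths differ")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("inputs must be finite")
        n = x.size
        if n < 3:
            raise InsufficientDataError(f"need at least 3 pairs, got {n}")
        if np.ptp(x) == 0:
            raise DegenerateDesignError("surrogate values have zero variance")

        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r2_ = float(res.rvalue**2)
        self.p_value_ = float(res.pvalue)
        self.df_ = n - 2
        resid = y - (self.intercept_ + self.slope_ * x)
        self.mse_ = float(resid @ resid / self.df_)
        self.n_chemicals_ = n
        self.n_features_in_ = 1
        if n >= 4:
            self.cv_success_pct_ = loo_cross_validation(
                np.column_stack([x, y]), fold=self.fold
            )
        else:
            self.cv_success_pct_ = float("nan")
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + self.slope_ * X[:, 0]

    def predict_concentration(self, surrogate_value_ugL: float) -> float:
        """Extrapolate a concentration (μg/L) from a surrogate seed value."""
        if not (surrogate_value_ugL > 0 and math.isfinite(surrogate_value_ugL)):
            raise ValueError("surrogate value must be positive and finite")
        return float(10 ** (self.intercept_ + self.slope_ * math.log10(surrogate_value_ugL)))

    def to_model(self, surrogate: Taxonomy, predicted: Taxonomy) -> ICEModel:
        return ICEModel(
            surrogate=surrogate,
            predicted=predicted,
            intercept=self.intercept_,
            slope=self.slope_,
            mse=self.mse_,
            r2=self.r2_,
            df=self.df_,
            p_value=self.p_value_,
            cv_success_pct=self.cv_success_pct_,
            taxonomic_distance=taxonomic_distance(surrogate, predicted),
            n_chemicals=self.n_chemicals_,
        )


def fit_ice_model(
    pairs: Iterable[tuple[float, float]],
    surrogate: Taxonomy,
    predicted: Taxonomy,
    fold: float = 5.0,
) -> ICEModel:
    """Fit a surrogate→predicted log–log OLS model with full diagnostics."""
    x, y = _as_pairs(pairs)
    reg = ICERegressor(fold=fold).fit(x, y)
    return reg.to_model(surrogate, predicted)


def loo_cross_validation(
    pairs: Iterable[tuple[float, float]], fold: float = 5.0
) -> float:
    """Leave-one-out cross-validation success rate, in percent.

    Each point is held out in turn, the line refit on the rest, and the
    held-out response predicted; a prediction within ``fold``-fold of the
    observation (|Δ log10| ≤ log10(fold), boundary inclusive) is a success.
    """
    x, y = _as_pairs(pairs)
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"need at least 4 pairs for LOO-CV, got {n}")
    threshold = math.log10(fold)
    successes = 0
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        xi, yi = x[keep], y[keep]
        if np.ptp(xi) == 0:
            raise DegenerateDesignError(
                "surrogate values have zero variance after leaving one out"
            )
        slope, intercept = np.polyfit(xi, yi, 1)
        if abs(intercept + slope * x[i] - y[i]) <= threshold + 1e-12:
            successes += 1
    return 100.0 * successes / n


def predict_toxicity(model: ICEModel, surrogate_value_ugL: float) -> float:
    """Seed a fitted ICE model with a surrogate concentration (μg/L)."""
    if not (surrogate_value_ugL > 0 and math.isfinite(surrogate_value_ugL)):
        raise ValueError("surrogate value must be positive and finite")
    return float(
        10 ** (model.intercept + model.slope * math.log10(surrogate_value_ugL))
    )


def _violations(m: ICEModel, c: FilterCriteria, allow_unknown: bool) -> list[str]:
    le = (lambda v, t: v <= t) if c.inclusive else (lambda v, t: v < t)
    ge = (lambda v, t: v >= t) if c.inclusive else (lambda v, t: v > t)
    reasons = []
    if not le(m.mse, c.max_mse):
        reasons.append("mse")
    if not m.taxonomic_distance <= c.max_taxonomic_distance:
        reasons.append("taxonomic_distance")
    if not ge(m.cv_success_pct, c.min_cv_success_pct):
        reasons.append("cv_success_pct")
    for attr, thr, kind in (("df", c.min_df, ge), ("p_value", c.max_p, le)):
        value = getattr(m, attr)
        if value is None:
            if allow_unknown:
                warnings.warn(
                    f"{m.predicted.species}: {attr} unknown, passed by policy",
                    stacklevel=3,
                )
            else:
                reasons.append(attr)
        elif attr == "df" and not kind(value, thr):
            reasons.append("df")
        elif attr == "p_value" and not kind(value, thr):
            reasons.append("p_value")
    if not ge(m.r2, c.min_r2):
        reasons.append("r2")
    return reasons


def filter_models(
    models: Sequence[ICEModel],
    criteria: FilterCriteria | None = None,
    allow_unknown: bool = True,
) -> tuple[list[ICEModel], list[tuple[ICEModel, list[str]]]]:
    """Partition ICE models into adopted and rejected sets.

    Returns ``(accepted, rejected)`` where each rejected entry carries the
    names of the violated criteria.  ``allow_unknown=True`` passes models
    whose ``df``/``p_value`` diagnostics are unavailable (with a warning),
    matching how published adopted sets treat table rows that omit them.
    """
    criteria = criteria or FilterCriteria()
    accepted: list[ICEModel] = []
    rejected: list[tuple[ICEModel, list[str]]] = []
    for m in models:
        reasons = _violations(m, criteria, allow_unknown)
        if reasons:
            rejected.append((m, reasons))
        else:
            accepted.append(m)
    return accepted, rejected


def load_published_models(
    path=None, unit: str = "ugL"
) -> list[tuple[ICEModel, ToxicityRecord]]:
    """Read a diagnostics table of externally fitted ICE predictions.

    Expects the bundled predicted-toxicity CSV layout: the toxicity-record
    columns plus ``surrogate``, ``cv_success_pct``, ``mse``, ``r2`` and
    ``taxonomic_distance``.  Regression coefficients, df and p are not part
    of such tables, so the returned models carry ``nan`` coefficients and
    ``None`` for df/p (handled by the ``allow_unknown`` filter policy).

    Returns one ``(model, record)`` pair per row, in row order; the record
    holds the predicted concentration in μg/L.
    """
    path = table2_path() if path is None else path
    records = load_toxicity_table(path, unit=unit)
    diag = pd.read_csv(path)
    surrogates = {normalize_name(r.species_name): r.taxonomy for r in load_table1()}
    out: list[tuple[ICEModel, ToxicityRecord]] = []
    for rec, row in zip(records, diag.itertuples(index=False)):
        name = str(row.surrogate).strip()
        surrogate = surrogates.get(normalize_name(name), Taxonomy(species=name))
        model = ICEModel(
            surrogate=surrogate,
            predicted=rec.taxonomy,
            intercept=float("nan"),
            slope=float("nan"),
            mse=float(row.mse),
            r2=float(row.r2),
            df=None,
            p_value=None,
            cv_success_pct=float(row.cv_success_pct),
            taxonomic_distance=int(row.taxonomic_distance),
        )
        out.append((model, rec))
    return out
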