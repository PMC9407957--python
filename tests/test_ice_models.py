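import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icessd.core_data import Taxonomy
from icessd.exceptions import (
    DegenerateDesignError,
    IncompleteTaxonomyError,
    InsufficientDataError,
)
from icessd.ice_models import (
    FilterCriteria,
    ICEModel,
    ICERegressor,
    filter_models,
    fit_ice_model,
    load_published_models,
    loo_cross_validation,
    predict_toxicity,
    taxonomic_distance,
)
from icessd.synthetic_data import InterspeciesScenario, generate_interspecies_pairs


def tax(species, genus="G", family="F", order="O", class_="C", phylum="P"):
    return Taxonomy(species=species, genus=genus, family=family, order=order,
                    class_=class_, phylum=phylum)


D_MAGNA = tax("Daphnia magna", genus="Daphnia", family="Daphniidae",
              order="Anomopoda", class_="Branchiopoda", phylum="Arthropoda")
D_PULEX = tax("Daphnia pulex", genus="Daphnia", family="Daphniidae",
              order="Anomopoda", class_="Branchiopoda", phylum="Arthropoda")
T_PLATYURUS = tax("Thamnocephalus platyurus", genus="Thamnocephalus",
                  family="Thamnocephalidae", order="Anostraca",
                  class_="Branchiopoda", phylum="Arthropoda")


class TestTaxonomicDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (D_MAGNA, D_MAGNA, 0),
            (D_MAGNA, D_PULEX, 1),  # same genus
            (D_MAGNA, T_PLATYURUS, 4),  # shared only at class Branchiopoda
            (tax("A", genus="Ga", family="X"), tax("B", genus="Gb", family="X"), 2),
            (tax("A", genus="Ga", order="X", family="F1"),
             tax("B", genus="Gb", order="X", family="F2"), 3),
            (tax("A", phylum="X", genus="a", family="b", order="c", class_="d"),
             tax("B", phylum="X", genus="e", family="f", order="g", class_="h"), 5),
            (tax("A", genus="a", family="b", order="c", class_="d", phylum="e"),
             tax("B", genus="v", family="w", order="x", class_="y", phylum="z"), 6),
        ],
    )
    def test_ladder(self, a, b, expected):
        assert taxonomic_distance(a, b) == expected
        assert taxonomic_distance(b, a) == expected  # symmetric

    def test_never_exceeds_kingdom(self):
        ranks = ["g", "f", "o", "c", "p"]
        for flips in itertools.product([0, 1], repeat=5):
            b = tax("B", *[r if keep else r.upper() + "x"
                           for r, keep in zip(ranks, flips)])
            a = tax("A", *ranks)
            assert 0 <= taxonomic_distance(a, b) <= 6

    def test_missing_rank_is_an_error(self):
        incomplete = Taxonomy(species="A", genus="", family="F")
        with pytest.raises(IncompleteTaxonomyError, match="genus"):
            taxonomic_distance(incomplete, D_MAGNA)


def ols_oracle(pairs):
    """Closed-form simple OLS via explicit sums (independent route)."""
    x = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


class TestFitIceModel:
    def test_noiseless_line(self):
        pairs = [(x, 1.0 + 2.0 * x) for x in np.linspace(0, 5, 10)]
        model = fit_ice_model(pairs, D_MAGNA, D_PULEX)
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(1.0)
        assert model.mse == pytest.approx(0.0, abs=1e-20)
        assert model.r2 == pytest.approx(1.0)
        assert model.cv_success_pct == 100.0
        assert model.df == 8
        assert model.taxonomic_distance == 1

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(3, 10), st.integers(0, 10_000))
    def test_matches_closed_form_ols(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 5, size=n)
        if np.ptp(x) == 0:
            return
        y = rng.normal(size=n)
        pairs = list(zip(x, y))
        model = fit_ice_model(pairs, D_MAGNA, D_PULEX)
        slope, intercept = ols_oracle(pairs)
        assert model.slope == pytest.approx(slope, rel=1e-9)
        assert model.intercept == pytest.approx(intercept, rel=1e-9, abs=1e-9)

    def test_slope_recovery_under_noise(self):
        hits = 0
        for seed in range(40):
            pairs = generate_interspecies_pairs(
                InterspeciesScenario(n_chemicals=30, slope=0.9, intercept=0.5,
                                     noise_sd=0.2, seed=seed)
            )
            model = fit_ice_model(pairs, D_MAGNA, D_PULEX)
            hits += abs(model.slope - 0.9) <= 0.15 and model.r2 > 0.6
        assert hits >= 36  # 90% of replicates

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            fit_ice_model([(0, 0), (1, 1)], D_MAGNA, D_PULEX)

    def test_degenerate_design(self):
        with pytest.raises(DegenerateDesignError):
            fit_ice_model([(1, 0), (1, 1), (1, 2)], D_MAGNA, D_PULEX)

    def test_sklearn_estimator_contract(self):
        reg = ICERegressor(fold=5)
        assert reg.get_params() == {"fold": 5}
        x = np.linspace(0, 3, 6)
        reg.fit(x, 2 * x)
        assert reg.predict([[1.0]]) == pytest.approx([2.0])
        reg.set_params(fold=2)
        assert reg.fold == 2


class TestLooCrossValidation:
    def test_noiseless_line_is_100(self):
        pairs = [(x, 3 - 0.5 * x) for x in np.linspace(0, 4, 8)]
        assert loo_cross_validation(pairs) == 100.0

    def test_single_gross_outlier_gives_90(self):
        # 9 points on y = x, one mid-design point 2 log10 units off the
        # line: its LOO prediction misses by far more than log10(5) = 0.699
        # while, at low leverage, every other point's prediction barely moves
        pairs = [(float(x), float(x)) for x in range(10) if x != 4] + [(4.0, 6.0)]
        result = loo_cross_validation(pairs, fold=5)
        # independent enumeration of the same rule
        expected = 0
        for i in range(10):
            rest = [p for j, p in enumerate(pairs) if j != i]
            sx = sum(p[0] for p in rest); sy = sum(p[1] for p in rest)
            sxx = sum(p[0] ** 2 for p in rest)
            sxy = sum(p[0] * p[1] for p in rest)
            n = len(rest)
            slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
            inter = (sy - slope * sx) / n
            expected += abs(inter + slope * pairs[i][0] - pairs[i][1]) <= math.log10(5)
        assert result == pytest.approx(10.0 * expected)
        assert result == 90.0

    def test_boundary_residual_counts_as_success(self):
        # fold=1 makes the threshold 0: exact predictions still succeed
        pairs = [(0.0, 0.0), (1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]
        assert loo_cross_validation(pairs, fold=1) == 100.0

    def test_order_invariance_and_granularity(self):
        rng = np.random.default_rng(5)
        pairs = [(float(x), float(x + rng.normal(0, 0.5))) for x in range(8)]
        a = loo_cross_validation(pairs)
        b = loo_cross_validation(pairs[::-1])
        assert a == b
        assert (a * 8 / 100) == pytest.approx(round(a * 8 / 100))

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            loo_cross_validation([(0, 0), (1, 1), (2, 2)])


def _model(**overrides):
    defaults = dict(
        surrogate=D_MAGNA, predicted=D_PULEX, intercept=0.0, slope=1.0,
        mse=0.1, r2=0.9, df=20, p_value=1e-4, cv_success_pct=95.0,
        taxonomic_distance=1,
    )
    defaults.update(overrides)
    return ICEModel(**defaults)


class TestPredictToxicity:
    def test_identity_model(self):
        assert predict_toxicity(_model(slope=1.0, intercept=0.0), 770.0) == pytest.approx(770.0)

    def test_hand_computed(self):
        # 1 + 2*log10(100) = 5 -> 1e5
        assert predict_toxicity(_model(slope=2.0, intercept=1.0), 100.0) == pytest.approx(1e5)

    def test_constant_model(self):
        m = _model(slope=0.0, intercept=3.0)
        for v in (1.0, 770.0, 1e6):
            assert predict_toxicity(m, v) == pytest.approx(1000.0)

    def test_monotone_when_slope_positive(self):
        m = _model(slope=0.7, intercept=0.2)
        values = [predict_toxicity(m, v) for v in (1, 10, 100, 1e4)]
        assert values == sorted(values)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            predict_toxicity(_model(), -1.0)


class TestFilterModels:
    def test_bundled_table_all_adopted_inclusive(self, table2_pairs):
        models = [m for m, _ in table2_pairs]
        with pytest.warns(UserWarning, match="passed by policy"):
            accepted, rejected = filter_models(models, FilterCriteria())
        assert len(accepted) == 19
        assert rejected == []

    def test_strict_mode_rejects_boundary_mse(self, table2_pairs):
        models = [m for m, _ in table2_pairs]
        with pytest.warns(UserWarning):
            accepted, rejected = filter_models(models, FilterCriteria().strict())
        assert len(accepted) == 18
        assert [(m.predicted.species, reasons) for m, reasons in rejected] == [
            ("Pimephales promelas", ["mse"])
        ]

    def test_mse_violation_reason(self):
        accepted, rejected = filter_models([_model(mse=0.30)])
        assert accepted == []
        assert rejected[0][1] == ["mse"]

    def test_empty_input(self):
        assert filter_models([]) == ([], [])

    def test_unknown_df_p_policy(self):
        m = _model(df=None, p_value=None)
        with pytest.warns(UserWarning, match="passed by policy"):
            accepted, _ = filter_models([m], allow_unknown=True)
        assert accepted == [m]
        accepted, rejected = filter_models([m], allow_unknown=False)
        assert accepted == []
        assert set(rejected[0][1]) == {"df", "p_value"}

    def test_partition_and_recheck(self):
        models = [
            _model(),
            _model(mse=0.5),
            _model(r2=0.2),
            _model(cv_success_pct=50.0),
            _model(taxonomic_distance=6),
            _model(df=3),
            _model(p_value=0.5),
        ]
        accepted, rejected = filter_models(models)
        assert len(accepted) + len(rejected) == len(models)
        c = FilterCriteria()
        for m in accepted:
            assert m.mse <= c.max_mse and m.r2 >= c.min_r2
            assert m.cv_success_pct >= c.min_cv_success_pct
            assert m.taxonomic_distance <= c.max_taxonomic_distance
            assert m.df >= c.min_df and m.p_value <= c.max_p
        assert len(accepted) == 1


def test_load_published_models_pairs_diagnostics_with_records():
    pairs = load_published_models()
    assert len(pairs) == 19
    model, record = next(
        (m, r) for m, r in pairs if m.predicted.species == "Pimephales promelas"
    )
    assert model.mse == pytest.approx(0.22)
    assert model.r2 == pytest.approx(0.85)
    assert model.cv_success_pct == 97
    assert model.taxonomic_distance == 4
    assert model.surrogate.species == "Hyalella azteca"
    assert record.concentration == pytest.approx(3457.14)
    assert model.df is None and model.p_value is None
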