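import numpy as np
import pytest

from genoenc import (
    fit_hybrid_one,
    fit_hybrid_two,
    fit_ordinal,
    fit_ordinal_flipped,
    fit_target_based,
    ridge_solve,
    transform,
)
from genoenc.core import MISSING, GenotypeMatrix, ValidationError
from genoenc.encodings import TransformError, marker_trait_correlations

from conftest import make_genotypes, make_traits


class TestOrdinal:
    def test_zero_one_two_base(self):
        G = make_genotypes([[0, 1, 2], [2, 2, 0]])
        model = fit_ordinal(G, "zero_one_two")
        assert np.array_equal(model.table, [[0, 1, 2], [0, 1, 2]])

    def test_minus_one_zero_one_base(self):
        G = make_genotypes([[0, 1, 2]])
        model = fit_ordinal(G, "minus_one_zero_one")
        assert np.array_equal(model.table, [[-1, 0, 1]])

    def test_same_map_for_all_markers(self):
        G = make_genotypes([[0, 1, 2], [1, 1, 0], [2, 0, 0]])
        model = fit_ordinal(G)
        assert (model.table == model.table[0]).all()

    def test_requires_oriented(self):
        G = make_genotypes([[0, 1, 2]], oriented=False)
        with pytest.raises(ValidationError, match="oriented"):
            fit_ordinal(G)


class TestOrdinalFlipped:
    def test_negative_correlation_flips(self):
        G = make_genotypes([[0, 0, 1, 2, 2]])
        y = make_traits([10, 9, 5, 2, 1])
        model = fit_ordinal_flipped(G, y)
        assert list(model.table[0]) == [2, 1, 0]

    def test_positive_correlation_keeps(self):
        G = make_genotypes([[0, 1, 2]])
        y = make_traits([1, 2, 3])
        assert list(fit_ordinal_flipped(G, y).table[0]) == [0, 1, 2]

    def test_monomorphic_marker_not_flipped(self):
        G = make_genotypes([[1, 1, 1]])
        y = make_traits([3, 2, 1])
        assert list(fit_ordinal_flipped(G, y).table[0]) == [0, 1, 2]

    def test_zero_variance_correlation_is_zero(self):
        G = make_genotypes([[1, 1, 1], [0, 1, 2]])
        y = make_traits([1.0, 2.0, 3.0])
        r = marker_trait_correlations(G, y)
        assert r[0] == 0.0
        assert r[1] == pytest.approx(1.0)


class TestTraitAwareFits:
    def test_toy_maps(self, toy6):
        G, y = toy6
        assert np.allclose(fit_target_based(G, y).table[0], [1.5, 4.0, 9.0])
        assert np.allclose(fit_hybrid_one(G, y).table[0], [1.5, 29 / 6, 9.0])
        assert np.allclose(fit_hybrid_two(G, y).table[0], [1.5, 5.25, 9.0])

    def test_homozygote_encodings_agree_across_methods(self, toy6):
        G, y = toy6
        tables = [
            f(G, y).table for f in (fit_target_based, fit_hybrid_one, fit_hybrid_two)
        ]
        for t in tables[1:]:
            assert np.array_equal(t[:, [0, 2]], tables[0][:, [0, 2]])

    def test_constant_trait_collapses(self):
        G = make_genotypes([[0, 1, 2, 1]])
        y = make_traits([4.0, 4.0, 4.0, 4.0])
        for f in (fit_target_based, fit_hybrid_one, fit_hybrid_two):
            assert np.allclose(f(G, y).table, 4.0)

    def test_absent_category_falls_back_to_overall_mean(self):
        G = make_genotypes([[0, 0, 1, 1]])
        y = make_traits([1, 2, 3, 5])
        with pytest.warns(UserWarning, match="absent"):
            model = fit_target_based(G, y)
        assert np.allclose(model.table[0], [1.5, 4.0, 2.75])

    def test_hybrid_two_midpoint_after_fallback(self):
        # no category-2 samples: E2 falls back to the overall mean first,
        # then the heterozygote is the exact midpoint
        G = make_genotypes([[0, 0, 1, 1]])
        y = make_traits([1, 2, 3, 5])
        with pytest.warns(UserWarning):
            model = fit_hybrid_two(G, y)
        e0, e1, e2 = model.table[0]
        assert (e0, e2) == (1.5, 2.75)
        assert e1 == (e0 + e2) / 2

    def test_fit_ignores_samples_outside_training_set(self, toy6):
        # leakage guard: the fit sees only what it is given
        G, y = toy6
        ref = fit_hybrid_two(G, y).table
        G2 = make_genotypes([[0, 0, 1, 1, 2, 2, 2, 2]])
        y2 = make_traits([1, 2, 3, 5, 8, 10, 99, -99])
        train = np.arange(6)
        again = fit_hybrid_two(G2.take_samples(train), y2.take(train)).table
        assert np.array_equal(ref, again)

    @pytest.mark.parametrize("seed", range(5))
    def test_order_maintenance_on_random_markers(self, seed):
        rng = np.random.default_rng(seed)
        cols = rng.integers(0, 3, size=(40, 30))
        G = make_genotypes(cols.T.tolist())
        y = make_traits(cols[:, :5].sum(axis=1) + 0.3 * rng.normal(size=40))
        t2 = fit_hybrid_two(G, y).table
        lo = np.minimum(t2[:, 0], t2[:, 2])
        hi = np.maximum(t2[:, 0], t2[:, 2])
        assert ((lo <= t2[:, 1]) & (t2[:, 1] <= hi)).all()
        assert np.array_equal(t2[:, 1], (t2[:, 0] + t2[:, 2]) / 2)


class TestTransform:
    def test_lookup(self, toy6):
        G, y = toy6
        model = fit_hybrid_two(G, y)
        Gnew = make_genotypes([[2, 1, 0]])
        assert np.allclose(transform(model, Gnew)[:, 0], [9.0, 5.25, 1.5])

    def test_ordinal_transform_is_identity_coding(self):
        G = make_genotypes([[0, 2, 1], [1, 0, 2]])
        X = transform(fit_ordinal(G), G)
        assert np.array_equal(X, G.values)

    def test_missing_imputed_with_training_column_mean(self, toy6):
        G, y = toy6
        model = fit_hybrid_two(G, y)
        # training encoded column: [1.5,1.5,5.25,5.25,9,9] -> mean 5.25
        Gm = GenotypeMatrix(("x",), ("m0",), np.array([[MISSING]], dtype=np.int8),
                            oriented=True)
        assert transform(model, Gm)[0, 0] == pytest.approx(5.25)

    def test_unknown_marker_errors(self, toy6):
        G, y = toy6
        model = fit_hybrid_two(G, y)
        Gnew = make_genotypes([[0, 1]], marker_prefix="other")
        with pytest.raises(TransformError, match="other0"):
            transform(model, Gnew)

    def test_transform_depends_only_on_categories(self, toy6):
        G, y = toy6
        model = fit_hybrid_one(G, y)
        Gnew = make_genotypes([[1, 0, 2, 1]], sample_prefix="q")
        X1 = transform(model, Gnew)
        X2 = transform(model, Gnew)
        assert np.array_equal(X1, X2)


def test_ols_fitted_values_invariant_to_column_shifts():
    """Unpenalized least squares with an intercept gives identical fitted
    values when every feature is shifted by a per-marker constant: the
    shift is absorbed into the intercept and the error term alone."""
    rng = np.random.default_rng(0)
    X = rng.integers(0, 3, size=(40, 8)).astype(float)
    y = rng.normal(size=40)
    b0, b = ridge_solve(X, y, 0.0)
    shifts = rng.normal(size=8) * 10
    b0s, bs = ridge_solve(X + shifts, y, 0.0)
    fit1 = b0 + X @ b
    fit2 = b0s + (X + shifts) @ bs
    assert np.max(np.abs(fit1 - fit2)) < 1e-8
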