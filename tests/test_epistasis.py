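import numpy as np
import pytest

from genoenc import (
    PairSelection,
    TraitVector,
    fit_pair_grid_hybrid_one,
    fit_pair_grid_hybrid_two,
    product_features,
    select_pairs,
    transform_pairs,
)
from genoenc.core import MISSING, GenotypeMatrix, ValidationError

from conftest import make_genotypes, make_traits

TOY_H1_GRID = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])


class TestSelectPairs:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.X = rng.normal(size=(30, 4))
        self.X[:, 2] = np.arange(30)  # strongly correlated column
        self.ids = ["m0", "m1", "m2", "m3"]
        self.y = make_traits(np.arange(30) + rng.normal(scale=0.1, size=30))

    def test_all_pairs_count(self):
        pairs = select_pairs(self.X, self.y, PairSelection("all_pairs"), self.ids)
        assert len(pairs) == 6

    def test_top_t_two_markers_one_pair(self):
        pairs = select_pairs(
            self.X, self.y, PairSelection("top_t_by_correlation", t=2), self.ids
        )
        assert len(pairs) == 1
        assert "m2" in pairs[0]

    def test_self_pair_rejected(self):
        sel = PairSelection("explicit_list", pairs=(("m1", "m1"),))
        with pytest.raises(ValidationError, match="self-pair"):
            select_pairs(self.X, self.y, sel, self.ids)

    def test_explicit_pairs_deduplicated_and_ordered(self):
        sel = PairSelection(
            "explicit_list", pairs=(("m3", "m0"), ("m0", "m3"), ("m1", "m2"))
        )
        pairs = select_pairs(self.X, self.y, sel, self.ids)
        assert pairs == (("m0", "m3"), ("m1", "m2"))

    def test_t_above_marker_count_errors(self):
        sel = PairSelection("top_t_by_correlation", t=9)
        with pytest.raises(ValidationError):
            select_pairs(self.X, self.y, sel, self.ids)

    def test_all_pairs_cap(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 5))
        sel = PairSelection("all_pairs", all_pairs_cap=4)
        with pytest.raises(ValidationError, match="cap"):
            select_pairs(X, self.y.take(np.arange(10)), sel, [f"m{j}" for j in range(5)])


class TestProductFeatures:
    def test_elementwise_product(self):
        X = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        out = product_features(X, [("m0", "m1")], ["m0", "m1"])
        assert np.array_equal(out[:, 0], [0.0, 1.0, 0.0])

    def test_all_ones_column_is_identity(self):
        X = np.column_stack([np.arange(4.0), np.ones(4)])
        out = product_features(X, [("m0", "m1")], ["m0", "m1"])
        assert np.array_equal(out[:, 0], X[:, 0])

    def test_zero_category_annihilates(self):
        X = np.array([[0.0, 2.0], [2.0, 0.0]])
        out = product_features(X, [("m0", "m1")], ["m0", "m1"])
        assert np.array_equal(out[:, 0], [0.0, 0.0])


class TestPairGrids:
    def test_hybrid_one_toy(self, toy9):
        G, y = toy9
        model = fit_pair_grid_hybrid_one(G, y, [("m0", "m1")])
        assert np.allclose(model.grids[0], TOY_H1_GRID)

    def test_hybrid_two_toy_agrees_on_additive_cells(self, toy9):
        # cell means are additive in rows/columns, so corner averages
        # reproduce the pooled marginals exactly
        G, y = toy9
        model = fit_pair_grid_hybrid_two(G, y, [("m0", "m1")])
        assert np.allclose(model.grids[0], TOY_H1_GRID)

    def test_hybrid_two_center_from_corners(self):
        # corners 0,0,4,4 -> edges 2,0,4,2... center 2
        cats = [(a, b) for a in (0, 2) for b in (0, 2)]
        G = make_genotypes([[a for a, _ in cats], [b for _, b in cats]])
        y = make_traits([0.0, 0.0, 4.0, 4.0])
        model = fit_pair_grid_hybrid_two(G, y, [("m0", "m1")])
        assert model.grids[0][1, 1] == pytest.approx(2.0)

    def test_constant_trait_collapses(self, toy9):
        G, _ = toy9
        y = make_traits([7.0] * 9)
        for fit in (fit_pair_grid_hybrid_one, fit_pair_grid_hybrid_two):
            assert np.allclose(fit(G, y, [("m0", "m1")]).grids, 7.0)

    def test_empty_corner_falls_back_to_overall_mean(self, toy9):
        G, y = toy9
        keep = np.arange(8)  # drop the (2,2) sample
        model = fit_pair_grid_hybrid_one(G.take_samples(keep), y.take(keep),
                                         [("m0", "m1")])
        assert model.grids[0][2, 2] == pytest.approx(np.mean(y.values[:8]))

    def test_reversed_pair_gives_same_canonical_model(self, toy9):
        G, y = toy9
        m1 = fit_pair_grid_hybrid_one(G, y, [("m0", "m1")])
        m2 = fit_pair_grid_hybrid_one(G, y, [("m1", "m0")])
        assert m1.pairs == m2.pairs
        assert np.array_equal(m1.grids, m2.grids)
        assert np.array_equal(transform_pairs(m1, G), transform_pairs(m2, G))

    @pytest.mark.parametrize("seed", range(4))
    def test_hybrid_two_order_property(self, seed):
        """Each edge lies between its adjacent corners and the center lies
        within the edge range, for random training data."""
        rng = np.random.default_rng(seed)
        cols = rng.integers(0, 3, size=(60, 10))
        G = make_genotypes(cols.T.tolist())
        y = make_traits(rng.normal(size=60))
        pairs = [(f"m{i}", f"m{j}") for i in range(5) for j in range(5, 10)]
        model = fit_pair_grid_hybrid_two(G, y, pairs)
        for g in model.grids:
            for (e, c1, c2) in [
                ((1, 0), (0, 0), (2, 0)), ((1, 2), (0, 2), (2, 2)),
                ((0, 1), (0, 0), (0, 2)), ((2, 1), (2, 0), (2, 2)),
            ]:
                lo, hi = sorted((g[c1], g[c2]))
                assert lo <= g[e] <= hi
            edges = [g[1, 0], g[1, 2], g[0, 1], g[2, 1]]
            assert min(edges) <= g[1, 1] <= max(edges)


class TestTransformPairs:
    def test_grid_lookup(self, toy9):
        G, y = toy9
        model = fit_pair_grid_hybrid_one(G, y, [("m0", "m1")])
        Gnew = make_genotypes([[1, 0], [2, 0]])
        assert np.allclose(transform_pairs(model, Gnew)[:, 0], [6.0, 1.0])

    def test_missing_genotype_uses_fallback(self, toy9):
        G, y = toy9
        model = fit_pair_grid_hybrid_one(G, y, [("m0", "m1")])
        values = np.array([[MISSING, 2]], dtype=np.int8)
        Gm = GenotypeMatrix(("x",), ("m0", "m1"), values, oriented=True)
        assert transform_pairs(model, Gm)[0, 0] == pytest.approx(5.0)

    def test_unknown_marker_errors(self, toy9):
        from genoenc.encodings import TransformError

        G, y = toy9
        model = fit_pair_grid_hybrid_one(G, y, [("m0", "m1")])
        Gnew = make_genotypes([[0, 1]], marker_prefix="zz")
        with pytest.raises(TransformError):
            transform_pairs(model, Gnew)
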