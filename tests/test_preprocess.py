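import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spotmil import (
    BagAssignment,
    CellTable,
    SpotCounts,
    assign_cells_to_spots,
    inverse_robust_scale,
    lognormalize,
    morans_i,
    qc_filter,
    robust_scale,
    select_hvg,
    select_svg,
)


def _sc(counts, xy=None, radius=5.0):
    counts = np.asarray(counts)
    s, g = counts.shape
    if xy is None:
        xy = np.column_stack([np.arange(s) * 10.0, np.zeros(s)])
    return SpotCounts(
        counts=counts,
        spot_ids=np.array([f"s{i}" for i in range(s)], dtype=object),
        gene_ids=np.array([f"g{j}" for j in range(g)], dtype=object),
        slide_id="t",
        spot_xy=xy,
        spot_radius=radius,
    )


class TestQcFilter:
    def test_gene_rules_hand_counted(self):
        # totals [300, 250, 100]; detection fractions [1.0, 0.25, 1.0]
        counts = np.zeros((4, 3), dtype=int)
        counts[:, 0] = 75          # total 300, detected 4/4
        counts[0, 1] = 250         # total 250, detected 1/4
        counts[:, 2] = 25          # total 100, detected 4/4
        sc = _sc(counts)
        bags = BagAssignment({i: np.array([i]) for i in range(4)})
        gene_mask, _ = qc_filter(sc, bags, min_gene_counts=200, min_detect_frac=0.10)
        assert gene_mask.tolist() == [True, True, False]

    def test_spot_count_rule_hand_counted(self):
        counts = np.array([[360], [120], [15]])
        sc = _sc(counts)
        bags = BagAssignment({i: np.array([i]) for i in range(3)})
        _, spot_mask = qc_filter(sc, bags, min_gene_counts=1, min_detect_frac=0.0)
        assert spot_mask.tolist() == [True, True, False]

    def test_spot_without_cells_dropped(self):
        counts = np.array([[40], [40]])
        sc = _sc(counts)
        bags = BagAssignment({0: np.array([0])})  # spot 1 has no cells
        _, spot_mask = qc_filter(sc, bags, min_gene_counts=1, min_detect_frac=0.0)
        assert spot_mask.tolist() == [True, False]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(30, 20))
        sc = _sc(counts)
        bags = BagAssignment({i: np.array([i]) for i in range(30)})
        gm, sm = qc_filter(sc, bags, min_gene_counts=100, min_detect_frac=0.5, min_spot_counts=80)
        sc2 = _sc(counts[np.ix_(sm, gm)], xy=sc.spot_xy[sm])
        bags2 = BagAssignment({i: np.array([i]) for i in range(int(sm.sum()))})
        gm2, sm2 = qc_filter(sc2, bags2, min_gene_counts=100, min_detect_frac=0.5, min_spot_counts=80)
        assert gm2.all() and sm2.all()

    def test_all_genes_removed_is_an_error(self):
        sc = _sc(np.ones((3, 2), dtype=int))
        bags = BagAssignment({i: np.array([i]) for i in range(3)})
        with pytest.raises(ValueError, match="threshold"):
            qc_filter(sc, bags, min_gene_counts=10**6)


class TestLognormalize:
    def test_direct_formula_values(self):
        np.testing.assert_allclose(
            lognormalize(np.array([0.0, 4.0])), [0.0, np.log(10001)], rtol=1e-12
        )
        np.testing.assert_allclose(
            lognormalize(np.array([1.0, 3.0])),
            [np.log(2501), np.log(7501)],
            rtol=1e-12,
        )

    def test_single_gene_is_log1p_s(self):
        for c in (1.0, 7.0, 1000.0):
            np.testing.assert_allclose(lognormalize(np.array([c])), [np.log(10001)])

    @given(st.integers(min_value=1, max_value=50))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(3)
        y = rng.poisson(4, size=12).astype(float) + 1
        np.testing.assert_allclose(lognormalize(scale * y), lognormalize(y), rtol=1e-10)

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            lognormalize(np.zeros(4))


class TestRobustScale:
    def test_hand_computed_column(self):
        col = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        scaled, _ = robust_scale(col)
        np.testing.assert_allclose(scaled.ravel(), [-1, -0.5, 0, 0.5, 1])

    def test_constant_column_maps_to_zero(self):
        scaled, _ = robust_scale(np.full((3, 1), 7.0))
        np.testing.assert_array_equal(scaled, np.zeros((3, 1)))

    def test_per_slide_medians_map_to_zero(self):
        vals = np.array([[1.0], [2.0], [3.0], [101.0], [102.0], [103.0]])
        slides = np.array(["a", "a", "a", "b", "b", "b"], dtype=object)
        scaled, _ = robust_scale(vals, slides)
        assert scaled[1, 0] == 0.0 and scaled[4, 0] == 0.0

    def test_round_trip_identity(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(20, 5))
        slides = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        scaled, params = robust_scale(vals, slides)
        back = inverse_robust_scale(scaled, params, slides)
        np.testing.assert_allclose(back, vals, atol=1e-12)

    def test_uncentered_variant_preserves_sign(self):
        vals = np.abs(np.random.default_rng(2).normal(size=(10, 3))) + 0.1
        scaled, _ = robust_scale(vals, with_centering=False)
        assert scaled.min() > 0


class TestSelectHvg:
    def test_variance_order_at_equal_means(self):
        # three genes with equal means but raw variances 1, 9, 4
        rng = np.random.default_rng(0)
        n = 400
        base = rng.normal(size=n)
        counts = np.column_stack(
            [10 + base * 1.0, 10 + base * 3.0, 10 + base * 2.0]
        )
        sel = select_hvg([counts], ["g1", "g2", "g3"], n=3)
        assert sel.gene_ids == ["g2", "g3", "g1"]

    def test_two_identical_batches_match_single(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(rng.uniform(0.5, 20, 8), size=(100, 8)).astype(float)
        ids = [f"g{j}" for j in range(8)]
        single = select_hvg([counts], ids, n=4)
        double = select_hvg([counts, counts.copy()], ids, n=4)
        assert single.gene_ids == double.gene_ids

    def test_n_equals_g_returns_all_ranked(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(5, size=(50, 6)).astype(float)
        sel = select_hvg([counts], [f"g{j}" for j in range(6)], n=6)
        assert sorted(sel.gene_ids) == [f"g{j}" for j in range(6)]
        assert np.all(np.diff(sel.statistic) <= 1e-12)

    def test_n_too_large_rejected(self):
        with pytest.raises(ValueError):
            select_hvg([np.ones((5, 3))], ["a", "b", "c"], n=4)


def _brute_force_moran(values, xy, k):
    from spotmil.preprocess import _knn_weights

    w = _knn_weights(np.asarray(xy, float), k).toarray()
    x = np.asarray(values, float)
    n = len(x)
    z = x - x.mean()
    num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / w.sum()) * num / (z @ z)


class TestMoransI:
    def test_alternating_ring_is_minus_one(self):
        # 4 spots on a ring, each adjacent to its 2 ring neighbours
        xy = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        values = np.array([1.0, -1.0, 1.0, -1.0])
        assert morans_i(values, xy, n_neighbors=2) == pytest.approx(-1.0)

    def test_gradient_on_chain_is_positive(self):
        xy = np.column_stack([np.arange(10.0), np.zeros(10)])
        grad = np.arange(10.0)
        assert morans_i(grad, xy, n_neighbors=2) > 0

    def test_permutation_shrinks_magnitude(self):
        xy = np.column_stack([np.arange(10.0), np.zeros(10)])
        grad = np.arange(10.0)
        rng = np.random.default_rng(4)
        perm = rng.permutation(grad)
        assert abs(morans_i(perm, xy, 2)) < morans_i(grad, xy, 2)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(11)
        xy = rng.uniform(0, 100, size=(18, 2))
        values = rng.normal(size=18)
        fast = morans_i(values, xy, n_neighbors=6)
        slow = _brute_force_moran(values, xy, 6)
        assert fast == pytest.approx(slow, abs=1e-12)

    def test_constant_field_rejected(self):
        xy = np.column_stack([np.arange(5.0), np.zeros(5)])
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(5), xy, 2)


class TestSelectSvg:
    def test_single_slide_matches_moran_order(self):
        rng = np.random.default_rng(0)
        n = 30
        xy = np.column_stack([np.arange(float(n)), np.zeros(n)])
        smooth = np.linspace(1, 30, n) + rng.normal(0, 0.5, n)
        rough = rng.permutation(smooth)
        counts = np.column_stack([smooth, rough, rng.poisson(10, n)]).astype(int) + 1
        sel = select_svg([(counts, xy)], ["smooth", "rough", "noise"], n=3)
        assert sel.gene_ids[0] == "smooth"

    def test_shifted_geometric_mean_ordering(self):
        # gene A: I = (0.5, 0.5) -> sqrt(1.5*1.5) = 1.5
        # gene B: I = (0.9, 0.0) -> sqrt(1.9*1.0) ~ 1.378
        a = np.sqrt(1.5 * 1.5)
        b = np.sqrt(1.9 * 1.0)
        assert a > b  # the ordering the shifted geometric mean induces

    def test_n_one_returns_best(self):
        rng = np.random.default_rng(1)
        n = 20
        xy = np.column_stack([np.arange(float(n)), np.zeros(n)])
        counts = np.column_stack(
            [np.arange(n) + 1, rng.permutation(np.arange(n) + 1)]
        ).astype(int)
        sel = select_svg([(counts, xy)], ["grad", "perm"], n=1)
        assert sel.gene_ids == ["grad"]


class TestAssignCellsToSpots:
    def test_boundary_inclusive(self):
        sc = _sc(np.ones((1, 2), dtype=int), xy=np.array([[0.0, 0.0]]), radius=5.0)
        cells = CellTable(
            cell_ids=np.array(["c0"], dtype=object),
            slide_id="t",
            cell_xy=np.array([[3.0, 4.0]]),  # distance exactly 5
        )
        bags, unassigned = assign_cells_to_spots(cells, sc)
        assert bags.spot_to_cells[0].tolist() == [0] and len(unassigned) == 0

    def test_outside_radius_unassigned(self):
        sc = _sc(np.ones((1, 2), dtype=int), xy=np.array([[0.0, 0.0]]), radius=5.0)
        cells = CellTable(
            cell_ids=np.array(["c0"], dtype=object),
            slide_id="t",
            cell_xy=np.array([[6.0, 0.0]]),
        )
        bags, unassigned = assign_cells_to_spots(cells, sc)
        assert len(bags.spot_to_cells) == 0 and unassigned.tolist() == [0]

    def test_overlap_goes_to_nearer_spot(self):
        sc = _sc(
            np.ones((2, 2), dtype=int),
            xy=np.array([[0.0, 0.0], [8.0, 0.0]]),
            radius=6.0,
        )
        cells = CellTable(
            cell_ids=np.array(["c0"], dtype=object),
            slide_id="t",
            cell_xy=np.array([[5.0, 0.0]]),  # within both, nearer to spot 1
        )
        bags, _ = assign_cells_to_spots(cells, sc)
        assert 1 in bags.spot_to_cells and 0 not in bags.spot_to_cells

    def test_equidistant_tie_lower_index(self):
        sc = _sc(
            np.ones((2, 2), dtype=int),
            xy=np.array([[0.0, 0.0], [8.0, 0.0]]),
            radius=6.0,
        )
        cells = CellTable(
            cell_ids=np.array(["c0"], dtype=object),
            slide_id="t",
            cell_xy=np.array([[4.0, 0.0]]),
        )
        bags, _ = assign_cells_to_spots(cells, sc)
        assert 0 in bags.spot_to_cells
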