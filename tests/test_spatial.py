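"""Spatial weights, Moran's I (global/local), permutation inference, LISA."""

import numpy as np
import pytest

import hazegrid as hg
from hazegrid.spatial import (
    CLUSTER_HH, CLUSTER_HL, CLUSTER_LL, CLUSTER_NS, lisa_classify,
)


def brute_force_global(x, w):
    """Literal double-loop evaluation of the global statistic."""
    z = x - x.mean()
    W = w.w.toarray()
    n = len(x)
    num = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return n / W.sum() * num / np.sum(z ** 2)


def brute_force_local(x, w):
    z = x - x.mean()
    W = w.w.toarray()
    n = len(x)
    s2 = np.sum(z ** 2) / (n - 1)
    return np.array([z[i] / s2 * sum(W[i, j] * z[j] for j in range(n))
                     for i in range(n)])


class TestWeights:
    def test_rook_adjacency_counts(self, full_weights_3x3):
        w = full_weights_3x3
        card = w.cardinality.reshape(3, 3)
        assert card[1, 1] == 4
        assert card[0, 0] == card[0, 2] == card[2, 0] == card[2, 2] == 2
        assert card[0, 1] == 3

    def test_queen_adjacency_counts(self):
        w = hg.build_weights(np.ones((3, 3), bool), "queen", "binary")
        card = w.cardinality.reshape(3, 3)
        assert card[1, 1] == 8 and card[0, 0] == 3

    def test_row_standardized_rows_sum_to_one(self):
        w = hg.build_weights(np.ones((5, 7), bool), "queen", "row")
        sums = np.asarray(w.w.sum(axis=1)).ravel()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_no_self_neighbours(self):
        w = hg.build_weights(np.ones((4, 4), bool), "queen", "binary")
        assert w.w.diagonal().sum() == 0

    def test_nodata_cells_removed_from_graph(self):
        mask = np.ones((4, 4), bool)
        mask[1, 1] = False
        w = hg.build_weights(mask, "rook", "binary")
        assert w.n == 15
        # the removed cell's neighbours lose one edge each
        card = w.expand(w.cardinality.astype(float))
        assert card[0, 1] == 2 and card[1, 0] == 2

    def test_too_few_cells_rejected(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = True
        with pytest.raises(ValueError):
            hg.build_weights(mask)


class TestGlobalMoran:
    def test_checkerboard_is_minus_one(self):
        x = (np.indices((4, 4)).sum(axis=0) % 2).astype(float)
        w = hg.build_weights(np.ones((4, 4), bool), "rook", "row")
        assert hg.global_morans_i(x, w) == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        w = hg.build_weights(np.ones((3, 3), bool), "rook", "row")
        with pytest.raises(ValueError, match="variance"):
            hg.global_morans_i(np.ones(9), w)

    def test_smooth_gradient_strongly_positive(self):
        x = np.tile(np.arange(10.0), (10, 1))
        w = hg.build_weights(np.ones((10, 10), bool), "rook", "row")
        assert hg.global_morans_i(x, w) > 0.8

    @pytest.mark.parametrize("scheme", ["rook", "queen"])
    @pytest.mark.parametrize("standardization", ["row", "binary"])
    def test_matches_brute_force_on_small_grids(self, scheme, standardization):
        rng = np.random.default_rng(0)
        for shape in [(2, 2), (3, 4), (5, 5), (4, 6)]:
            if shape[0] * shape[1] > 25:
                continue
            x = rng.random(shape[0] * shape[1])
            w = hg.build_weights(np.ones(shape, bool), scheme, standardization)
            assert hg.global_morans_i(x, w) == pytest.approx(
                brute_force_global(x, w), abs=1e-12)

    def test_sign_behaviour_alternating_vs_smooth(self):
        checker = (np.indices((6, 6)).sum(axis=0) % 2).astype(float)
        smooth = np.tile(np.linspace(0, 1, 6), (6, 1))
        for scheme in ("rook", "queen"):
            w = hg.build_weights(np.ones((6, 6), bool), scheme, "row")
            assert hg.global_morans_i(checker, w) < 0
            assert hg.global_morans_i(smooth, w) > 0

    def test_permutation_p_detects_structure(self):
        x = np.tile(np.arange(8.0), (8, 1))
        w = hg.build_weights(np.ones((8, 8), bool), "queen", "row")
        i_obs, p = hg.global_morans_i(x, w, n_perm=199, seed=1)
        assert i_obs > 0.5 and p <= 0.01


class TestLocalMoran:
    def test_sign_contracts(self):
        x = np.zeros((5, 5))
        x[1:4, 1:4] = 5.0  # high plateau: centre above mean amid high values
        w = hg.build_weights(np.ones((5, 5), bool), "rook", "row")
        li = w.expand(hg.local_morans_i(x, w))
        assert li[2, 2] > 0
        x2 = np.zeros((5, 5))
        x2[2, 2] = 5.0     # isolated spike amid low values
        li2 = w.expand(hg.local_morans_i(x2, w))
        assert li2[2, 2] < 0

    def test_three_by_three_worked_grid(self):
        x = np.arange(1.0, 10.0)
        w = hg.build_weights(np.ones((3, 3), bool), "rook", "row")
        np.testing.assert_allclose(hg.local_morans_i(x, w),
                                   brute_force_local(x, w), atol=1e-12)

    @pytest.mark.parametrize("scheme", ["rook", "queen"])
    def test_matches_brute_force_on_small_grids(self, scheme):
        rng = np.random.default_rng(2)
        for shape in [(3, 3), (4, 5), (5, 5)]:
            x = rng.random(shape[0] * shape[1])
            w = hg.build_weights(np.ones(shape, bool), scheme, "row")
            np.testing.assert_allclose(hg.local_morans_i(x, w),
                                       brute_force_local(x, w), atol=1e-12)

    def test_sum_identity_with_global(self):
        rng = np.random.default_rng(3)
        x = rng.random(30)
        w = hg.build_weights(np.ones((5, 6), bool), "queen", "row")
        n = w.n
        s0 = float(w.w.sum())
        total = hg.local_morans_i(x, w).sum()
        assert total == pytest.approx(
            hg.global_morans_i(x, w) * s0 * (n - 1) / n, abs=1e-10)


class TestPermutationInference:
    def test_identical_seed_identical_p(self):
        rng = np.random.default_rng(4)
        x = rng.random(36)
        w = hg.build_weights(np.ones((6, 6), bool), "queen", "row")
        p1 = hg.permutation_p(x, w, n_perm=99, seed=7)
        p2 = hg.permutation_p(x, w, n_perm=99, seed=7)
        np.testing.assert_array_equal(p1, p2)

    def test_minimum_permutations_enforced(self):
        w = hg.build_weights(np.ones((3, 3), bool), "rook", "row")
        with pytest.raises(ValueError, match="99"):
            hg.permutation_p(np.arange(9.0), w, n_perm=10)

    def test_type_one_error_calibrated_on_white_noise(self):
        """Empirical rejection rate at α = 0.05 under the null lies in
        [0.03, 0.08] (999 permutations, 20 seeds, 20×20 grid)."""
        rates = []
        w = hg.build_weights(np.ones((20, 20), bool), "queen", "row")
        for seed in range(20):
            x = np.random.default_rng(1000 + seed).standard_normal(400)
            p = hg.permutation_p(x, w, n_perm=999, seed=seed)
            rates.append(np.mean(p[np.isfinite(p)] <= 0.05))
        assert 0.03 <= np.mean(rates) <= 0.08

    def test_power_on_clustered_blob(self):
        spec_shape = (15, 15)
        x = np.random.default_rng(5).normal(0, 0.1, spec_shape)
        x[5:10, 5:10] += 4.0
        w = hg.build_weights(np.ones(spec_shape, bool), "queen", "row")
        p = hg.permutation_p(w.compact(x), w, n_perm=499, seed=0)
        blob = np.zeros(spec_shape, bool)
        blob[6:9, 6:9] = True  # blob interior
        p_grid = w.expand(p)
        assert np.mean(p_grid[blob] <= 0.05) > 0.9


class TestLISAClassification:
    def test_all_insignificant_is_ns(self):
        x = np.arange(9.0)
        w = hg.build_weights(np.ones((3, 3), bool), "rook", "row")
        li = hg.local_morans_i(x, w)
        codes = lisa_classify(x, li, np.ones(9), alpha=0.05, w=w)
        assert (codes == CLUSTER_NS).all()

    def test_plateau_and_sea_quadrants(self):
        # a high plateau over half the grid: interiors of both phases are
        # unusually homogeneous relative to the 50/50 value mix
        grid = np.zeros((20, 20))
        grid[:, :10] = 10.0
        res = hg.lisa(grid, scheme="queen", alpha=0.05, n_perm=499, seed=2)
        assert (res.cluster[2:18, 2:8] == CLUSTER_HH).all()  # plateau interior
        assert (res.cluster[2:18, 12:18] == CLUSTER_LL).all()  # sea interior
        assert res.global_i > 0.5

    def test_single_high_outlier_is_hl(self):
        # a high spike whose immediate neighbours are unusually low for the
        # surrounding value distribution: the textbook high-low outlier
        rng = np.random.default_rng(3)
        grid = 5.0 + rng.normal(0, 0.2, (9, 9))
        grid[4, 4] = 50.0
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            grid[4 + dr, 4 + dc] = 0.0
        res = hg.lisa(grid, scheme="rook", alpha=0.05, n_perm=999, seed=3)
        assert res.cluster[4, 4] == CLUSTER_HL

    def test_nodata_cells_excluded(self):
        grid = np.random.default_rng(6).random((8, 8))
        grid[0, :] = np.nan
        res = hg.lisa(grid, n_perm=99, seed=0)
        assert np.isnan(res.local_i[0, :]).all()
        assert np.isfinite(res.local_i[2:, :]).all()
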