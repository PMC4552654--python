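import numpy as np
import pytest

import forestprio as fp

from _oracles import brute_force_removal_order, direct_kernel_transform
from conftest import random_stack


class TestConnectivityAlpha:
    @pytest.mark.parametrize(
        "km,expected", [(2.0, 0.001), (0.2, 0.01), (4.0, 0.0005)]
    )
    def test_alpha_is_two_over_mean_dispersal(self, km, expected):
        assert fp.connectivity_alpha(km) == pytest.approx(expected, rel=1e-12)

    def test_non_positive_distance_rejected(self):
        with pytest.raises(ValueError):
            fp.connectivity_alpha(0.0)


class TestMatrixConnectivityTransform:
    def test_point_kernel_reproduces_original(self):
        rng = np.random.default_rng(0)
        stack = random_stack(rng, h=5, w=5, n_features=2)
        # alpha so large the kernel truncates inside one cell
        cfg = fp.ConnectivityConfig(
            mean_dispersal_km=0.001, multiplier_matrix=np.eye(2), kernel_truncation=1e-6
        )
        out = fp.matrix_connectivity_transform(stack, cfg)
        np.testing.assert_allclose(out.data, stack.data, rtol=1e-12)

    def test_uniform_layer_stays_uniform_in_the_interior(self):
        h = w = 21
        stack = fp.FeatureStack(
            names=["f"], data=np.full((1, h, w), 3.0), weights=np.ones(1),
            group_labels=[("f", None)], valid_mask=np.ones((h, w), dtype=bool),
            cell_size=60.0,
        )
        cfg = fp.ConnectivityConfig(
            mean_dispersal_km=0.06, multiplier_matrix=np.eye(1), kernel_truncation=1e-3
        )
        out = fp.matrix_connectivity_transform(stack, cfg)
        # truncation radius ~3.5 cells: cells deeper than that see identical kernels
        interior = out.data[0, 5:-5, 5:-5]
        assert interior.std() / interior.mean() < 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_direct_double_loop_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        n_feat = 2
        stack = random_stack(rng, h=5, w=5, n_features=n_feat)
        M = rng.uniform(0.1, 1.0, size=(n_feat, n_feat))
        np.fill_diagonal(M, 1.0)
        cfg = fp.ConnectivityConfig(
            mean_dispersal_km=2 / (2 / 120) / 1000,  # alpha = 2/120 per metre
            multiplier_matrix=M,
            kernel_truncation=1e-6,
        )
        out = fp.matrix_connectivity_transform(stack, cfg)
        expected = direct_kernel_transform(
            stack.data, stack.valid_mask, M, cfg.alphas(n_feat), 60.0, 1e-6
        )
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_layer_totals_conserved(self):
        rng = np.random.default_rng(3)
        stack = random_stack(rng, h=12, w=10, n_features=3)
        stack.valid_mask[2:4, 2:5] = False
        stack.data[:, ~stack.valid_mask] = 0.0
        cfg = fp.ConnectivityConfig(mean_dispersal_km=0.5)
        out = fp.matrix_connectivity_transform(stack, cfg)
        np.testing.assert_allclose(out.totals(), stack.totals(), rtol=1e-9)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        stack = random_stack(rng, n_features=2)
        cfg = fp.ConnectivityConfig(multiplier_matrix=np.eye(3))
        with pytest.raises(ValueError, match="dimension"):
            fp.matrix_connectivity_transform(stack, cfg)

    def test_original_stack_untouched(self):
        rng = np.random.default_rng(7)
        stack = random_stack(rng, h=6, w=6)
        before = stack.data.copy()
        fp.matrix_connectivity_transform(stack, fp.ConnectivityConfig())
        np.testing.assert_array_equal(stack.data, before)


def test_default_multiplier_matrix_structure():
    labels = [("pine", 1), ("pine", 2), ("birch", 1)]
    M = fp.default_multiplier_matrix(labels)
    assert M[0, 0] == 1.0
    assert M[0, 1] == 0.5  # same species, different fertility
    assert M[0, 2] == 0.2  # different species


class TestRankLandscape:
    def test_single_feature_z1_removes_ascending_values(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(12).astype(float).reshape(3, 4) + 1.0
        stack = fp.FeatureStack(
            names=["f"], data=vals[None], weights=np.ones(1),
            group_labels=[("f", None)], valid_mask=np.ones((3, 4), dtype=bool),
        )
        r = fp.rank_landscape(stack, fp.PrioritizationConfig(z_exponent=1.0))
        assert np.array_equal(r.removal_order, np.argsort(vals.ravel(), kind="stable"))
        # rank is the normalized value rank
        assert np.array_equal(np.argsort(r.rank.ravel()), np.argsort(vals.ravel(), kind="stable"))

    def test_identical_cells_follow_tie_break_order(self):
        stack = fp.FeatureStack(
            names=["a", "b"], data=np.full((2, 3, 3), 2.0), weights=np.array([1.0, 2.0]),
            group_labels=[("a", None), ("b", None)],
            valid_mask=np.ones((3, 3), dtype=bool),
        )
        r = fp.rank_landscape(stack, fp.PrioritizationConfig())
        assert np.array_equal(r.removal_order, np.arange(9))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = int(rng.integers(2, 5))
        w = int(rng.integers(2, 5))
        n_feat = int(rng.integers(2, 5))
        stack = random_stack(rng, h=h, w=w, n_features=n_feat)
        r = fp.rank_landscape(stack, fp.PrioritizationConfig(z_exponent=0.25))
        expected = brute_force_removal_order(
            stack.data.reshape(n_feat, -1).T, stack.weights, 0.25
        )
        assert r.removal_order.tolist() == expected

    def test_four_cell_two_feature_instance_matches_oracle(self):
        data = np.array([[[4.0, 1.0], [2.0, 8.0]], [[1.0, 5.0], [7.0, 2.0]]])
        stack = fp.FeatureStack(
            names=["a", "b"], data=data, weights=np.array([1.0, 1.5]),
            group_labels=[("a", None), ("b", None)],
            valid_mask=np.ones((2, 2), dtype=bool),
        )
        r = fp.rank_landscape(stack, fp.PrioritizationConfig(z_exponent=0.25))
        expected = brute_force_removal_order(data.reshape(2, -1).T, stack.weights, 0.25)
        assert r.removal_order.tolist() == expected

    def test_scaling_one_feature_preserves_order(self):
        rng = np.random.default_rng(5)
        stack = random_stack(rng, h=5, w=5, n_features=3)
        r1 = fp.rank_landscape(stack, fp.PrioritizationConfig())
        scaled = stack.copy()
        scaled.data[1] *= 3.7
        r2 = fp.rank_landscape(scaled, fp.PrioritizationConfig())
        assert np.array_equal(r1.removal_order, r2.removal_order)

    def test_unit_condition_reproduces_ranking_bit_for_bit(self):
        rng = np.random.default_rng(6)
        stack = random_stack(rng, h=6, w=6, n_features=2)
        r1 = fp.rank_landscape(stack, fp.PrioritizationConfig())
        cond = fp.ConditionLayer(
            multiplier=np.ones((6, 6)), effect_table={}
        )
        r2 = fp.rank_landscape(stack, fp.PrioritizationConfig(condition=cond))
        assert np.array_equal(r1.removal_order, r2.removal_order)
        assert np.array_equal(r1.rank, r2.rank)
        assert np.array_equal(r1.curves, r2.curves)

    def test_condition_discounts_value(self):
        # a cell whose value is fully discounted drops to the bottom
        vals = np.array([[[5.0, 10.0, 3.0]]])
        cond_mult = np.array([[1.0, 0.0, 1.0]])
        stack = fp.FeatureStack(
            names=["f"], data=vals, weights=np.ones(1),
            group_labels=[("f", None)], valid_mask=np.ones((1, 3), dtype=bool),
        )
        cond = fp.ConditionLayer(multiplier=cond_mult, effect_table={})
        r = fp.rank_landscape(
            stack, fp.PrioritizationConfig(z_exponent=1.0, condition=cond)
        )
        assert r.removal_order.tolist() == [1, 2, 0]

    def test_rank_is_bijection_onto_unit_grid(self):
        rng = np.random.default_rng(8)
        stack = random_stack(rng, h=7, w=5, n_features=2)
        stack.valid_mask[0, :3] = False
        stack.data[:, ~stack.valid_mask] = 0.0
        r = fp.rank_landscape(stack, fp.PrioritizationConfig())
        n = r.n_cells
        ranks = np.sort(r.rank[stack.valid_mask])
        np.testing.assert_allclose(ranks, np.arange(1, n + 1) / n)
        assert np.all(np.isnan(r.rank[~stack.valid_mask]))

    def test_curves_start_at_one_decrease_to_zero(self):
        rng = np.random.default_rng(9)
        stack = random_stack(rng, h=6, w=6, n_features=3)
        r = fp.rank_landscape(stack, fp.PrioritizationConfig())
        assert np.all(r.curves[0] == 1.0)
        assert np.all(r.curves[-1] == 0.0)
        assert np.all(np.diff(r.curves, axis=0) <= 1e-15)

    def test_all_zero_stack_warns_and_uses_tie_break(self):
        stack = fp.FeatureStack(
            names=["f"], data=np.zeros((1, 2, 2)), weights=np.ones(1),
            group_labels=[("f", None)], valid_mask=np.ones((2, 2), dtype=bool),
        )
        with pytest.warns(UserWarning, match="zero"):
            r = fp.rank_landscape(stack, fp.PrioritizationConfig())
        assert np.array_equal(r.removal_order, np.arange(4))

    def test_weight_increase_never_hurts_that_feature(self):
        for seed in range(4):
            rng = np.random.default_rng(seed)
            stack = random_stack(rng, h=5, w=5, n_features=3)
            base = fp.performance_at(
                fp.rank_landscape(stack, fp.PrioritizationConfig()), 0.1
            )
            boosted = stack.copy()
            boosted.weights[0] *= 4.0
            bumped = fp.performance_at(
                fp.rank_landscape(boosted, fp.PrioritizationConfig()), 0.1
            )
            assert bumped[0] >= base[0] - 1e-12

    def test_batch_removal_ranks_share_batch_position(self):
        rng = np.random.default_rng(10)
        stack = random_stack(rng, h=4, w=4, n_features=2)
        r = fp.rank_landscape(stack, fp.PrioritizationConfig(removal_batch=4))
        vals = np.unique(r.rank[stack.valid_mask])
        np.testing.assert_allclose(vals, [0.25, 0.5, 0.75, 1.0])


class TestPerformanceAndCrossLoad:
    def _ten_cell_result(self):
        vals = np.arange(1.0, 11.0).reshape(1, 2, 5)
        stack = fp.FeatureStack(
            names=["f"], data=vals, weights=np.ones(1),
            group_labels=[("f", None)], valid_mask=np.ones((2, 5), dtype=bool),
        )
        return stack, fp.rank_landscape(stack, fp.PrioritizationConfig(z_exponent=1.0))

    def test_full_and_empty_fractions(self):
        _, r = self._ten_cell_result()
        assert np.all(fp.performance_at(r, 1.0) == 1.0)
        assert np.all(fp.performance_at(r, 0.0) == 0.0)

    def test_top_three_of_ten(self):
        _, r = self._ten_cell_result()
        assert fp.performance_at(r, 0.3)[0] == pytest.approx((8 + 9 + 10) / 55)

    def test_cross_load_on_native_order_equals_performance(self):
        rng = np.random.default_rng(11)
        stack = random_stack(rng, h=5, w=5, n_features=3)
        r = fp.rank_landscape(stack, fp.PrioritizationConfig())
        native = fp.performance_at(r, 0.2)
        cross = fp.cross_load_evaluation(r, stack, 0.2)
        np.testing.assert_allclose(cross["per_feature"].to_numpy(), native, rtol=1e-12)

    def test_reversed_order_covers_bottom_decile(self):
        stack, r = self._ten_cell_result()
        reversed_result = fp.RankResult(
            rank=1.0 + 1.0 / 10 - r.rank,  # flips the ordering
            removal_order=r.removal_order[::-1].copy(),
            curves=r.curves,
            feature_names=r.feature_names,
            valid_mask=r.valid_mask,
            adjusted_totals=r.adjusted_totals,
        )
        cross = fp.cross_load_evaluation(reversed_result, stack, 0.1)
        assert cross["per_feature"].iloc[0] == pytest.approx(1 / 55)

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        stack, r = self._ten_cell_result()
        other = random_stack(rng, h=3, w=3)
        with pytest.raises(ValueError, match="grid"):
            fp.cross_load_evaluation(r, other, 0.1)
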