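import numpy as np
import pytest

from blocksdm.geo import PointLL, haversine_km
from blocksdm.grid_io import Grid, GridHeader, point_cell_indices
from blocksdm.synthetic_data import (
    make_bias_field,
    make_env_stack,
    make_future_stack,
    make_world,
    sample_presences,
    true_suitability,
)


class TestMakeEnvStack:
    def test_same_seed_is_bit_identical(self):
        a = make_env_stack(n_vars=4, seed=9)
        c = make_env_stack(n_vars=4, seed=9)
        for name in a.names:
            np.testing.assert_array_equal(a[name].values, c[name].values)

    def test_planted_pair_is_strongly_correlated(self):
        stack = make_env_stack(n_vars=4, corr_groups=[{0, 1}], seed=2)
        v0 = stack[stack.names[0]].values.ravel()
        v1 = stack[stack.names[1]].values.ravel()
        assert abs(np.corrcoef(v0, v1)[0, 1]) >= 0.85

    def test_ungrouped_variables_stay_below_threshold(self):
        # independence holds for blur scales up to 2 cells
        for seed in range(10):
            stack = make_env_stack(n_vars=6, seed=seed, blur_cells=2.0)
            X = np.column_stack([stack[n].values.ravel() for n in stack.names])
            r = np.corrcoef(X, rowvar=False)
            off = r[~np.eye(6, dtype=bool)]
            assert np.abs(off).max() < 0.8

    def test_fields_are_standardised(self):
        stack = make_env_stack(n_vars=3, seed=4)
        for name in stack.names:
            v = stack[name].values
            assert v.mean() == pytest.approx(0.0, abs=1e-9)
            assert v.std() == pytest.approx(1.0, abs=1e-9)

    def test_group_index_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="n_vars"):
            make_env_stack(n_vars=3, corr_groups=[{0, 5}])

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            make_env_stack(n_vars=5, corr_groups=[{0, 1}, {1, 2}])


class TestTrueSuitability:
    def test_zero_model_gives_uniform_half(self):
        stack = make_env_stack(n_vars=2, seed=1)
        t = true_suitability(stack, {}, intercept=0.0)
        assert np.all(t.values == 0.5)

    def test_large_negative_intercept_saturates_to_zero(self):
        stack = make_env_stack(n_vars=2, seed=1)
        t = true_suitability(stack, {}, intercept=-20.0)
        assert t.values.max() < 1e-8

    def test_single_positive_coefficient_is_rank_monotone(self):
        stack = make_env_stack(n_vars=2, seed=3)
        name = stack.names[0]
        t = true_suitability(stack, {name: 1.0})
        order_var = np.argsort(stack[name].values.ravel())
        order_truth = np.argsort(t.values.ravel())
        np.testing.assert_array_equal(order_var, order_truth)

    def test_unknown_variable_raises(self):
        stack = make_env_stack(n_vars=2, seed=1)
        with pytest.raises(KeyError):
            true_suitability(stack, {"nope": 1.0})


class TestBiasField:
    def test_weight_at_center_is_one(self):
        h = GridHeader(10, 10, 30.0, 40.0, 0.5)
        lon, lat = h.cell_center(np.array([4]), np.array([6]))
        bias = make_bias_field(h, [PointLL(lon[0], lat[0])], decay_km=50.0)
        assert bias.values[4, 6] == pytest.approx(1.0)

    def test_decreases_with_distance_from_single_center(self):
        h = GridHeader(20, 20, 30.0, 40.0, 0.5)
        c = PointLL(35.0, 45.0)
        bias = make_bias_field(h, [c], decay_km=50.0)
        rows, cols = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        lon, lat = h.cell_center(rows.ravel(), cols.ravel())
        d = np.array([haversine_km((x, y), (c.lon, c.lat)) for x, y in zip(lon, lat)])
        order = np.argsort(d)
        w = bias.values.ravel()[order]
        assert np.all(np.diff(w) <= 1e-12)

    def test_two_symmetric_centers_give_mirror_field(self):
        # centers mirrored about the grid's E-W midline on a symmetric grid
        h = GridHeader(10, 10, 0.0, -2.5, 0.5)
        bias = make_bias_field(
            h, [PointLL(1.25, 1.25), PointLL(1.25, -1.25)], decay_km=100.0
        )
        np.testing.assert_allclose(bias.values, bias.values[::-1, :], atol=1e-9)

    def test_rejects_bad_inputs(self):
        h = GridHeader(2, 2, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            make_bias_field(h, [PointLL(0, 0)], decay_km=0.0)
        with pytest.raises(ValueError):
            make_bias_field(h, [], decay_km=10.0)


class TestSamplePresences:
    def test_degenerate_support_concentrates_all_points(self):
        h = GridHeader(5, 5, 0.0, 0.0, 1.0)
        truth = Grid(h, np.zeros((5, 5)))
        truth.values[2, 3] = 1.0
        bias = Grid(h, np.ones((5, 5)))
        pts = sample_presences(truth, bias, 50, seed=1)
        r, c, inside = point_cell_indices(h, pts[:, 0], pts[:, 1])
        assert inside.all()
        assert np.all(r == 2) and np.all(c == 3)

    def test_n_zero_gives_empty(self):
        h = GridHeader(2, 2, 0.0, 0.0, 1.0)
        g = Grid(h, np.ones((2, 2)))
        assert sample_presences(g, g, 0).shape == (0, 2)

    def test_zero_product_field_raises(self):
        h = GridHeader(2, 2, 0.0, 0.0, 1.0)
        zero = Grid(h, np.zeros((2, 2)))
        one = Grid(h, np.ones((2, 2)))
        with pytest.raises(ValueError, match="zero"):
            sample_presences(zero, one, 5)

    def test_counts_track_truth_times_bias(self, world):
        pts = sample_presences(world.truth, world.bias, 5000, seed=77)
        h = world.truth.header
        r, c, _ = point_cell_indices(h, pts[:, 0], pts[:, 1])
        counts = np.zeros((h.nrows, h.ncols))
        np.add.at(counts, (r, c), 1)
        w = (world.truth.values * world.bias.values).ravel()
        assert np.corrcoef(counts.ravel(), w)[0, 1] > 0.9

    def test_bias_is_recoverable_from_presence_density(self, world):
        # density / truth correlates with the effort field: the structure
        # spatial thinning is meant to mitigate
        pts = sample_presences(world.truth, world.bias, 5000, seed=78)
        h = world.truth.header
        r, c, _ = point_cell_indices(h, pts[:, 0], pts[:, 1])
        counts = np.zeros((h.nrows, h.ncols))
        np.add.at(counts, (r, c), 1)
        ok = world.truth.values > 0.05
        ratio = counts[ok] / world.truth.values[ok]
        assert np.corrcoef(ratio, world.bias.values[ok])[0, 1] > 0.5

    def test_determinism(self, world):
        a = sample_presences(world.truth, world.bias, 100, seed=5)
        c = sample_presences(world.truth, world.bias, 100, seed=5)
        np.testing.assert_array_equal(a, c)


class TestWorldAndFuture:
    def test_truth_in_unit_interval_and_cold_strip_near_zero(self, world):
        assert world.truth.values.min() >= 0.0
        assert world.truth.values.max() <= 1.0
        n_strip = world.truth.header.nrows // 5
        assert world.truth.values[:n_strip].max() < 0.05

    def test_future_stack_warms_only_temperature_layers(self, world):
        fut = make_future_stack(world.stack, temp_shift_sd=1.0)
        assert np.all(fut["BIO1"].values > world.stack["BIO1"].values)
        np.testing.assert_array_equal(fut["BIO13"].values, world.stack["BIO13"].values)
        np.testing.assert_array_equal(fut["SOC"].values, world.stack["SOC"].values)
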