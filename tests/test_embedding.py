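"""Delay embedding, distance matrices, thresholding and Theiler masking."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import crossrec as cr
from crossrec.errors import InsufficientLengthError, ValidationError

from reference import naive_distance, naive_embed, naive_recurrent_points


class TestEmbedSeries:
    def test_dim_one_is_identity(self, rng):
        x = rng.standard_normal(30)
        emb = cr.embed_series(x, delay=5, dim=1)
        assert emb.points.shape == (30, 1)
        np.testing.assert_array_equal(emb.points[:, 0], x)

    def test_pairs_of_consecutive_values(self):
        emb = cr.embed_series([1, 2, 3, 4, 5], delay=1, dim=2)
        np.testing.assert_array_equal(
            emb.points, [[1, 2], [2, 3], [3, 4], [4, 5]])

    def test_row_count_formula(self, rng):
        emb = cr.embed_series(rng.standard_normal(1000), delay=10, dim=3)
        assert emb.points.shape == (980, 3)

    def test_columns_are_delayed_copies(self, rng):
        x = rng.standard_normal(100)
        emb = cr.embed_series(x, delay=7, dim=3)
        for k in range(3):
            np.testing.assert_array_equal(emb.points[:, k], x[7 * k: 7 * k + 86])

    def test_too_short_raises_and_names_minimum(self):
        with pytest.raises(InsufficientLengthError, match="minimum length 21"):
            cr.embed_series(np.arange(20.0), delay=10, dim=3)


class TestCrossDistance:
    def test_self_distance_symmetric_zero_diagonal(self, rng):
        a = cr.embed_series(rng.standard_normal(40), delay=2, dim=2)
        D = cr.cross_distance_matrix(a, a)
        assert np.allclose(np.diag(D), 0)
        assert np.allclose(D, D.T)

    def test_hand_computed_values(self):
        a = cr.embed_series([0.0, 1.0, 2.0], delay=1, dim=1)
        b = cr.embed_series([0.0, 0.0, 0.0], delay=1, dim=1)
        D = cr.cross_distance_matrix(a, b)
        np.testing.assert_allclose(D, [[0, 0, 0], [1, 1, 1], [2, 2, 2]])

    def test_matches_naive_loop_oracle(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        a, b = cr.embed_series(x, 2, 3), cr.embed_series(y, 2, 3)
        D = cr.cross_distance_matrix(a, b)
        expected = naive_distance(naive_embed(x, 2, 3), naive_embed(y, 2, 3))
        np.testing.assert_allclose(D, expected, atol=1e-12)

    @pytest.mark.parametrize("mode,stat", [("mean", np.mean), ("max", np.max)])
    def test_rescale_sets_reference_to_100(self, rng, mode, stat):
        a = cr.embed_series(rng.standard_normal(30), 1, 2)
        b = cr.embed_series(rng.standard_normal(30), 1, 2)
        D = cr.cross_distance_matrix(a, b, rescale=mode)
        assert stat(D) == pytest.approx(100.0)

    def test_dim_mismatch_rejected(self, rng):
        a = cr.embed_series(rng.standard_normal(30), 1, 2)
        b = cr.embed_series(rng.standard_normal(30), 1, 3)
        with pytest.raises(ValidationError, match="dimension"):
            cr.cross_distance_matrix(a, b)


class TestThreshold:
    def test_near_zero_radius_keeps_exact_matches_only(self):
        x = np.array([1, 2, 1, 3], dtype=float)
        y = np.array([2, 1, 1, 3], dtype=float)
        D = np.abs(x[:, None] - y[None, :])
        R = cr.threshold_to_recurrence(D, 0.001)
        expected = {(i + 1, j + 1) for i in range(4) for j in range(4)
                    if x[i] == y[j]}
        assert set(map(tuple, R.points())) == expected

    def test_hand_enumerated_three_by_three(self):
        D = np.abs(np.array([0., 1., 0.])[:, None] - np.array([0., 0., 1.])[None, :])
        R = cr.threshold_to_recurrence(D, 0.5)
        assert set(map(tuple, R.points())) == {(1, 1), (1, 2), (2, 3), (3, 1), (3, 2)}
        assert R.recurrence_rate == pytest.approx(100 * 5 / 9)

    def test_radius_above_max_saturates(self, rng):
        D = np.abs(rng.standard_normal((6, 6)))
        R = cr.threshold_to_recurrence(D, D.max())
        assert R.count == 36
        assert R.recurrence_rate == 100.0


class TestTheilerWindow:
    def _full(self, n):
        D = np.zeros((n, n))
        return cr.threshold_to_recurrence(D, 1.0)

    def test_zero_window_is_identity(self):
        R = self._full(3)
        R2 = cr.apply_theiler_window(R, 0)
        assert set(map(tuple, R2.points())) == set(map(tuple, R.points()))

    def test_window_one_removes_main_diagonal(self):
        R2 = cr.apply_theiler_window(self._full(3), 1)
        assert R2.count == 6
        assert all(i != j for i, j in R2.points())

    def test_window_two_keeps_far_corners(self):
        R2 = cr.apply_theiler_window(self._full(3), 2)
        assert set(map(tuple, R2.points())) == {(1, 3), (3, 1)}

    def test_window_covering_everything_rejected(self):
        with pytest.raises(ValidationError, match="every diagonal"):
            cr.apply_theiler_window(self._full(3), 3)

    def test_rectangular_matrix_rejected(self):
        R = cr.threshold_to_recurrence(np.zeros((3, 4)), 1.0)
        with pytest.raises(ValidationError, match="square"):
            cr.apply_theiler_window(R, 1)


class TestInvariants:
    @given(st.integers(0, 2 ** 31 - 1))
    def test_recurrence_count_monotone_in_radius(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal(25), rng.standard_normal(25)
        D = np.abs(x[:, None] - y[None, :])
        counts = [cr.threshold_to_recurrence(D, r).count
                  for r in np.linspace(0, D.max(), 8)]
        assert counts == sorted(counts)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_swapping_series_transposes_the_plot(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal(20), rng.standard_normal(24)
        Rxy = cr.recurrence_matrix(x, y, radius=0.8, datatype="continuous")
        Ryx = cr.recurrence_matrix(y, x, radius=0.8, datatype="continuous")
        flipped = {(j, i) for i, j in map(tuple, Rxy.points())}
        assert set(map(tuple, Ryx.points())) == flipped

    def test_identical_inputs_recur_along_the_main_diagonal(self, rng):
        x = rng.standard_normal(15)
        R = cr.recurrence_matrix(x, x, radius=0.0, datatype="continuous")
        pts = set(map(tuple, R.points()))
        assert {(i, i) for i in range(1, 16)} <= pts

    def test_vectorized_pipeline_matches_naive_oracle_exactly(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 200))
            dim = int(rng.integers(1, 4))
            delay = int(rng.integers(1, 4))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            D_naive = naive_distance(naive_embed(x, delay, dim),
                                     naive_embed(y, delay, dim))
            radius = float(np.quantile(np.asarray(D_naive), 0.2))
            R = cr.recurrence_matrix(x, y, delay=delay, embed=dim, radius=radius,
                                     datatype="continuous")
            assert set(map(tuple, R.points())) == naive_recurrent_points(D_naive, radius)


class TestDenseGuard:
    def test_small_matrix_densifies(self):
        R = cr.threshold_to_recurrence(np.zeros((4, 5)), 1.0)
        assert R.to_dense().shape == (4, 5)
        assert R.to_dense().all()

    def test_guard_refuses_oversized(self):
        R = cr.RecurrenceMatrix(10, 10, np.array([0]), np.array([0]))
        with pytest.raises(ValidationError, match="guard"):
            R.to_dense(guard=5)
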