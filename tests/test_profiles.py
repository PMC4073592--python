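"""Diagonal-wise recurrence profiles and windowed recurrence."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import crossrec as cr
from crossrec.errors import ValidationError

from reference import naive_drp


class TestDiagonalProfile:
    def test_identical_series_peak_at_zero(self, rng):
        x = rng.integers(1, 4, size=60)
        prof = cr.diagonal_recurrence_profile(x, x, W=2)
        assert prof.rr[prof.lags == 0][0] == 100.0
        assert prof.maxlag == 0 and prof.maxrec == 100.0

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_shifted_copy_peaks_at_minus_shift(self, rng, k):
        # y(t) = x(t - k): series 1 leads, so the peak sits at lag -k
        x = rng.integers(1, 4, size=80)
        y = np.roll(x, k)
        prof = cr.diagonal_recurrence_profile(x[k:], y[k:], W=4)
        assert prof.maxlag == -k
        assert prof.rr[prof.lags == -k][0] == 100.0

    def test_matches_naive_loop_oracle(self, rng):
        x = rng.integers(0, 3, size=50)
        y = rng.integers(0, 3, size=50)
        prof = cr.diagonal_recurrence_profile(x, y, W=6)
        lags, rr = naive_drp(x, y, 6)
        np.testing.assert_array_equal(prof.lags, lags)
        np.testing.assert_allclose(prof.rr, rr, atol=1e-12)

    def test_exclude_nonevent_drops_joint_zeros(self, rng):
        x = rng.integers(0, 2, size=60)
        y = rng.integers(0, 2, size=60)
        prof = cr.diagonal_recurrence_profile(x, y, W=3, exclude_nonevent=0)
        lags, rr = naive_drp(x, y, 3, exclude_nonevent=0)
        np.testing.assert_allclose(prof.rr, rr, atol=1e-12)
        plain = cr.diagonal_recurrence_profile(x, y, W=3)
        assert np.all(prof.rr <= plain.rr)

    def test_profile_equals_per_diagonal_density_of_full_plot(self, rng):
        # lag l corresponds to the diagonal at offset d = -l of the matrix
        x = rng.integers(0, 3, size=40)
        y = rng.integers(0, 3, size=40)
        prof = cr.diagonal_recurrence_profile(x, y, W=5)
        R = cr.recurrence_matrix(x.astype(float), y.astype(float), radius=0.001,
                                 datatype="continuous")
        offsets = R.j_idx - R.i_idx
        for lag, rr in zip(prof.lags, prof.rr):
            d = -lag
            count = int((offsets == d).sum())
            assert rr == pytest.approx(100.0 * count / (40 - abs(d)))

    def test_lag_window_must_fit(self):
        with pytest.raises(ValidationError, match="smaller"):
            cr.diagonal_recurrence_profile([1, 2, 3], [1, 2, 3], W=3)

    def test_tie_break_prefers_small_then_negative_lags(self):
        prof = cr.DiagonalProfile(lags=np.arange(-2, 3),
                                  rr=np.array([50.0, 50.0, 10.0, 50.0, 50.0]))
        assert prof.maxlag == -1

    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 5))
    def test_sign_convention_property(self, seed, k):
        rng = np.random.default_rng(seed)
        x = rng.integers(1, 5, size=70)
        y = np.concatenate([np.full(k, -1), x[:-k]])  # y(t) = x(t-k)
        prof = cr.diagonal_recurrence_profile(x, y, W=6)
        assert prof.maxlag == -k


class TestWindowedProfile:
    def test_identical_constant_series_are_fully_recurrent(self):
        x = np.ones(40, dtype=int)
        wp = cr.windowed_diagonal_profile(x, x, window_size=10, step=5, lag_window=3)
        assert all(v == 100.0 for v in wp.values)

    def test_half_matching_half_disjoint_series(self):
        x = np.array([1] * 50 + [2] * 50)
        y = np.array([1] * 50 + [3] * 50)
        wp = cr.windowed_diagonal_profile(x, y, window_size=20, step=10, lag_window=4)
        values = dict(zip(wp.starts, wp.values))
        for s, v in values.items():
            if s + 19 <= 50:
                assert v == 100.0
            elif s > 50:
                assert v == 0.0

    def test_window_grid_and_trailing_windows_dropped(self):
        x = np.ones(25, dtype=int)
        wp = cr.windowed_diagonal_profile(x, x, window_size=10, step=4, lag_window=2)
        np.testing.assert_array_equal(wp.starts, [1, 5, 9, 13])

    def test_lag_window_must_be_smaller_than_window(self):
        x = np.ones(30, dtype=int)
        with pytest.raises(ValidationError, match="lag_window"):
            cr.windowed_diagonal_profile(x, x, window_size=10, step=5, lag_window=10)

    def test_series_shorter_than_window_rejected(self):
        x = np.ones(5, dtype=int)
        with pytest.raises(ValidationError, match="shorter"):
            cr.windowed_diagonal_profile(x, x, window_size=10, step=2, lag_window=3)


class TestWindowedCRQA:
    def test_single_window_equals_global_crqa(self, rng):
        x = rng.integers(0, 3, size=30)
        wp = cr.windowed_full_crqa(x, x, window_size=30, step=1)
        assert len(wp.values) == 1
        glob = cr.crqa(x, x).measures
        for k, v in wp.values[0].as_dict().items():
            g = getattr(glob, k)
            assert (math.isnan(v) and math.isnan(g)) or v == g

    def test_shifted_copy_is_deterministic_in_every_window(self):
        # a never-repeating ramp shifted by one: the only recurrences form
        # one unbroken diagonal, so every window is fully deterministic
        x = np.arange(100, dtype=float)
        y = x - 1.0
        wp = cr.windowed_full_crqa(x, y, window_size=30, step=10,
                                   datatype="continuous")
        for m in wp.values:
            assert m.DET == 100.0
            assert m.Lmax == 29.0

    def test_windows_are_independent(self, rng):
        x = rng.integers(0, 2, size=60)
        y = rng.integers(0, 2, size=60)
        wp = cr.windowed_full_crqa(x, y, window_size=20, step=10)
        for start, m in zip(wp.starts, wp.values):
            s = start - 1
            solo = cr.crqa(x[s:s + 20], y[s:s + 20]).measures
            for k, v in m.as_dict().items():
                g = getattr(solo, k)
                assert (math.isnan(v) and math.isnan(g)) or v == g
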