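"""Velocity, normalization and segmentation contracts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gazegan import preprocess as pp
from gazegan.errors import (DegenerateRangeError, DuplicateTimestampError,
                            FormatError, InsufficientDataError, ZeroTimeGapError)


class TestLoadGazeTable:
    def test_reads_three_rows(self, gaze_csv):
        rec = pp.load_gaze_table(gaze_csv([(0, 0, 0), (1, 3, 4), (2, 3, 4)]))
        assert len(rec) == 3
        assert rec.n_dropped == 0

    def test_drops_and_counts_nan_rows(self, gaze_csv):
        rec = pp.load_gaze_table(gaze_csv([(0, 0, 0), (1, "nan", 4), (2, 3, 4)]))
        assert len(rec) == 2
        assert rec.n_dropped == 1

    def test_single_valid_row_is_insufficient(self, gaze_csv):
        with pytest.raises(InsufficientDataError):
            pp.load_gaze_table(gaze_csv([(0, 1, 1)]))

    def test_missing_column_is_format_error(self, gaze_csv):
        path = gaze_csv([(0, 1), (1, 2)], header="time_ms,x_px")
        with pytest.raises(FormatError):
            pp.load_gaze_table(path)

    def test_duplicate_timestamps_raise(self, gaze_csv):
        with pytest.raises(DuplicateTimestampError):
            pp.load_gaze_table(gaze_csv([(0, 0, 0), (0, 1, 1), (2, 2, 2)]))

    def test_eye_filter_selects_rows(self, gaze_csv):
        path = gaze_csv([(0, 0, 0, "L"), (1, 1, 1, "R"), (2, 2, 2, "L"),
                         (3, 3, 3, "L")], header="time_ms,x_px,y_px,eye")
        rec = pp.load_gaze_table(path, eye="left")
        assert len(rec) == 3


class TestComputeVelocity:
    def test_three_four_five_triangle(self):
        rec = pp.GazeRecording([0, 1], [0, 3], [0, 4])
        assert pp.compute_velocity(rec).values == pytest.approx([5.0])

    def test_constant_position_gives_zeros(self):
        rec = pp.GazeRecording([0, 1, 2, 3], [7, 7, 7, 7], [2, 2, 2, 2])
        assert np.all(pp.compute_velocity(rec).values == 0.0)

    def test_time_gap_divides_distance(self):
        rec = pp.GazeRecording([0, 2], [0, 1], [0, 0])
        assert pp.compute_velocity(rec).values == pytest.approx([0.5])

    def test_zero_gap_raises_with_index(self):
        rec = pp.GazeRecording.__new__(pp.GazeRecording)
        rec.time = np.array([0.0, 1.0, 1.0])
        rec.x = np.zeros(3)
        rec.y = np.zeros(3)
        with pytest.raises(ZeroTimeGapError) as exc:
            pp.compute_velocity(rec)
        assert exc.value.index == 1

    def test_output_length_is_input_minus_one(self, rng):
        n = 57
        rec = pp.GazeRecording(np.arange(n), rng.normal(size=n), rng.normal(size=n))
        v = pp.compute_velocity(rec)
        assert len(v) == n - 1
        assert np.all(v.values >= 0)


class TestNormalization:
    def test_worked_example(self):
        y, params = pp.minmax_normalize(np.array([2.0, 4.0, 6.0]))
        assert y == pytest.approx([0.0, 0.5, 1.0])
        assert (params.min, params.max) == (2.0, 6.0)

    def test_unit_range_is_fixed_point(self):
        y, params = pp.minmax_normalize(np.array([0.0, 0.25, 1.0]))
        assert y == pytest.approx([0.0, 0.25, 1.0])
        assert (params.min, params.max) == (0.0, 1.0)

    def test_constant_series_raises(self):
        with pytest.raises(DegenerateRangeError):
            pp.minmax_normalize(np.array([5.0, 5.0, 5.0]))

    def test_denormalize_worked_example(self):
        params = pp.NormalizationParams(2.0, 6.0)
        assert pp.denormalize([0.0, 0.5, 1.0], params) == pytest.approx([2, 4, 6])
        assert pp.denormalize(np.zeros(4), params) == pytest.approx([2, 2, 2, 2])

    def test_round_trip_on_random_values(self, rng):
        v = rng.gamma(1.0, 2.0, size=1000)
        y, params = pp.minmax_normalize(v)
        back = pp.denormalize(y, params)
        assert np.max(np.abs(back - v)) / np.max(np.abs(v)) < 1e-12

    @given(st.lists(st.floats(0.0, 1e3), min_size=2, max_size=200).filter(
        lambda v: max(v) > min(v)))
    def test_round_trip_property(self, values):
        v = np.asarray(values)
        y, params = pp.minmax_normalize(v)
        assert y.min() >= 0.0 and y.max() <= 1.0
        assert np.allclose(pp.denormalize(y, params), v, rtol=1e-12, atol=1e-9)

    def test_apply_normalization_clips_out_of_range(self):
        params = pp.NormalizationParams(0.0, 2.0)
        out = pp.apply_normalization(np.array([-1.0, 1.0, 5.0]), params)
        assert out == pytest.approx([0.0, 0.5, 1.0])


class TestSegmentation:
    def test_exact_multiple(self, rng):
        ds = pp.segment_sequences(rng.random(1000), 200)
        assert ds.n_seq == 5 and ds.n_discarded == 0

    def test_remainder_discarded_and_reported(self, rng):
        ds = pp.segment_sequences(rng.random(450), 200)
        assert ds.n_seq == 2 and ds.n_discarded == 50

    def test_too_short_raises(self, rng):
        with pytest.raises(InsufficientDataError):
            pp.segment_sequences(rng.random(199), 200)

    @given(st.integers(10, 997), st.integers(2, 50))
    def test_segment_count_bounds(self, n, L):
        y = np.linspace(0, 1, n)
        if n < L:
            with pytest.raises(InsufficientDataError):
                pp.segment_sequences(y, L)
            return
        ds = pp.segment_sequences(y, L)
        assert ds.n_seq * L <= n < (ds.n_seq + 1) * L

    def test_pooling_concatenates(self, rng):
        a = pp.segment_sequences(rng.random(64), 16)
        b = pp.segment_sequences(rng.random(48), 16)
        pooled = pp.pool_datasets(a, b)
        assert pooled.n_seq == a.n_seq + b.n_seq
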