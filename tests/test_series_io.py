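"""Series containers, categorical coding, and delimited-text I/O."""

import json

import numpy as np
import pytest

import crossrec as cr
from crossrec.errors import DataError
from crossrec.io import (write_json, write_measures_csv, write_profile_csv,
                         write_recurrence_points)


class TestTimeSeries:
    def test_empty_series_rejected(self):
        with pytest.raises(DataError, match="at least one"):
            cr.TimeSeries(np.array([]), "continuous")

    def test_non_finite_continuous_rejected(self):
        with pytest.raises(DataError, match="non-finite"):
            cr.TimeSeries(np.array([1.0, np.nan, 2.0]), "continuous")

    def test_two_dimensional_input_rejected(self):
        with pytest.raises(DataError, match="one-dimensional"):
            cr.TimeSeries(np.zeros((3, 2)), "continuous")


class TestEncodeCategorical:
    def test_shared_alphabet_common_states_first(self):
        x, y = cr.encode_categorical(["dog", "cat", "dog"], ["cat", "fish"])
        assert x.categories == y.categories
        # "cat" is the only common state, so it takes code 0
        assert x.categories[0] == "cat"
        assert set(x.categories) == {"dog", "cat", "fish"}

    def test_coding_is_injective_and_consistent(self):
        x, y = cr.encode_categorical([1, 2, 1, 3], [3, 2, 2])
        decoded_x = [x.categories[c] for c in x.values]
        decoded_y = [y.categories[c] for c in y.values]
        assert decoded_x == [1, 2, 1, 3]
        assert decoded_y == [3, 2, 2]


class TestReadSeries:
    def test_two_column_csv_with_header(self, tmp_path):
        p = tmp_path / "pair.csv"
        p.write_text("a,b\n1.5,2.5\n3.5,4.5\n")
        x, y = cr.read_series(p, datatype="continuous")
        np.testing.assert_allclose(x.values, [1.5, 3.5])
        np.testing.assert_allclose(y.values, [2.5, 4.5])

    def test_headerless_auto_detection(self, tmp_path):
        p = tmp_path / "pair.csv"
        p.write_text("1,2\n3,4\n")
        x, y = cr.read_series(p, datatype="continuous")
        assert len(x) == 2 and len(y) == 2

    def test_categorical_strings_share_alphabet(self, tmp_path):
        p = tmp_path / "pair.csv"
        p.write_text("s1,s2\ndog,cat\ncat,dog\ndog,dog\n")
        x, y = cr.read_series(p, datatype="categorical")
        assert x.categories == y.categories
        assert (x.values == y.values).tolist() == [False, False, True]

    def test_two_single_column_files(self, tmp_path):
        p1, p2 = tmp_path / "x.csv", tmp_path / "y.csv"
        p1.write_text("1\n2\n3\n")
        p2.write_text("4\n5\n6\n")
        x, y = cr.read_series((p1, p2), datatype="continuous")
        np.testing.assert_allclose(x.values, [1, 2, 3])
        np.testing.assert_allclose(y.values, [4, 5, 6])

    def test_tab_separated_by_extension(self, tmp_path):
        p = tmp_path / "pair.tsv"
        p.write_text("1\t2\n3\t4\n")
        x, y = cr.read_series(p, datatype="continuous")
        np.testing.assert_allclose(y.values, [2, 4])

    def test_blank_cell_error_names_row_and_column(self, tmp_path):
        p = tmp_path / "pair.csv"
        p.write_text("a,b\n1,2\n,4\n")
        with pytest.raises(DataError, match=r"row 3, column 1"):
            cr.read_series(p, datatype="continuous")

    def test_non_numeric_continuous_cell_rejected(self, tmp_path):
        p = tmp_path / "pair.csv"
        p.write_text("1,2\n3,oops\n")
        with pytest.raises(DataError, match="non-numeric"):
            cr.read_series(p, datatype="continuous")

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(DataError, match="not found"):
            cr.read_series(tmp_path / "nope.csv")

    def test_round_trip_preserves_values(self, tmp_path):
        c, s = cr.simulate_coupled_binary(cr.SimParams(seed=7, steps=100))
        p = tmp_path / "sim.csv"
        p.write_text("C,S\n" + "\n".join(f"{a},{b}" for a, b in
                                         zip(c.values, s.values)) + "\n")
        x, y = cr.read_series(p, datatype="categorical")
        decoded_x = np.array([x.categories[v] for v in x.values])
        decoded_y = np.array([y.categories[v] for v in y.values])
        np.testing.assert_array_equal(decoded_x, c.values)
        np.testing.assert_array_equal(decoded_y, s.values)


class TestWriters:
    def test_measures_csv_fixed_column_order(self, tmp_path):
        res = cr.crqa([0, 1, 0], [0, 0, 1], radius=0.5, datatype="continuous")
        p = tmp_path / "m.csv"
        write_measures_csv(res.measures, p)
        header = p.read_text().splitlines()[0]
        assert header == "RR,DET,L,Lmax,ENTR,LAM,TT"

    def test_profile_csv_and_sidecar(self, tmp_path):
        prof = cr.diagonal_recurrence_profile([1, 2, 1, 2], [1, 2, 1, 2], W=1)
        write_profile_csv(prof, tmp_path / "p.csv", tmp_path / "p.json")
        rows = (tmp_path / "p.csv").read_text().splitlines()
        assert rows[0] == "lag,rr"
        side = json.loads((tmp_path / "p.json").read_text())
        assert side["maxlag"] == 0 and side["maxrec"] == 100.0
        assert side["provenance"]["package"] == "crossrec"

    def test_recurrence_point_export_is_one_based(self, tmp_path):
        R = cr.recurrence_matrix([1, 2], [1, 2], datatype="continuous")
        write_recurrence_points(R, tmp_path / "r.csv", tmp_path / "r.json")
        rows = (tmp_path / "r.csv").read_text().splitlines()
        assert rows[0] == "i,j"
        assert "1,1" in rows and "2,2" in rows
        side = json.loads((tmp_path / "r.json").read_text())
        assert side["n1"] == 2 and side["theiler_window"] == 0

    def test_json_writer_maps_nan_to_null(self, tmp_path):
        write_json({"v": float("nan")}, tmp_path / "x.json")
        assert json.loads((tmp_path / "x.json").read_text())["v"] is None
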