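"""Delimited-text readers and result writers.

Input: CSV/TSV with one column per series (or two single-column files);
header row optional ("auto" treats a non-numeric first row as a header).
Missing values are rejected with the offending row and column named.

Output: flat JSON and small CSVs.  Measures use the fixed column order
RR,DET,L,Lmax,ENTR,LAM,TT; sparse recurrence exports are two-column
(i, j) CSVs, 1-based, with a JSON sidecar recording dimensions and
parameters.  Every JSON result carries a provenance block (package
version, parameters, seed) so an output file is self-describing.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .categorical import ContingencyStack, PhiProfile
from .embedding import RecurrenceMatrix
from .errors import DataError, ValidationError
from .measures import MEASURE_ORDER, RQAMeasures
from .profiles import DiagonalProfile, WindowedProfile
from .series import TimeSeries, encode_categorical

__all__ = ["read_series", "provenance", "write_json", "write_measures_csv",
           "write_profile_csv", "write_windowed_csv", "write_recurrence_points",
           "write_contingency_csv", "write_phi_csv"]


def _read_columns(path, sep, header) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, header=None, dtype=str,
                         keep_default_na=False, skip_blank_lines=False)
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise DataError(f"could not parse {path}: {e}") from e
    if df.empty:
        raise DataError(f"empty input file: {path}")
    if header == "auto":
        first = df.iloc[0]
        header = not all(_is_number(v) for v in first)
    if header:
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            raise DataError(f"no data rows below the header in {path}")
    return df, bool(header)


def _is_number(v: str) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def _check_missing(col: pd.Series, path, col_idx: int, offset: int) -> None:
    blank = col.str.strip() == ""
    if blank.any():
        row = int(np.flatnonzero(blank.to_numpy())[0])
        raise DataError(
            f"missing value at row {row + 1 + offset}, column {col_idx + 1} in {path}"
        )


def read_series(paths, datatype: str = "continuous", columns=None,
                header="auto", sep=None) -> tuple[TimeSeries, TimeSeries]:
    """Read a pair of series from one two-column file or two files.

    Parameters
    ----------
    paths
        A single path (two columns expected) or a pair of paths (one
        column each).
    datatype
        "continuous" (cells must be numeric) or "categorical" (cells are
        state labels, integer-coded over a shared alphabet).
    columns
        Column indices to use, 0-based: a pair for a single file,
        one index per file otherwise.  Defaults to the first column(s).
    header
        True / False / "auto" (non-numeric first row treated as header).
    sep
        Field delimiter; by default "," (or a tab for .tsv/.tab files).
    """
    if isinstance(paths, (str, Path)):
        df, had_header = _read_columns(paths, sep, header)
        c0, c1 = columns if columns is not None else (0, 1)
        if df.shape[1] <= max(c0, c1):
            raise DataError(
                f"{paths} has {df.shape[1]} column(s); columns {c0} and {c1} requested"
            )
        raw = [(df.iloc[:, c0], paths, c0, had_header),
               (df.iloc[:, c1], paths, c1, had_header)]
    else:
        p1, p2 = paths
        cols = columns if columns is not None else (0, 0)
        raw = []
        for p, c in zip((p1, p2), cols):
            df, had_header = _read_columns(p, sep, header)
            if df.shape[1] <= c:
                raise DataError(f"{p} has {df.shape[1]} column(s); column {c} requested")
            raw.append((df.iloc[:, c], p, c, had_header))
    for col, p, c, had_header in raw:
        _check_missing(col, p, c, 1 if had_header else 0)
    if datatype == "continuous":
        series = []
        for col, p, c, had_header in raw:
            bad = ~col.map(_is_number)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise DataError(
                    f"non-numeric value {col.iloc[row]!r} at row "
                    f"{row + 1 + (1 if had_header else 0)}, column {c + 1} in {p}"
                )
            series.append(TimeSeries(col.astype(float).to_numpy(), "continuous"))
        return series[0], series[1]
    if datatype != "categorical":
        raise ValidationError(f"unknown datatype {datatype!r}")
    labels = [col.to_numpy() for col, _, _, _ in raw]
    # numeric-looking labels are normalized so "1" and "1.0" coincide
    labels = [np.array([_norm_label(v) for v in col], dtype=object) for col in labels]
    return encode_categorical(labels[0], labels[1])


def _norm_label(v: str):
    try:
        f = float(v)
        return int(f) if f.is_integer() else f
    except (TypeError, ValueError):
        return v


# --------------------------------------------------------------------------
# writers

def provenance(params: dict | None = None, seed=None) -> dict:
    from . import __version__
    block = {"package": "crossrec", "version": __version__}
    if params:
        block["parameters"] = params
    if seed is not None:
        block["seed"] = seed
    return block


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f  # JSON has no NaN
    return obj


def write_json(result: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(result), indent=2) + "\n")


def write_measures_csv(m: RQAMeasures, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(MEASURE_ORDER)
        w.writerow([getattr(m, k) for k in MEASURE_ORDER])


def write_profile_csv(profile: DiagonalProfile, path, json_path=None, params=None) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["lag", "rr"])
        for lag, rr in zip(profile.lags, profile.rr):
            w.writerow([int(lag), float(rr)])
    if json_path is not None:
        write_json({"maxrec": profile.maxrec, "maxlag": profile.maxlag,
                    "provenance": provenance(params)}, json_path)


def write_windowed_csv(wp: WindowedProfile, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if wp.values and isinstance(wp.values[0], RQAMeasures):
            w.writerow(["window_start", *MEASURE_ORDER])
            for s, m in zip(wp.starts, wp.values):
                w.writerow([int(s), *[getattr(m, k) for k in MEASURE_ORDER]])
        else:
            w.writerow(["window_start", "rr"])
            for s, v in zip(wp.starts, wp.values):
                w.writerow([int(s), float(v)])


def write_recurrence_points(R: RecurrenceMatrix, csv_path, json_path=None,
                            params=None) -> None:
    pts = R.points()
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["i", "j"])
        for i, j in pts:
            w.writerow([int(i), int(j)])
    if json_path is not None:
        write_json({"n1": R.n1, "n2": R.n2, "theiler_window": R.theiler_window,
                    "n_recurrent": R.count, "provenance": provenance(params)}, json_path)


def write_contingency_csv(stack: ContingencyStack, path) -> None:
    """Long format: one row per (lag, state_i, state_j) cell."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["lag", "state_i", "state_j", "count"])
        for lag, ct in zip(stack.lags, stack.tables):
            for a, si in zip(stack.all_states, ct):
                for b, cnt in zip(stack.all_states, si):
                    w.writerow([int(lag), a, b, int(cnt)])


def write_phi_csv(pp: PhiProfile, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["lag", "phi"])
        for lag, phi in zip(pp.lags, pp.phi):
            w.writerow([int(lag), "" if math.isnan(phi) else float(phi)])
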