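"""Line structures and the seven recurrence measures.

From a recurrence plot, diagonal lines (contiguous recurrent points along
a fixed offset j - i) index sequences of revisited trajectory regions,
and vertical lines index dwelling of one system while the other stays
within reach.  The seven scalar measures:

RR    recurrence rate: point density of the plot, in percent
DET   percent of recurrent points on diagonal lines of length >= minline
L     mean length of those qualifying diagonal lines
Lmax  length of the longest qualifying diagonal line
ENTR  Shannon entropy (nats) of the qualifying diagonal length distribution
LAM   percent of recurrent points on vertical lines of length >= minline
TT    trapping time: mean length of qualifying vertical lines

When no line qualifies, the percentage/entropy measures are 0 and the
mean/max lengths are NaN (never silently 0, so downstream averages cannot
be diluted by degenerate windows).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .embedding import RecurrenceMatrix
from .errors import ValidationError

__all__ = ["LineHistogram", "RQAMeasures", "extract_lines", "compute_rqa_measures"]

MEASURE_ORDER = ("RR", "DET", "L", "Lmax", "ENTR", "LAM", "TT")


@dataclass(frozen=True)
class LineHistogram:
    """Counts of maximal contiguous runs, keyed by run length."""

    kind: str  # "diagonal" | "vertical"
    counts: dict[int, int]

    @property
    def total_points(self) -> int:
        return sum(l * c for l, c in self.counts.items())

    def qualifying(self, minline: int) -> dict[int, int]:
        return {l: c for l, c in self.counts.items() if l >= minline}


@dataclass(frozen=True)
class RQAMeasures:
    RR: float
    DET: float
    L: float
    Lmax: float
    ENTR: float
    LAM: float
    TT: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in MEASURE_ORDER}

    @classmethod
    def nan(cls) -> "RQAMeasures":
        return cls(*([float("nan")] * 7))


def extract_lines(R: RecurrenceMatrix, kind: str) -> LineHistogram:
    """Histogram of maximal contiguous runs, diagonal or vertical.

    Diagonal runs are consecutive points along a fixed offset d = j - i.
    Vertical runs are consecutive series-1 indices i at a fixed series-2
    index j (dwelling of series 1 near one moment of series 2).  Runs are
    maximal: they cannot be extended by a neighbouring recurrent point.
    """
    if kind not in ("diagonal", "vertical"):
        raise ValidationError(f"unknown line kind {kind!r}")
    if R.count == 0:
        return LineHistogram(kind, {})
    if kind == "diagonal":
        key = R.j_idx - R.i_idx
    else:
        key = R.j_idx
    pos = R.i_idx
    order = np.lexsort((pos, key))
    k, p = key[order], pos[order]
    new_run = np.ones(k.size, dtype=bool)
    new_run[1:] = (k[1:] != k[:-1]) | (p[1:] != p[:-1] + 1)
    starts = np.flatnonzero(new_run)
    lengths = np.diff(np.append(starts, k.size))
    return LineHistogram(kind, dict(Counter(lengths.tolist())))


def _line_stats(hist: LineHistogram, minline: int, n_points: int):
    """(percentage on qualifying lines, mean length, max length, entropy)."""
    q = hist.qualifying(minline)
    if not q or n_points == 0:
        return 0.0, float("nan"), float("nan"), 0.0
    pts = sum(l * c for l, c in q.items())
    n_runs = sum(q.values())
    pct = 100.0 * pts / n_points
    mean_len = pts / n_runs
    max_len = float(max(q))
    probs = [c / n_runs for c in q.values()]
    entr = -sum(p * math.log(p) for p in probs)
    return pct, mean_len, max_len, entr


def compute_rqa_measures(R: RecurrenceMatrix, minline: int = 2) -> RQAMeasures:
    """The seven measures of a (Theiler-masked) recurrence matrix.

    RR uses the full matrix area n1*n2 as denominator (Theiler-masked
    cells simply count as non-recurrent).  An empty matrix yields RR = 0
    and NaN/0 line measures, never an exception.
    """
    if minline < 1:
        raise ValidationError("minline must be >= 1")
    n_points = R.count
    rr = 100.0 * n_points / (R.n1 * R.n2)
    det, l_mean, l_max, entr = _line_stats(extract_lines(R, "diagonal"), minline, n_points)
    lam, tt, _vmax, _ventr = _line_stats(extract_lines(R, "vertical"), minline, n_points)
    return RQAMeasures(RR=rr, DET=det, L=l_mean, Lmax=l_max, ENTR=entr, LAM=lam, TT=tt)
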