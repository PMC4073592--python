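"""Time-delay embedding, cross-distance matrices and recurrence thresholding.

A scalar series X(t) is unfolded into delay coordinates
(X(t), X(t+tau), ..., X(t+(m-1)tau)); two embedded trajectories are then
compared point against point with the Euclidean metric, and index pairs
whose distance falls within a radius are marked recurrent.  The result is
kept as a sparse coordinate set: recurrence plots of behavioural data are
typically only a few percent dense, and every downstream quantity (line
histograms, diagonal profiles) is computable directly from coordinates.

Index convention: recurrent points are exposed 1-based as (i, j), with i
indexing series 1 (horizontal axis of a plotted recurrence plot) and j
indexing series 2 (vertical axis).  A point at j = i + 1 therefore sits
one diagonal *above* the line of coincidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InsufficientLengthError, ValidationError
from .series import TimeSeries, as_timeseries, zscore

__all__ = [
    "EmbeddingConfig",
    "EmbeddedSeries",
    "RecurrenceMatrix",
    "embed_series",
    "cross_distance_matrix",
    "threshold_to_recurrence",
    "apply_theiler_window",
]

#: matrices at most this size on a side may be materialized densely
DENSE_GUARD = 4000


@dataclass(frozen=True)
class EmbeddingConfig:
    """Parameters of the embed -> distance -> threshold pipeline.

    delay and dim are in samples / counts; radius is in the units of the
    (possibly rescaled) distance matrix.  ``normalize="zscore"``
    standardizes each series before embedding (sensible for continuous
    data only).  ``rescale`` divides the distance matrix by its mean or
    maximum and expresses it as a percentage, so the radius becomes a
    percentage of the typical (or maximal) distance.
    """

    delay: int = 1
    dim: int = 1
    radius: float = 0.001
    normalize: str = "none"  # none | zscore
    rescale: str = "none"  # none | mean | max

    def __post_init__(self) -> None:
        if self.delay < 1:
            raise ValidationError("delay must be >= 1")
        if self.dim < 1:
            raise ValidationError("embedding dimension must be >= 1")
        if self.radius < 0:
            raise ValidationError("radius must be >= 0")
        if self.normalize not in ("none", "zscore"):
            raise ValidationError(f"unknown normalize mode {self.normalize!r}")
        if self.rescale not in ("none", "mean", "max"):
            raise ValidationError(f"unknown rescale mode {self.rescale!r}")


@dataclass(frozen=True)
class EmbeddedSeries:
    """A series unfolded into delay coordinates.

    ``points`` has shape (n_rows, dim) with n_rows = T - (dim-1)*delay;
    column k holds X(t + k*delay).
    """

    points: np.ndarray
    source_length: int
    delay: int
    dim: int

    @property
    def n_rows(self) -> int:
        return self.points.shape[0]


@dataclass
class RecurrenceMatrix:
    """Sparse set of recurrent (i, j) index pairs.

    ``n1`` counts the points of series 1 (index i), ``n2`` those of
    series 2 (index j).  ``i_idx``/``j_idx`` are 0-based internally;
    :meth:`points` exposes the 1-based pairs.  ``theiler_window`` records
    the Theiler exclusion already applied (0 = none).
    """

    n1: int
    n2: int
    i_idx: np.ndarray
    j_idx: np.ndarray
    theiler_window: int = 0

    def __post_init__(self) -> None:
        self.i_idx = np.asarray(self.i_idx, dtype=np.int64)
        self.j_idx = np.asarray(self.j_idx, dtype=np.int64)
        if self.i_idx.shape != self.j_idx.shape:
            raise ValidationError("i/j coordinate arrays must have equal length")
        if self.i_idx.size:
            if self.i_idx.min() < 0 or self.i_idx.max() >= self.n1:
                raise ValidationError("recurrent point index i out of bounds")
            if self.j_idx.min() < 0 or self.j_idx.max() >= self.n2:
                raise ValidationError("recurrent point index j out of bounds")

    @property
    def count(self) -> int:
        return int(self.i_idx.size)

    @property
    def recurrence_rate(self) -> float:
        """Point density as a percentage of the full matrix area."""
        return 100.0 * self.count / (self.n1 * self.n2)

    def points(self) -> np.ndarray:
        """Recurrent pairs as an (n, 2) array of 1-based (i, j)."""
        return np.column_stack([self.i_idx + 1, self.j_idx + 1])

    def to_dense(self, guard: int = DENSE_GUARD) -> np.ndarray:
        """Materialize as a dense boolean array of shape (n1, n2)."""
        if self.n1 > guard or self.n2 > guard:
            raise ValidationError(
                f"refusing to densify a {self.n1}x{self.n2} matrix (guard {guard})"
            )
        dense = np.zeros((self.n1, self.n2), dtype=bool)
        dense[self.i_idx, self.j_idx] = True
        return dense

    def transpose(self) -> "RecurrenceMatrix":
        return RecurrenceMatrix(self.n2, self.n1, self.j_idx.copy(), self.i_idx.copy(),
                                self.theiler_window)


def embed_series(x, delay: int, dim: int, normalize: str = "none",
                 datatype: str = "continuous") -> EmbeddedSeries:
    """Unfold a series into (T - (dim-1)*delay) rows of delay coordinates."""
    ts = as_timeseries(x, datatype)
    if delay < 1 or dim < 1:
        raise ValidationError("delay and dim must be >= 1")
    v = ts.values.astype(float)
    if normalize == "zscore":
        v = zscore(v)
    elif normalize != "none":
        raise ValidationError(f"unknown normalize mode {normalize!r}")
    T = v.size
    min_len = (dim - 1) * delay + 1
    if T < min_len:
        raise InsufficientLengthError(
            f"insufficient length: series of length {T} cannot be embedded with "
            f"delay {delay} and dimension {dim} (minimum length {min_len})"
        )
    n_rows = T - (dim - 1) * delay
    cols = [v[k * delay: k * delay + n_rows] for k in range(dim)]
    return EmbeddedSeries(np.column_stack(cols), T, delay, dim)


def cross_distance_matrix(a: EmbeddedSeries, b: EmbeddedSeries,
                          rescale: str = "none") -> np.ndarray:
    """Euclidean distances between every pair of embedded points.

    D[i, j] is the distance between a.points[i] and b.points[j].  With
    ``rescale="mean"`` (or ``"max"``) every entry is divided by the mean
    (max) of D and expressed as a percentage.
    """
    if a.dim != b.dim:
        raise ValidationError(
            f"mismatched embedding dimensions: {a.dim} vs {b.dim}"
        )
    D = cdist(a.points, b.points, metric="euclidean")
    if rescale == "mean":
        D = 100.0 * D / D.mean()
    elif rescale == "max":
        D = 100.0 * D / D.max()
    elif rescale != "none":
        raise ValidationError(f"unknown rescale mode {rescale!r}")
    return D


def threshold_to_recurrence(D: np.ndarray, radius: float) -> RecurrenceMatrix:
    """Mark (i, j) recurrent wherever D[i, j] <= radius."""
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    D = np.asarray(D)
    i_idx, j_idx = np.nonzero(D <= radius)
    return RecurrenceMatrix(D.shape[0], D.shape[1], i_idx, j_idx, theiler_window=0)


def apply_theiler_window(R: RecurrenceMatrix, tw: int) -> RecurrenceMatrix:
    """Remove the band of diagonals |j - i| <= tw - 1 around the LOC.

    tw = 0 is the identity (the cross-recurrence default, since two
    different series are legitimately synced along the main diagonal);
    tw = 1 removes exactly the main diagonal.  Requires a square matrix
    for tw >= 1 (the LOC is only meaningful there).
    """
    if tw < 0:
        raise ValidationError("Theiler window must be >= 0")
    if tw == 0:
        return RecurrenceMatrix(R.n1, R.n2, R.i_idx.copy(), R.j_idx.copy(), 0)
    if R.n1 != R.n2:
        raise ValidationError("Theiler window >= 1 requires a square recurrence matrix")
    if tw >= R.n1:
        raise ValidationError(
            f"Theiler window {tw} removes every diagonal of a {R.n1}x{R.n1} matrix"
        )
    keep = np.abs(R.j_idx - R.i_idx) > tw - 1
    return RecurrenceMatrix(R.n1, R.n2, R.i_idx[keep], R.j_idx[keep], tw)
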