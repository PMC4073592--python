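"""Time-series containers and categorical coding.

A :class:`TimeSeries` wraps a one-dimensional array together with its
datatype.  Continuous series hold real values (no NaN/Inf allowed);
categorical series hold small non-negative integer codes obtained by
mapping the original labels (strings, integers, ...) injectively onto
consecutive integers.  When two categorical series are analysed together
the mapping must be *shared*, so that equal codes mean equal states
across the pair — :func:`encode_categorical` builds that shared alphabet,
putting the states common to both series first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError, ValidationError

__all__ = ["TimeSeries", "as_timeseries", "encode_categorical", "zscore"]


@dataclass(frozen=True)
class TimeSeries:
    """An ordered univariate series, either continuous or categorical.

    Parameters
    ----------
    values
        1-D array.  Continuous: floats, all finite.  Categorical: integer
        codes into ``categories``.
    datatype
        ``"continuous"`` or ``"categorical"``.
    categories
        For categorical series, the original labels; ``categories[code]``
        recovers the label.  ``None`` for continuous series.
    """

    values: np.ndarray
    datatype: str = "continuous"
    categories: tuple | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 1:
            raise DataError(f"series must be one-dimensional, got shape {v.shape}")
        if v.size < 1:
            raise DataError("series must contain at least one sample")
        if self.datatype == "continuous":
            v = v.astype(float)
            if not np.all(np.isfinite(v)):
                bad = int(np.flatnonzero(~np.isfinite(v))[0])
                raise DataError(f"continuous series contains a non-finite value at index {bad}")
        elif self.datatype == "categorical":
            if not np.issubdtype(np.asarray(v).dtype, np.integer):
                v = v.astype(np.int64)
        else:
            raise ValidationError(f"unknown datatype {self.datatype!r}")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def length(self) -> int:
        return len(self)


def as_timeseries(obj, datatype: str = "continuous") -> TimeSeries:
    """Coerce an array-like (or pass through a TimeSeries) to :class:`TimeSeries`."""
    if isinstance(obj, TimeSeries):
        return obj
    arr = np.asarray(obj)
    if datatype == "categorical" and not np.issubdtype(arr.dtype, np.integer):
        x, _ = encode_categorical(arr, arr)
        return x
    return TimeSeries(arr, datatype=datatype)


def encode_categorical(x: Sequence, y: Sequence) -> tuple[TimeSeries, TimeSeries]:
    """Integer-code two label sequences over a shared alphabet.

    States present in *both* series are assigned the first consecutive
    codes (in order of first appearance scanning ``x`` then ``y``),
    followed by the states unique to either series.  The shared coding
    makes "same code" mean "same state" across the pair, which is what
    near-zero-radius recurrence on categorical data relies on.
    """
    xa = [_hashable(v) for v in np.asarray(x, dtype=object)]
    ya = [_hashable(v) for v in np.asarray(y, dtype=object)]
    seen: dict = {}
    for v in xa + ya:
        if v not in seen:
            seen[v] = len(seen)
    sx, sy = set(xa), set(ya)
    common = [v for v in seen if v in sx and v in sy]
    rest = [v for v in seen if v not in common]
    alphabet = common + rest
    code = {v: i for i, v in enumerate(alphabet)}
    cats = tuple(alphabet)
    tsx = TimeSeries(np.array([code[v] for v in xa], dtype=np.int64), "categorical", cats)
    tsy = TimeSeries(np.array([code[v] for v in ya], dtype=np.int64), "categorical", cats)
    return tsx, tsy


def _hashable(v):
    # numpy scalars hash like their python counterparts; unwrap for stable keys
    return v.item() if isinstance(v, np.generic) else v


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardize to zero mean / unit (population) standard deviation."""
    v = np.asarray(values, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValidationError("zero variance: cannot z-score a constant series")
    return (v - v.mean()) / sd
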