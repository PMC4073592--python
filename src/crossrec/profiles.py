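"""Diagonal-wise recurrence profiles and windowed recurrence.

The diagonal-wise recurrence profile (DRP) measures, for each lag l in
[-W, +W], how often the two systems co-visit the same state when one is
shifted by l samples: rr(l) compares x(t) against y(t - l).  Under this
sign convention a *negative* lag means series 1 leads series 2 (if
y(t) = x(t - k) exactly, the profile peaks at lag -k), and lag l
corresponds to the diagonal at offset d = j - i = -l of the full
recurrence matrix.  The per-lag denominator is the number of valid
comparisons (T - |l|), so edge lags are not artificially deflated.

The windowed variants slide a window along the overlap of the two series
and either average the DRP over a small lag band per window (a coarse
time course of coupling) or run the full measure set per window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CrossRecError, ValidationError
from .measures import RQAMeasures
from .pipeline import crqa
from .series import TimeSeries, as_timeseries, zscore

__all__ = [
    "DiagonalProfile",
    "WindowedProfile",
    "diagonal_recurrence_profile",
    "windowed_diagonal_profile",
    "windowed_full_crqa",
]


@dataclass(frozen=True)
class DiagonalProfile:
    """Per-lag recurrence rates over lags -W..+W (percentages)."""

    lags: np.ndarray
    rr: np.ndarray

    @property
    def maxrec(self) -> float:
        return float(self.rr[self._argmax()])

    @property
    def maxlag(self) -> int:
        return int(self.lags[self._argmax()])

    def _argmax(self) -> int:
        # ties: smallest |lag| wins; if still tied, the negative lag
        order = sorted(range(len(self.lags)),
                       key=lambda k: (-self.rr[k], abs(self.lags[k]), self.lags[k]))
        return order[0]


@dataclass(frozen=True)
class WindowedProfile:
    """Per-window values over window start indices (1-based starts)."""

    window_size: int
    step: int
    lag_window: int
    starts: np.ndarray
    values: list  # float per window (windowed DRP) or RQAMeasures per window


def _prepare_pair(x, y, datatype, normalize):
    if (datatype == "categorical"
            and not isinstance(x, TimeSeries) and not isinstance(y, TimeSeries)
            and not (np.issubdtype(np.asarray(x).dtype, np.number)
                     and np.issubdtype(np.asarray(y).dtype, np.number))):
        # raw label sequences: integer-code them over a *shared* alphabet
        from .series import encode_categorical
        tx, ty = encode_categorical(x, y)
    else:
        tx = as_timeseries(x, datatype)
        ty = as_timeseries(y, datatype)
    n = min(len(tx), len(ty))  # profiles run on the overlap of the two series
    vx = tx.values[:n].astype(float)
    vy = ty.values[:n].astype(float)
    if normalize == "zscore":
        vx, vy = zscore(vx), zscore(vy)
    elif normalize != "none":
        raise ValidationError(f"unknown normalize mode {normalize!r}")
    return vx, vy, n


def diagonal_recurrence_profile(x, y, W: int, radius: float = 0.001, delay: int = 1,
                                embed: int = 1, normalize: str = "none",
                                exclude_nonevent=None,
                                datatype: str = "categorical") -> DiagonalProfile:
    """Recurrence rate per lag in [-W, +W] (the drpdfromts analysis).

    For categorical series the radius should stay near 0 (e.g. 0.001) so
    that only identical state codes recur.  ``exclude_nonevent`` names a
    state (e.g. 0 for binary event series) whose simultaneous occurrence
    in both series is dropped from the numerator: matches of the
    non-event then do not count as recurrence, while the denominator
    remains the number of valid comparisons per lag.
    """
    vx, vy, n = _prepare_pair(x, y, datatype, normalize)
    if W >= n:
        raise ValidationError(f"lag window W={W} must be smaller than the series overlap {n}")
    if W < 0:
        raise ValidationError("lag window W must be >= 0")
    # delay-embed both series; lag comparisons run over embedded rows
    from .embedding import embed_series
    A = embed_series(vx, delay, embed).points
    B = embed_series(vy, delay, embed).points
    m = min(A.shape[0], B.shape[0])
    A, B = A[:m], B[:m]
    if W >= m:
        raise ValidationError(f"lag window W={W} too large for embedded length {m}")
    lags = np.arange(-W, W + 1)
    rr = np.empty(lags.size)
    for idx, lag in enumerate(lags):
        if lag >= 0:
            xa, yb = A[lag:m], B[0:m - lag]
        else:
            xa, yb = A[0:m + lag], B[-lag:m]
        d = np.sqrt(((xa - yb) ** 2).sum(axis=1))
        rec = d <= radius
        if exclude_nonevent is not None:
            both_nonevent = (xa[:, 0] == exclude_nonevent) & (yb[:, 0] == exclude_nonevent)
            rec = rec & ~both_nonevent
        rr[idx] = 100.0 * rec.sum() / (m - abs(lag))
    return DiagonalProfile(lags=lags, rr=rr)


def windowed_diagonal_profile(x, y, window_size: int, step: int, lag_window: int,
                              radius: float = 0.001, delay: int = 1, embed: int = 1,
                              normalize: str = "none", exclude_nonevent=None,
                              datatype: str = "categorical") -> WindowedProfile:
    """Mean diagonal recurrence in overlapping windows (the windowdrp analysis).

    In each window the diagonal profile over lags [-lag_window, +lag_window]
    is computed and averaged over lags, giving one coupling value per
    window.  Windows advance by ``step`` from the start of the overlap;
    trailing partial windows are dropped.
    """
    if step < 1:
        raise ValidationError("step must be >= 1")
    if lag_window >= window_size:
        raise ValidationError(
            "lag_window must be smaller than window_size: within a window, the profile "
            "can only be computed for lags smaller than the window itself"
        )
    vx, vy, n = _prepare_pair(x, y, datatype, normalize)
    if n < window_size:
        raise ValidationError(f"series overlap {n} is shorter than window_size {window_size}")
    starts0 = np.arange(0, n - window_size + 1, step)
    values = []
    for s in starts0:
        prof = diagonal_recurrence_profile(
            vx[s:s + window_size], vy[s:s + window_size], W=lag_window, radius=radius,
            delay=delay, embed=embed, normalize="none",
            exclude_nonevent=exclude_nonevent, datatype="continuous")
        values.append(float(prof.rr.mean()))
    return WindowedProfile(window_size, step, lag_window, starts0 + 1, values)


def windowed_full_crqa(x, y, window_size: int, step: int, minline: int = 2,
                       radius: float = 0.001, delay: int = 1, embed: int = 1, tw: int = 0,
                       normalize: str = "none",
                       datatype: str = "categorical") -> WindowedProfile:
    """Full recurrence measures per overlapping window (the wincrqa analysis).

    Degenerate windows (e.g. too short for the embedding) yield all-NaN
    measures rather than aborting the sweep.
    """
    if step < 1:
        raise ValidationError("step must be >= 1")
    vx, vy, n = _prepare_pair(x, y, datatype, normalize)
    if n < window_size:
        raise ValidationError(f"series overlap {n} is shorter than window_size {window_size}")
    starts0 = np.arange(0, n - window_size + 1, step)
    values: list[RQAMeasures] = []
    for s in starts0:
        try:
            res = crqa(vx[s:s + window_size], vy[s:s + window_size], delay=delay,
                       embed=embed, radius=radius, tw=tw, minline=minline,
                       normalize="none", datatype="continuous")
            values.append(res.measures)
        except CrossRecError:
            values.append(RQAMeasures.nan())
    return WindowedProfile(window_size, step, 0, starts0 + 1, values)
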