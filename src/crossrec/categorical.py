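"""Contingency-table recurrence for categorical sequences.

For two event series x, y over a shared state alphabet, the lag-l
contingency table CT_l counts co-occurrences: CT_l[a, b] is the number of
valid time points t with x(t) = a and y(t - l) = b (the same sign
convention as the diagonal profiles: negative l means series 1 leads).
The recurrence rate at lag l is the diagonal mass of CT_l over the states
*common* to both series, divided by the table total — identical, lag by
lag, to the diagonal-wise recurrence profile at near-zero radius, but the
table keeps the full state-by-state co-occurrence structure, bridging to
lag-sequential analysis.

Tables are built over the union alphabet so that each per-lag total
equals the number of valid comparisons (T - |l|); states present in only
one series contribute off-diagonal ("not-k") mass but never recurrence.

phi(k) collapses each table to 2x2 over {k, not-k} and applies the
Pearson phi coefficient: it grows with matched visits to k (and matched
avoidance of k) and shrinks with mismatches, per lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .profiles import DiagonalProfile
from .series import TimeSeries, as_timeseries, encode_categorical

__all__ = ["ContingencyStack", "PhiProfile", "build_contingency_stack",
           "rr_from_contingency", "phi_profile"]


@dataclass(frozen=True)
class ContingencyStack:
    """Per-lag state-by-state co-occurrence tables.

    ``tables[k]`` is the table at ``lags[k]``, indexed by ``all_states``
    on both axes (rows: series-1 state, columns: series-2 state).
    ``common_states`` lists the states shared by both series; their
    diagonal cells define recurrence.  States are reported as original
    labels when known, integer codes otherwise.
    """

    all_states: tuple
    common_states: tuple
    lags: np.ndarray
    tables: list[np.ndarray]

    def common_table(self, lag: int) -> np.ndarray:
        """The S x S sub-table restricted to the common states."""
        k = int(np.flatnonzero(self.lags == lag)[0])
        idx = [self.all_states.index(s) for s in self.common_states]
        return self.tables[k][np.ix_(idx, idx)]


@dataclass(frozen=True)
class PhiProfile:
    """Per-lag 2x2 phi association with one state k versus the rest."""

    state: object
    lags: np.ndarray
    phi: np.ndarray
    n_undefined: int  # lags where a zero margin left phi undefined (NaN)


def _coerce_pair(x, y) -> tuple[TimeSeries, TimeSeries]:
    if isinstance(x, TimeSeries) and isinstance(y, TimeSeries):
        if x.datatype != "categorical" or y.datatype != "categorical":
            raise ValidationError("contingency recurrence requires categorical series")
        return x, y
    return encode_categorical(np.asarray(x), np.asarray(y))


def build_contingency_stack(x, y, W: int) -> ContingencyStack:
    """Co-occurrence tables for every lag in [-W, +W]."""
    tx, ty = _coerce_pair(x, y)
    n = min(len(tx), len(ty))
    vx = tx.values[:n]
    vy = ty.values[:n]
    if W < 0 or W >= n:
        raise ValidationError(f"lag window W={W} must be in [0, {n - 1}]")
    codes = np.union1d(np.unique(vx), np.unique(vy))
    common_codes = np.intersect1d(np.unique(vx), np.unique(vy))
    if common_codes.size == 0:
        ax = sorted(_labels(tx, np.unique(vx)))
        ay = sorted(_labels(ty, np.unique(vy)))
        raise ValidationError(
            f"the two series share no states: series 1 uses {ax}, series 2 uses {ay}"
        )
    U = codes.size
    remap = {c: k for k, c in enumerate(codes.tolist())}
    rx = np.array([remap[c] for c in vx.tolist()])
    ry = np.array([remap[c] for c in vy.tolist()])
    lags = np.arange(-W, W + 1)
    tables = []
    for lag in lags:
        if lag >= 0:
            xa, yb = rx[lag:n], ry[0:n - lag]
        else:
            xa, yb = rx[0:n + lag], ry[-lag:n]
        flat = np.bincount(xa * U + yb, minlength=U * U)
        tables.append(flat.reshape(U, U))
    return ContingencyStack(
        all_states=tuple(_labels(tx, codes)),
        common_states=tuple(_labels(tx, common_codes)),
        lags=lags,
        tables=tables,
    )


def _labels(ts: TimeSeries, codes: np.ndarray):
    if ts.categories is not None:
        return [ts.categories[int(c)] for c in codes]
    return [int(c) for c in codes]


def rr_from_contingency(stack: ContingencyStack) -> DiagonalProfile:
    """Recurrence per lag: common-state diagonal mass over table total."""
    idx = np.array([stack.all_states.index(s) for s in stack.common_states])
    rr = np.empty(stack.lags.size)
    for k, ct in enumerate(stack.tables):
        total = ct.sum()
        rr[k] = 100.0 * ct[idx, idx].sum() / total if total else 0.0
    return DiagonalProfile(lags=stack.lags.copy(), rr=rr)


def phi_profile(stack: ContingencyStack, k) -> PhiProfile:
    """Pearson phi between "x visits k" and "y visits k", per lag.

    Collapsing CT_l over {k, not-k} gives a 2x2 table (a, b; c, d) with
    a = (k, k), b = (k, not-k), c = (not-k, k), d = (not-k, not-k), and
    phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)).  Any zero margin leaves
    phi undefined (NaN) at that lag; the count of such lags is reported.
    """
    if k not in stack.common_states:
        raise ValidationError(
            f"state {k!r} is not among the common states {list(stack.common_states)}"
        )
    ki = stack.all_states.index(k)
    phi = np.empty(stack.lags.size)
    n_undef = 0
    for idx, ct in enumerate(stack.tables):
        a = float(ct[ki, ki])
        b = float(ct[ki, :].sum() - a)
        c = float(ct[:, ki].sum() - a)
        d = float(ct.sum() - a - b - c)
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        if denom == 0:
            phi[idx] = np.nan
            n_undef += 1
        else:
            phi[idx] = (a * d - b * c) / np.sqrt(denom)
    return PhiProfile(state=k, lags=stack.lags.copy(), phi=phi, n_undefined=n_undef)
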