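"""Coupled binary-agent simulator and cross-correlation profile.

The simulator produces two 0/1 event series: a "confederate" C emitting
an event at base rate p_c (with repetition probability p_cc after an
event), and a "participant" S whose event probability is raised to p_sc
whenever C emitted on the *previous* step (falling back to base rate p_s
and repetition p_ss otherwise).  The one-step reaction makes C lead S by
one sample, so both the cross-correlation profile and the diagonal-wise
recurrence profile of a simulated pair peak at lag -1 under this
package's sign convention (negative lag = series 1 leads).  A same-step
variant is available behind ``coupling="same"``.

The stationary event rate of C follows from its two-state Markov chain:
P(C=1) = p_c + (1 - p_c) * p_cc * P(C=1), i.e. p_c / (1 - (1-p_c)*p_cc).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .series import TimeSeries, as_timeseries

__all__ = ["SimParams", "simulate_coupled_binary", "stationary_rate",
           "CrossCorrelationProfile", "cross_correlation_profile"]


@dataclass(frozen=True)
class SimParams:
    """Probabilities and length of a coupled binary simulation.

    p_c, p_s: base event rates of C and S; p_cc, p_ss: repetition
    probabilities (event given own previous event); p_sc: coupling
    (S's event probability given C's previous event).  ``coupling``
    selects whether S reacts to C's previous ("previous", default) or
    current ("same") step.
    """

    p_c: float = 0.25
    p_s: float = 0.05
    p_cc: float = 0.05
    p_ss: float = 0.05
    p_sc: float = 0.33
    steps: int = 1000
    seed: int | None = None
    coupling: str = "previous"

    def __post_init__(self) -> None:
        for name in ("p_c", "p_s", "p_cc", "p_ss", "p_sc"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be a probability in [0, 1], got {p}")
        if self.steps < 1:
            raise ValidationError("steps must be >= 1")
        if self.coupling not in ("previous", "same"):
            raise ValidationError(f"unknown coupling mode {self.coupling!r}")


def simulate_coupled_binary(params: SimParams) -> tuple[TimeSeries, TimeSeries]:
    """Generate one (C, S) pair of 0/1 event series.

    Per step, in order: C emits with probability p_c; failing that,
    repeats with probability p_cc if its previous output was an event.
    S emits with probability p_sc if C's reference output (previous step
    by default) was an event; failing that, at base rate p_s; failing
    that, repeats with probability p_ss after its own event.  Each
    decision consumes its own uniform draw; the generator is seeded, so
    equal seeds reproduce the pair bit for bit.
    """
    rng = np.random.default_rng(params.seed)
    u = rng.random((params.steps, 5))
    c = np.zeros(params.steps, dtype=np.int64)
    s = np.zeros(params.steps, dtype=np.int64)
    c_prev = 0
    s_prev = 0
    for t in range(params.steps):
        if u[t, 0] < params.p_c:
            ct = 1
        elif c_prev == 1 and u[t, 1] < params.p_cc:
            ct = 1
        else:
            ct = 0
        c_ref = c_prev if params.coupling == "previous" else ct
        if c_ref == 1 and u[t, 2] < params.p_sc:
            st = 1
        elif u[t, 3] < params.p_s:
            st = 1
        elif s_prev == 1 and u[t, 4] < params.p_ss:
            st = 1
        else:
            st = 0
        c[t], s[t] = ct, st
        c_prev, s_prev = ct, st
    cats = (0, 1)
    return (TimeSeries(c, "categorical", cats), TimeSeries(s, "categorical", cats))


def stationary_rate(p_base: float, p_repeat: float) -> float:
    """Stationary event rate of the driving agent's two-state chain."""
    return p_base / (1.0 - (1.0 - p_base) * p_repeat)


@dataclass(frozen=True)
class CrossCorrelationProfile:
    """Pearson correlation of x(t) with y(t - lag), per lag."""

    lags: np.ndarray
    r: np.ndarray

    def _argmax(self) -> int:
        key = np.where(np.isnan(self.r), -np.inf, self.r)
        order = sorted(range(len(self.lags)),
                       key=lambda k: (-key[k], abs(self.lags[k]), self.lags[k]))
        return order[0]

    @property
    def max_r(self) -> float:
        return float(self.r[self._argmax()])

    @property
    def maxlag(self) -> int:
        return int(self.lags[self._argmax()])


def cross_correlation_profile(x, y, W: int) -> CrossCorrelationProfile:
    """Lagged Pearson correlations over lags -W..+W.

    Same sign convention as the recurrence profiles: r(lag) correlates
    x(t) with y(t - lag), so a peak at a negative lag means series 1
    leads.  Lags where either aligned segment has zero variance yield
    NaN.
    """
    vx = as_timeseries(x, "categorical" if _is_int(x) else "continuous").values.astype(float)
    vy = as_timeseries(y, "categorical" if _is_int(y) else "continuous").values.astype(float)
    n = min(vx.size, vy.size)
    vx, vy = vx[:n], vy[:n]
    if W < 0 or W >= n:
        raise ValidationError(f"lag window W={W} must be in [0, {n - 1}]")
    lags = np.arange(-W, W + 1)
    r = np.empty(lags.size)
    for idx, lag in enumerate(lags):
        if lag >= 0:
            a, b = vx[lag:n], vy[0:n - lag]
        else:
            a, b = vx[0:n + lag], vy[-lag:n]
        if a.std() == 0 or b.std() == 0:
            r[idx] = np.nan
        else:
            r[idx] = float(np.corrcoef(a, b)[0, 1])
    return CrossCorrelationProfile(lags=lags, r=r)


def _is_int(obj) -> bool:
    if isinstance(obj, TimeSeries):
        return obj.datatype == "categorical"
    return np.issubdtype(np.asarray(obj).dtype, np.integer)
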