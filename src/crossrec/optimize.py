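"""Three-step parameter selection for continuous cross-recurrence.

Choosing (delay, embedding dimension, radius) for continuous data is the
hard part of recurrence analysis.  The procedure here follows the
standard phase-space-reconstruction recipe:

1. delay: for each series, the first local minimum of the average mutual
   information (AMI) between x(t) and x(t + lag) — the lag at which the
   delayed copy stops being redundant.  The two per-series delays are
   combined: the clearly longer one wins (so both series gain new
   information), close ones are averaged.
2. embedding dimension: Kennel-style false nearest neighbors (FNN) per
   series — the first dimension at which spurious neighbors (points close
   only because the space is folded) essentially vanish, taking the
   larger of the two series' answers.
3. radius: a deterministic grid of equally spaced radii between 0 and the
   radius giving roughly 25% recurrence, scanned upward until the
   recurrence rate of the embedded pair lands in a target band
   (2-5% by default), refining the grid when it steps over the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import mutual_info_score
from sklearn.neighbors import NearestNeighbors

from .embedding import embed_series
from .errors import CrossRecError, InsufficientLengthError, ValidationError
from .series import as_timeseries

__all__ = ["OptimalParams", "ami_delay", "combine_delays", "fnn_embedding",
           "radius_search", "recurrence_rate_for_radii", "optimize_params"]


@dataclass(frozen=True)
class OptimalParams:
    delay: int
    embed_dim: int
    radius: float
    achieved_rr: float
    diagnostics: dict = field(repr=False, default_factory=dict)


def ami_delay(x, max_lag: int, bins: int = 10, leveling_tol: float = 0.05,
              lookahead: int = 5,
              no_structure_frac: float = 0.1) -> tuple[int, np.ndarray]:
    """First persistent local minimum of the average mutual information.

    AMI(lag) is estimated in nats from an equal-width ``bins``-level
    discretization of the series (bins fixed across lags), via the joint
    histogram of (x(t), x(t + lag)).  Selection: if the curve collapses
    immediately (AMI(1) below ``no_structure_frac`` of AMI(0)), the
    delayed copy is already uninformative and lag 1 is returned.
    Otherwise the first *persistent* local minimum is returned — a lag
    the curve decreases into and that no lag within the next
    ``lookahead`` steps undercuts — which ignores one-lag wiggles of the
    histogram estimate.  If no such minimum exists, the first lag whose
    one-step relative decrease falls below ``leveling_tol`` is returned
    (the curve has levelled off), and ``max_lag`` as a last resort.  The
    full curve (lags 0..max_lag) is returned for inspection.
    """
    v = as_timeseries(x, "continuous").values
    if v.std() == 0:
        raise ValidationError("zero variance: AMI delay selection needs a non-constant series")
    if max_lag < 1 or max_lag >= v.size / 2:
        raise ValidationError(f"max_lag must be in [1, {v.size // 2 - 1}]")
    edges = np.linspace(v.min(), v.max(), bins + 1)
    codes = np.clip(np.digitize(v, edges[1:-1]), 0, bins - 1)
    ami = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a, b = codes[:v.size - lag], codes[lag:]
        H = np.bincount(a * bins + b, minlength=bins * bins).reshape(bins, bins)
        ami[lag] = mutual_info_score(None, None, contingency=H)
    if ami[1] <= no_structure_frac * ami[0]:
        return 1, ami
    for lag in range(1, max_lag + 1):
        ahead = ami[lag + 1: lag + 1 + lookahead]
        if ami[lag] < ami[lag - 1] and (ahead.size == 0 or ami[lag] <= ahead.min()):
            return lag, ami
    for lag in range(1, max_lag + 1):
        prev, cur = ami[lag - 1], ami[lag]
        if prev > 0 and (prev - cur) / prev < leveling_tol:
            return lag, ami
    return max_lag, ami


def combine_delays(d1: int, d2: int, closeness_ratio: float = 2.0) -> int:
    """Combine two per-series delays into one shared delay.

    If one delay is considerably longer (ratio above ``closeness_ratio``)
    it wins, ensuring new information is gained for both series;
    otherwise the rounded mean is used.
    """
    if d1 < 1 or d2 < 1:
        raise ValidationError("delays must be >= 1")
    lo, hi = min(d1, d2), max(d1, d2)
    if hi / lo > closeness_ratio:
        return hi
    return int(round((d1 + d2) / 2))


def fnn_embedding(x, delay: int, max_dim: int, ratio_tol: float = 10.0,
                  fnn_threshold: float = 0.05) -> tuple[int, np.ndarray]:
    """Embedding dimension by false nearest neighbors.

    For each dimension d, every point's nearest neighbor in the d-dim
    embedding is checked against the (d+1)-th coordinate: if the extra
    separation exceeds ``ratio_tol`` times the d-dim distance, the
    neighbor was false (an artifact of projecting the attractor into too
    few dimensions).  Returns the first dimension where the false-
    neighbor fraction drops below ``fnn_threshold`` or stops decreasing,
    together with the fractions evaluated (index d-1 for dimension d).
    """
    v = as_timeseries(x, "continuous").values
    if v.std() == 0:
        raise ValidationError("zero variance: FNN needs a non-constant series")
    if max_dim < 1:
        raise ValidationError("max_dim must be >= 1")
    if v.size - max_dim * delay < 2:
        raise InsufficientLengthError(
            f"series of length {v.size} too short for FNN up to dimension {max_dim} "
            f"at delay {delay} (needs length > {max_dim * delay + 1})"
        )
    fractions = []
    for d in range(1, max_dim + 1):
        emb = embed_series(v, delay, d).points
        n_pts = v.size - d * delay  # rows that still have a (d+1)-th coordinate
        pts = emb[:n_pts]
        extra = v[d * delay: d * delay + n_pts]
        nn = NearestNeighbors(n_neighbors=2).fit(pts)
        dist, idx = nn.kneighbors(pts)
        rd, nbr = dist[:, 1], idx[:, 1]
        sep = np.abs(extra - extra[nbr])
        # the absolute floor keeps float-precision jitter between exact
        # revisits (rd ~ 1e-16) from registering as false neighbors
        floor = 1e-9 * v.std()
        false = sep > ratio_tol * rd + floor
        frac = float(false.mean())
        fractions.append(frac)
        if frac < fnn_threshold:
            return d, np.array(fractions)
        if d >= 2 and frac >= fractions[d - 2]:
            return d - 1, np.array(fractions)
    return max_dim, np.array(fractions)


def recurrence_rate_for_radii(x, y, radii, delay: int = 1, embed_dim: int = 1,
                              normalize: str = "none",
                              block_elems: int = 4_000_000) -> np.ndarray:
    """Exact recurrence rate (percent) at each candidate radius.

    Evaluated blockwise so that pairs of long series never materialize
    the full distance matrix; a single pass counts distances at or below
    every candidate at once.
    """
    A = embed_series(as_timeseries(x, "continuous"), delay, embed_dim,
                     normalize=normalize).points
    B = embed_series(as_timeseries(y, "continuous"), delay, embed_dim,
                     normalize=normalize).points
    radii = np.asarray(radii, dtype=float)
    order = np.argsort(radii)
    sorted_r = radii[order]
    counts = np.zeros(sorted_r.size + 1, dtype=np.int64)
    rows_per_block = max(1, block_elems // max(1, B.shape[0]))
    for start in range(0, A.shape[0], rows_per_block):
        d = cdist(A[start:start + rows_per_block], B).ravel()
        pos = np.searchsorted(sorted_r, d, side="left")
        counts += np.bincount(pos, minlength=sorted_r.size + 1)
    le = np.cumsum(counts)[:sorted_r.size]
    rr_sorted = 100.0 * le / (A.shape[0] * B.shape[0])
    rr = np.empty_like(rr_sorted)
    rr[order] = rr_sorted
    return rr


def radius_search(x, y, delay: int = 1, embed_dim: int = 1,
                  target_rr: tuple[float, float] = (2.0, 5.0),
                  n_candidates: int = 20, max_rounds: int = 3,
                  normalize: str = "none",
                  subsample_cap: int = 1500) -> tuple[float, float, list]:
    """Smallest grid radius whose recurrence rate lands in the target band.

    Candidates are ``n_candidates`` equally spaced radii between 0 and
    the radius yielding roughly 25% recurrence (estimated from a strided
    subsample of the distance distribution), scanned in ascending order.
    If the grid steps over the band, it is refined between the bracketing
    candidates, up to ``max_rounds`` rounds.  The grid is deterministic:
    the same inputs always yield the same radius.

    Returns (radius, achieved recurrence rate, trace of (radius, rr)
    pairs evaluated).  Raises if the band is unreachable (e.g. the
    recurrence rate jumps across it on discrete-valued data), with the
    full trace attached to the error.
    """
    lo_t, hi_t = target_rr
    if not (0 <= lo_t < hi_t):
        raise ValidationError("target_rr must be an increasing pair of percentages")
    tx = as_timeseries(x, "continuous")
    ty = as_timeseries(y, "continuous")
    A = embed_series(tx, delay, embed_dim, normalize=normalize).points
    B = embed_series(ty, delay, embed_dim, normalize=normalize).points
    sa = A[:: max(1, int(np.ceil(A.shape[0] / subsample_cap)))]
    sb = B[:: max(1, int(np.ceil(B.shape[0] / subsample_cap)))]
    r_hi = float(np.quantile(cdist(sa, sb), 0.25))
    trace: list[tuple[float, float]] = []
    lo_r, hi_r = 0.0, r_hi
    if r_hi == 0:  # degenerate: a quarter of all distances are exactly zero
        rr0 = recurrence_rate_for_radii(tx, ty, [0.0], delay, embed_dim, normalize)[0]
        trace.append((0.0, float(rr0)))
        if lo_t <= rr0 <= hi_t:
            return 0.0, float(rr0), trace
        err = ValidationError(
            f"target recurrence band [{lo_t}, {hi_t}]% unreachable: RR(0) = {rr0:.3f}%")
        err.trace = trace
        raise err
    for _round in range(max_rounds):
        cand = np.linspace(lo_r, hi_r, n_candidates)
        rr = recurrence_rate_for_radii(tx, ty, cand, delay, embed_dim, normalize)
        trace.extend(zip(cand.tolist(), rr.tolist()))
        jumped = None
        for k in range(cand.size):
            if lo_t <= rr[k] <= hi_t:
                return float(cand[k]), float(rr[k]), trace
            if rr[k] > hi_t:
                jumped = k
                break
        if jumped is None:
            # even the largest candidate is below the band; push upward
            lo_r, hi_r = float(cand[-1]), hi_r * 2
        elif jumped == 0:
            break  # RR already above the band at the smallest radius
        else:
            lo_r, hi_r = float(cand[jumped - 1]), float(cand[jumped])
    err = ValidationError(
        f"no radius with recurrence rate in [{lo_t}, {hi_t}]% found after "
        f"{max_rounds} refinement rounds; the rate jumps across the band"
    )
    err.trace = trace
    raise err


def optimize_params(x, y, max_lag: int = 40, bins: int = 10, max_dim: int = 6,
                    target_rr: tuple[float, float] = (2.0, 5.0),
                    n_candidates: int = 20, max_rounds: int = 3,
                    normalize: str = "none") -> OptimalParams:
    """Compose the three selection steps on a pair of continuous series.

    Diagnostics retain the per-series AMI curves and delays, per-series
    FNN fractions and dimensions, and the radius-search trace.
    """
    diagnostics: dict = {}
    try:
        d1, ami1 = ami_delay(x, max_lag=max_lag, bins=bins)
        d2, ami2 = ami_delay(y, max_lag=max_lag, bins=bins)
    except CrossRecError as e:
        raise type(e)(f"delay selection (AMI): {e}") from e
    delay = combine_delays(d1, d2)
    diagnostics["ami"] = {"delays": (d1, d2), "curve_x": ami1, "curve_y": ami2}
    try:
        m1, f1 = fnn_embedding(x, delay, max_dim=max_dim)
        m2, f2 = fnn_embedding(y, delay, max_dim=max_dim)
    except CrossRecError as e:
        raise type(e)(f"embedding-dimension selection (FNN): {e}") from e
    embed_dim = max(m1, m2)
    diagnostics["fnn"] = {"dims": (m1, m2), "fractions_x": f1, "fractions_y": f2}
    try:
        radius, rr, trace = radius_search(
            x, y, delay=delay, embed_dim=embed_dim, target_rr=target_rr,
            n_candidates=n_candidates, max_rounds=max_rounds, normalize=normalize)
    except CrossRecError as e:
        e2 = type(e)(f"radius selection: {e}")
        e2.trace = getattr(e, "trace", None)
        raise e2 from e
    diagnostics["radius_trace"] = trace
    return OptimalParams(delay=delay, embed_dim=embed_dim, radius=radius,
                         achieved_rr=rr, diagnostics=diagnostics)
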