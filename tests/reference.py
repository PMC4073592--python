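"""Naive pure-Python reference implementation used as an independent oracle.

Everything here is written with explicit loops and sets, straight from
the definitions, and deliberately shares no code with the package: the
vectorized pipeline is checked against it element by element.
"""

from __future__ import annotations

import math


def naive_embed(x, delay, dim):
    x = list(x)
    n = len(x) - (dim - 1) * delay
    return [[x[t + k * delay] for k in range(dim)] for t in range(n)]


def naive_distance(a, b):
    out = []
    for pa in a:
        row = []
        for pb in b:
            row.append(math.sqrt(sum((u - v) ** 2 for u, v in zip(pa, pb))))
        out.append(row)
    return out


def naive_recurrent_points(D, radius):
    pts = set()
    for i, row in enumerate(D):
        for j, d in enumerate(row):
            if d <= radius:
                pts.add((i + 1, j + 1))
    return pts


def naive_theiler(points, tw):
    if tw == 0:
        return set(points)
    return {(i, j) for (i, j) in points if abs(j - i) > tw - 1}


def naive_diagonal_lengths(points, n1, n2):
    lengths = []
    for d in range(-(n1 - 1), n2):
        run = 0
        for i in range(1, n1 + 1):
            j = i + d
            if 1 <= j <= n2 and (i, j) in points:
                run += 1
            else:
                if run:
                    lengths.append(run)
                run = 0
        if run:
            lengths.append(run)
    return lengths


def naive_vertical_lengths(points, n1, n2):
    lengths = []
    for j in range(1, n2 + 1):
        run = 0
        for i in range(1, n1 + 1):
            if (i, j) in points:
                run += 1
            else:
                if run:
                    lengths.append(run)
                run = 0
        if run:
            lengths.append(run)
    return lengths


def naive_measures(points, n1, n2, minline=2):
    npts = len(points)
    rr = 100.0 * npts / (n1 * n2)
    diag = [l for l in naive_diagonal_lengths(points, n1, n2) if l >= minline]
    vert = [l for l in naive_vertical_lengths(points, n1, n2) if l >= minline]
    nan = float("nan")
    if diag and npts:
        det = 100.0 * sum(diag) / npts
        l_mean = sum(diag) / len(diag)
        l_max = float(max(diag))
        freqs = {}
        for l in diag:
            freqs[l] = freqs.get(l, 0) + 1
        entr = -sum((c / len(diag)) * math.log(c / len(diag)) for c in freqs.values())
    else:
        det, l_mean, l_max, entr = 0.0, nan, nan, 0.0
    if vert and npts:
        lam = 100.0 * sum(vert) / npts
        tt = sum(vert) / len(vert)
    else:
        lam, tt = 0.0, nan
    return {"RR": rr, "DET": det, "L": l_mean, "Lmax": l_max,
            "ENTR": entr, "LAM": lam, "TT": tt}


def naive_crqa(x, y, delay, dim, radius, tw=0, minline=2):
    a = naive_embed(x, delay, dim)
    b = naive_embed(y, delay, dim)
    D = naive_distance(a, b)
    pts = naive_theiler(naive_recurrent_points(D, radius), tw)
    return naive_measures(pts, len(a), len(b), minline)


def naive_drp(x, y, W, radius=0.001, exclude_nonevent=None):
    x, y = list(x), list(y)
    n = min(len(x), len(y))
    lags = list(range(-W, W + 1))
    rr = []
    for lag in lags:
        hits = 0
        valid = 0
        for t in range(n):
            s = t - lag
            if 0 <= s < n:
                valid += 1
                if abs(x[t] - y[s]) <= radius:
                    if exclude_nonevent is not None and \
                            x[t] == exclude_nonevent and y[s] == exclude_nonevent:
                        continue
                    hits += 1
        rr.append(100.0 * hits / valid)
    return lags, rr


def naive_ami_curve(x, max_lag, bins=10):
    """Equal-width 2-D histogram mutual information, in nats."""
    x = [float(v) for v in x]
    lo, hi = min(x), max(x)
    width = (hi - lo) / bins or 1.0

    def cell(v):
        k = int((v - lo) / width)
        return min(k, bins - 1)

    curve = []
    for lag in range(max_lag + 1):
        pairs = [(cell(x[t]), cell(x[t + lag])) for t in range(len(x) - lag)]
        n = len(pairs)
        joint = {}
        ma = [0] * bins
        mb = [0] * bins
        for a, b in pairs:
            joint[(a, b)] = joint.get((a, b), 0) + 1
            ma[a] += 1
            mb[b] += 1
        mi = 0.0
        for (a, b), c in joint.items():
            p = c / n
            mi += p * math.log(p / ((ma[a] / n) * (mb[b] / n)))
        curve.append(mi)
    return curve
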