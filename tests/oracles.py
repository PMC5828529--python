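"""Independent brute-force reference implementations.

Each oracle recomputes an operation from first principles, deliberately
avoiding the code paths (and where practical the library calls) used by the
package, so that agreement is evidence and not tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special, stats


def brute_median(values) -> float:
    v = sorted(values)
    n = len(v)
    return v[n // 2] if n % 2 else 0.5 * (v[n // 2 - 1] + v[n // 2])


def brute_median_filter(values, k: int, edges: str = "copy") -> list[float]:
    """k-point running median with explicit edge handling."""
    n = len(values)
    half = k // 2
    out = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if edges == "copy" and (i < half or i >= n - half):
            out.append(values[i])
        else:
            out.append(brute_median(values[lo:hi]))
    return out


def brute_smooth(mids, values, window_bp: float) -> list[float]:
    """Windowed mean by explicit membership test |dm| <= window/2."""
    out = []
    for m in mids:
        members = [v for mm, v in zip(mids, values) if abs(mm - m) <= window_bp / 2]
        out.append(sum(members) / len(members))
    return out


def brute_percentile(values, q: float) -> float:
    """Linear interpolation between order statistics, h = (n-1)q/100 + 1."""
    v = sorted(values)
    n = len(v)
    h = (n - 1) * q / 100.0 + 1
    lo = int(math.floor(h))
    frac = h - lo
    if lo >= n:
        return v[-1]
    return v[lo - 1] + frac * (v[lo] - v[lo - 1])


def brute_boxplot(values, whisker_factor: float = 1.5) -> dict:
    q25 = brute_percentile(values, 25)
    med = brute_percentile(values, 50)
    q75 = brute_percentile(values, 75)
    iqr = q75 - q25
    lo_candidates = [v for v in values if v >= q25 - whisker_factor * iqr]
    hi_candidates = [v for v in values if v <= q75 + whisker_factor * iqr]
    return {
        "median": med,
        "q25": q25,
        "q75": q75,
        "whisker_lo": min(lo_candidates),
        "whisker_hi": max(hi_candidates),
        "notch": 1.58 * iqr / math.sqrt(len(values)),
    }


def brute_bh(p_values) -> list[float]:
    """Step-up BH by direct definition: adj_i = min_{j>=i} (m/j) p_(j), capped."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj_sorted = [min(1.0, p_values[order[j]] * m / (j + 1)) for j in range(m)]
    for j in range(m - 2, -1, -1):
        adj_sorted[j] = min(adj_sorted[j], adj_sorted[j + 1])
    out = [0.0] * m
    for j, i in enumerate(order):
        out[i] = adj_sorted[j]
    return out


def brute_peak_runs(values, threshold: float, max_gap: int, min_probes: int):
    """Index runs strictly above threshold, merged across short gaps.

    Built from a boolean mask by gap-filling rather than incremental
    grouping: gaps of <= max_gap below-threshold probes *between* above
    probes are bridged, then maximal bridged stretches are read off and
    filtered on their above-threshold probe count.
    """
    above = [v > threshold for v in values]
    idx = [i for i, a in enumerate(above) if a]
    if not idx:
        return []
    bridged = list(above)
    for a, b in zip(idx[:-1], idx[1:]):
        if 0 < b - a - 1 <= max_gap:
            for i in range(a + 1, b):
                bridged[i] = True
    runs, cur = [], None
    for i, flag in enumerate(bridged):
        if flag and cur is None:
            cur = [i, i]
        elif flag:
            cur[1] = i
        elif cur is not None:
            runs.append(cur)
            cur = None
    if cur is not None:
        runs.append(cur)
    out = []
    for lo, hi in runs:
        members = [i for i in range(lo, hi + 1) if above[i]]
        if len(members) >= min_probes:
            out.append(members)
    return out


def brute_trigamma_inverse(y: float) -> float:
    """Bisection solve of trigamma(x) = y (trigamma is decreasing)."""
    lo, hi = 1e-8, 1e8
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def brute_moderated_t(bait: np.ndarray, ctrl: np.ndarray):
    """Closed-form moderated t computed step by step.

    Residual variance per row with d = n1+n2-2 df; prior (d0, s0^2) by
    moment matching on log s^2 (digamma/trigamma relations, trigamma
    inverted by bisection); posterior variance (d0 s0^2 + d s^2)/(d0 + d);
    t = fc / (s_post * sqrt(1/n1 + 1/n2)); two-sided p on d0 + d df.
    """
    n1, n2 = bait.shape[1], ctrl.shape[1]
    d = n1 + n2 - 2
    fc = bait.mean(axis=1) - ctrl.mean(axis=1)
    s2 = (
        ((bait - bait.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        + ((ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ) / d
    z = np.log(s2)
    e = z - special.digamma(d / 2) + math.log(d / 2)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2))
    if evar > 0:
        d0 = 2.0 * brute_trigamma_inverse(evar)
        s0_2 = math.exp(float(np.mean(e)) + special.digamma(d0 / 2) - math.log(d0 / 2))
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d
    else:
        s0_2 = math.exp(float(np.mean(e)))
        s2_post = np.full_like(s2, s0_2)
        d0, df_total = math.inf, 1e6
    t = fc / np.sqrt(s2_post * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(np.abs(t), df_total)
    return {"log2_fc": fc, "t": t, "p": p, "d0": d0, "s0_2": s0_2}


def brute_pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))
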