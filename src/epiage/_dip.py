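"""Hartigan's dip statistic for unimodality testing.

The dip of an empirical CDF is the largest vertical distance between it and
the closest unimodal CDF. It is computed here by the standard iterative
refinement: on the current candidate modal interval, fit the greatest convex
minorant (GCM) to the left part and the least concave majorant (LCM) to the
right, find where the two envelopes disagree most, shrink the interval to the
touch points flanking that disagreement, and accumulate the deviations of the
ECDF from the envelopes outside the new interval. The statistic is half the
largest accumulated deviation.

P-values are obtained by Monte Carlo under the uniform null at the observed
sample size (the classical least-favourable unimodal null), so the test is
exact in level by construction at any sample size.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_pvalue", "null_dip_distribution"]


def _convex_minorant(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the greatest convex minorant (lower hull) of points (x, y)."""
    hull = [0]
    for i in range(1, len(x)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # drop b if it lies on/above the chord a->i
            if (y[b] - y[a]) * (x[i] - x[a]) >= (y[i] - y[a]) * (x[b] - x[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull)


def _interp_hull(x: np.ndarray, y: np.ndarray, hull: np.ndarray, xq: np.ndarray) -> np.ndarray:
    return np.interp(xq, x[hull], y[hull])


def dip_statistic(values: np.ndarray) -> float:
    """Hartigan & Hartigan's dip statistic of a 1-D sample."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4 or x[0] == x[-1]:
        return 0.0

    # collapse ties: unique support points with lower/upper ECDF values
    u, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts)
    hi = cum / n            # F(u_j)
    lo = (cum - counts) / n  # F(u_j^-)

    m = u.size
    if m < 2:
        return 0.0

    low, high = 0, m - 1
    d_best = 0.0
    while True:
        xs = u[low : high + 1]
        lo_s = lo[low : high + 1]
        hi_s = hi[low : high + 1]

        gcm = _convex_minorant(xs, lo_s)               # convex minorant of lower ECDF
        lcm = _convex_minorant(xs, -hi_s)              # concave majorant of upper ECDF
        gcm_vals = _interp_hull(xs, lo_s, gcm, xs)
        lcm_vals = -_interp_hull(xs, -hi_s, lcm, xs)

        # largest disagreement between the two envelopes
        diff = lcm_vals - gcm_vals
        j_star = int(np.argmax(diff))
        d = float(diff[j_star])
        if d <= d_best:
            break

        # new modal interval: envelope touch points flanking the argmax
        new_low_rel = int(gcm[gcm <= j_star].max()) if np.any(gcm <= j_star) else 0
        new_high_rel = int(lcm[lcm >= j_star].min()) if np.any(lcm >= j_star) else len(xs) - 1

        # deviations of the ECDF from the envelopes outside the new interval
        left = slice(0, new_low_rel + 1)
        right = slice(new_high_rel, len(xs))
        d_left = float(np.max(hi_s[left] - gcm_vals[left])) if new_low_rel >= 0 else 0.0
        d_right = float(np.max(lcm_vals[right] - lo_s[right])) if new_high_rel < len(xs) else 0.0
        d_best = max(d_best, d_left, d_right)

        if new_low_rel == 0 and new_high_rel == len(xs) - 1:
            break
        if low + new_low_rel == low and low + new_high_rel == high:
            break
        low, high = low + new_low_rel, low + new_high_rel
        if high - low < 1:
            break

    return max(d_best, 1.0 / n) / 2.0


def null_dip_distribution(n: int, n_sim: int = 2000, rng: np.random.Generator | None = None) -> np.ndarray:
    """Monte-Carlo null distribution of the dip under Uniform(0,1) samples of size n."""
    rng = rng if rng is not None else np.random.default_rng(0)
    out = np.empty(n_sim)
    for i in range(n_sim):
        out[i] = dip_statistic(rng.uniform(size=n))
    return out


def dip_pvalue(values: np.ndarray, null_dips: np.ndarray) -> float:
    """MC p-value of the dip against a precomputed null distribution."""
    d = dip_statistic(values)
    return float((1 + np.sum(null_dips >= d)) / (1 + null_dips.size))
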