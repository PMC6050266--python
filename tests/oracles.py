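"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own KS code paths: the ECDF is
evaluated point by point and the permutation null is enumerated with
plain ``itertools`` so that agreement with the library is a genuine
cross-check, not a tautology.
"""

import itertools

import numpy as np


def ecdf_at(values, t):
    return float(np.mean(np.asarray(values) <= t))


def ks_stat_brute(x, y):
    """sup |ECDF_x - ECDF_y| by direct evaluation at every pooled point."""
    pts = np.concatenate([x, y])
    return max(abs(ecdf_at(x, t) - ecdf_at(y, t)) for t in pts)


def ks_perm_pvalue_brute(x, y):
    """Exhaustive permutation p-value over all C(n+m, n) group
    assignments of the pooled values."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, total = len(x), len(pooled)
    d_obs = ks_stat_brute(x, y)
    hits = count = 0
    for idx in itertools.combinations(range(total), n):
        sel = np.zeros(total, dtype=bool)
        sel[list(idx)] = True
        count += 1
        if ks_stat_brute(pooled[sel], pooled[~sel]) >= d_obs - 1e-12:
            hits += 1
    return hits / count


def bh_brute(p):
    """Step-up BH by the textbook formula: sort, scale by m/rank,
    cumulative minimum from the largest p, clip at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
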