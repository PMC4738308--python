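"""Independent brute-force oracle for the dip statistic.

The dip is the smallest d such that some unimodal CDF G stays within
sup-norm d of the empirical CDF.  For a fixed modal position (in one of
the gaps between distinct sample values, or beyond the extremes) the
existence of such a G — convex and nondecreasing left of the mode,
concave right of it, within the band [F(x_k)-d, F(x_k^-)+d] at each
distinct value x_k, in [0, 1], allowing an atom at the mode — is a
linear feasibility problem in G's values at the distinct sample points.
The oracle binary-searches d over all modal gaps with scipy's linprog.

This route shares no code or algorithmic structure with the production
GCM/LCM implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _feasible(d, z, F, Fm, j, variant):
    """Can a unimodal CDF with mode in gap (z[j-1], z[j]) fit within d?

    1-based thinking: left part covers distinct points 1..j, right part
    j+1..m (here 0-based: left 0..j-1, right j..m-1).  ``variant`` picks
    which side's adjacent slope bounds the cross-gap rise (the true
    condition is the minimum of the two; the union of both variants
    covers it).
    """
    m = len(z)
    lo = np.maximum(F - d, 0.0)
    hi = np.minimum(Fm + d, 1.0)
    if (lo > hi + 1e-12).any():
        return False

    A_ub, b_ub = [], []

    def add(coeffs, rhs=0.0):
        row = np.zeros(m)
        for k, v in coeffs:
            row[k] += v
        A_ub.append(row)
        b_ub.append(rhs)

    # monotone nondecreasing
    for k in range(m - 1):
        add([(k, 1.0), (k + 1, -1.0)])
    # convex slopes on the left part: indices 0..j-1
    for t in range(1, j - 1):
        dl = z[t] - z[t - 1]
        dr = z[t + 1] - z[t]
        # (g[t]-g[t-1])/dl <= (g[t+1]-g[t])/dr
        add([(t, 1.0 / dl + 1.0 / dr), (t - 1, -1.0 / dl), (t + 1, -1.0 / dr)])
    # concave slopes on the right part: indices j..m-1
    for t in range(j + 1, m - 1):
        dl = z[t] - z[t - 1]
        dr = z[t + 1] - z[t]
        # (g[t]-g[t-1])/dl >= (g[t+1]-g[t])/dr
        add([(t, -(1.0 / dl + 1.0 / dr)), (t - 1, 1.0 / dl), (t + 1, 1.0 / dr)])
    # cross-gap: g[j] - g[j-1] >= min(left exit slope, right entry slope) * gap
    if 1 <= j <= m - 1:
        gap = z[j] - z[j - 1]
        if variant == "left" and j >= 2:
            dl = z[j - 1] - z[j - 2]
            # slope_last * gap <= g[j] - g[j-1]
            add([(j - 1, gap / dl + 1.0), (j - 2, -gap / dl), (j, -1.0)])
        elif variant == "right" and j <= m - 2:
            dr = z[j + 1] - z[j]
            add([(j + 1, gap / dr), (j, -gap / dr + 1.0), (j - 1, -1.0)])
        # else: the bounding slope extends to an unconstrained tail (>= 0),
        # and monotonicity alone suffices.

    res = linprog(
        c=np.zeros(m),
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        bounds=list(zip(lo, hi)),
        method="highs",
    )
    return res.status == 0


def _feasible_point_mode(d, z, F, Fm, t):
    """Mode at distinct value z[t], allowing an atom of G there.

    Variables: g[0..m-1] = G(z_k) plus h = G(z_t^-), the left limit at the
    mode.  The left branch (convex) runs through z_0..z_{t-1} and ends at
    (z_t, h); the jump h -> g[t] is the modal atom; the right branch
    (concave) starts at (z_t, g[t]).
    """
    m = len(z)
    lo = np.maximum(F - d, 0.0)
    hi = np.minimum(Fm + d, 1.0)
    hi[t] = min(F[t] + d, 1.0)  # the interior bound moves onto h
    h_hi = min(Fm[t] + d, 1.0)
    if (lo > hi + 1e-12).any() or h_hi < -1e-12:
        return False

    nv = m + 1  # h is variable index m
    A_ub, b_ub = [], []

    def add(coeffs, rhs=0.0):
        row = np.zeros(nv)
        for k, v in coeffs:
            row[k] += v
        A_ub.append(row)
        b_ub.append(rhs)

    # monotone, routing through h at the mode
    for k in range(m - 1):
        if k == t - 1:
            add([(k, 1.0), (m, -1.0)])  # g[t-1] <= h
        else:
            add([(k, 1.0), (k + 1, -1.0)])
    if t >= 1:
        add([(m, 1.0), (t, -1.0)])  # h <= g[t]

    def left_val(k):
        return m if k == t else k

    # convex slopes on the left branch: knots z_0..z_{t-1}, (z_t, h)
    for u in range(1, t):
        dl = z[u] - z[u - 1]
        dr = z[u + 1] - z[u]
        a, b_, c = left_val(u - 1), left_val(u), left_val(u + 1)
        add([(b_, 1.0 / dl + 1.0 / dr), (a, -1.0 / dl), (c, -1.0 / dr)])
    # concave slopes on the right branch: knots z_t..z_{m-1}
    for u in range(t + 1, m - 1):
        dl = z[u] - z[u - 1]
        dr = z[u + 1] - z[u]
        add([(u, -(1.0 / dl + 1.0 / dr)), (u - 1, 1.0 / dl), (u + 1, 1.0 / dr)])

    bounds = list(zip(lo, hi)) + [(0.0, h_hi)]
    res = linprog(
        c=np.zeros(nv),
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        bounds=bounds,
        method="highs",
    )
    return res.status == 0


def dip_brute(sample, tol: float = 1e-9) -> float:
    """Minimise sup|F_n - G| over unimodal G by LP feasibility + bisection."""
    x = np.sort(np.asarray(sample, dtype=np.float64))
    n = len(x)
    z, counts = np.unique(x, return_counts=True)
    F = np.cumsum(counts) / n  # ECDF at each distinct value
    Fm = F - counts / n  # left limits
    m = len(z)
    if m == 1:
        return 1.0 / (2.0 * n)

    def feasible(d):
        for t in range(m):
            if _feasible_point_mode(d, z, F, Fm, t):
                return True
        for j in range(m + 1):
            variants = ("left", "right") if 1 <= j <= m - 1 else ("left",)
            for v in variants:
                if _feasible(d, z, F, Fm, j, v):
                    return True
        return False

    lo_d, hi_d = 0.0, 0.5
    while hi_d - lo_d > tol:
        mid = (lo_d + hi_d) / 2
        if feasible(mid):
            hi_d = mid
        else:
            lo_d = mid
    return hi_d
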