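"""Individual-differences statistics.

Covers the cross-participant consistency permutation test on
referent-similarity vectors, Hartigan's dip test of unimodality for the
across-participant distribution of neighbourhood feature values (with a
Gaussian bootstrap null), the correlation between imagery vividness
(VVIQ) and tuning change, and fixed-bandwidth kernel density reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "ConsistencyResult",
    "DipResult",
    "consistency_test",
    "dip_statistic",
    "dip_test_bootstrap",
    "vividness_correlation",
    "kde",
]


# --------------------------------------------------------------------------
# Cross-participant consistency of similarity vectors
# --------------------------------------------------------------------------

@dataclass
class ConsistencyResult:
    mean_r: float
    p_value: float
    null: np.ndarray
    n_perm: int
    seed: int


def _mean_pairwise_r(M: np.ndarray) -> float:
    """Mean Pearson r over all participant pairs (rows of M)."""
    Z = M - M.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Z, axis=1)
    if (norms == 0).any():
        raise ValueError("constant similarity vector")
    Z = Z / norms[:, None]
    R = Z @ Z.T
    P = M.shape[0]
    iu = np.triu_indices(P, k=1)
    return float(R[iu].mean())


def consistency_test(
    similarity_vectors: pd.DataFrame | np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "pearson",
) -> ConsistencyResult:
    """Permutation test of shared representational structure across people.

    ``similarity_vectors`` holds one row per participant (columns: the
    non-referent stimuli, in a shared id order).  The statistic is the
    mean pairwise Pearson correlation between participants' vectors; the
    null permutes each participant's entries independently, destroying
    cross-participant stimulus alignment while keeping each vector's
    marginal distribution.
    """
    M = np.asarray(similarity_vectors, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] < 3:
        raise ValueError("need vectors from at least 3 participants")
    if method == "spearman":
        M = np.apply_along_axis(_st.rankdata, 1, M)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    observed = _mean_pairwise_r(M)
    rng = np.random.default_rng(seed)
    P, n = M.shape
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = np.empty_like(M)
        for i in range(P):
            perm[i] = M[i, rng.permutation(n)]
        null[b] = _mean_pairwise_r(perm)
    p = (1.0 + (null >= observed).sum()) / (n_perm + 1.0)
    return ConsistencyResult(mean_r=observed, p_value=float(p), null=null,
                             n_perm=n_perm, seed=seed)


# --------------------------------------------------------------------------
# Hartigan's dip statistic
# --------------------------------------------------------------------------

def dip_statistic(sample) -> float:
    """Hartigan's dip: sup-norm distance from the closest unimodal CDF.

    Computed exactly on the sorted sample by the iterative greatest-convex-
    minorant / least-concave-majorant construction.  Lies in (0, 0.25]; a
    uniform-spaced sample attains the minimum 1/(2n).
    """
    x = np.sort(np.asarray(sample, dtype=np.float64))
    n = len(x)
    if n < 4:
        raise ValueError("dip statistic needs at least 4 observations")
    if x[0] == x[-1]:
        return 1.0 / (2.0 * n)

    # 1-based arrays mirroring the classic algorithm.
    xv = np.empty(n + 1)
    xv[1:] = x

    # Candidate touch points for the greatest convex minorant...
    mn = np.empty(n + 1, dtype=np.int64)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            if mnj == 1:
                break
            mnmnj = mn[mnj]
            if (xv[j] - xv[mnj]) * (mnj - mnmnj) < (xv[mnj] - xv[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    # ... and for the least concave majorant.
    mj = np.empty(n + 2, dtype=np.int64)
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            if mjk == n:
                break
            mjmjk = mj[mjk]
            if (xv[k] - xv[mjk]) * (mjk - mjmjk) < (xv[mjk] - xv[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    gcm = np.empty(n + 2, dtype=np.int64)
    lcm = np.empty(n + 2, dtype=np.int64)
    low, high = 1, n
    dip = 1.0  # in count units; divided by 2n at the end

    while True:
        # Change points of the GCM (from high down to low) and LCM (low up).
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i
        ig = i
        ix = i - 1

        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i
        ih = i
        iv = 2

        # Largest distance between the GCM and the LCM on [low, high].
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    denom = xv[gcmix] - xv[gcmi1]
                    frac = (xv[lcmiv] - xv[gcmi1]) * (gcmix - gcmi1) / denom \
                        if denom > 0 else float(gcmix - gcmi1)
                    dx = (lcmiv - gcmi1 + 1) - frac
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    denom = xv[lcmiv] - xv[lcmiv1]
                    frac = (xv[gcmix] - xv[lcmiv1]) * (lcmiv - lcmiv1) / denom \
                        if denom > 0 else 0.0
                    dx = frac - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # Maximum deviation of the ECDF from the GCM fit ...
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and xv[je] != xv[jb]:
                C = (je - jb) / (xv[je] - xv[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (xv[jj] - xv[jb]) * C
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # ... and from the LCM fit.
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and xv[je] != xv[jb]:
                C = (je - jb) / (xv[je] - xv[jb])
                for jj in range(jb, je + 1):
                    t = (xv[jj] - xv[jb]) * C - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dip < dipnew:
            dip = dipnew
        low = gcm[ig]
        high = lcm[ih]
        if dip >= d:
            break

    return dip / (2.0 * n)


@dataclass
class DipResult:
    dip: float
    p_value: float
    n_boot: int
    n: int
    seed: int
    null: np.ndarray | None = None


def dip_test_bootstrap(sample, n_boot: int = 10000, seed: int = 0,
                       keep_null: bool = False) -> DipResult:
    """Dip test with a same-size Gaussian reference null.

    Null dips come from ``n_boot`` Gaussian samples of the same size with
    the observed sample's mean and SD (the dip itself is location/scale
    invariant, so only the size matters for the null; mean and SD are used
    for fidelity to the reporting convention).
    """
    x = np.asarray(sample, dtype=np.float64)
    n = len(x)
    if n < 4:
        raise ValueError("dip test needs at least 4 observations")
    observed = dip_statistic(x)
    rng = np.random.default_rng(seed)
    mu, sd = x.mean(), x.std(ddof=1)
    null = np.empty(n_boot)
    for b in range(n_boot):
        null[b] = dip_statistic(rng.normal(loc=mu, scale=sd, size=n))
    p = (1.0 + (null >= observed).sum()) / (n_boot + 1.0)
    return DipResult(dip=observed, p_value=float(p), n_boot=n_boot, n=n,
                     seed=seed, null=null if keep_null else None)


# --------------------------------------------------------------------------
# Vividness correlation and density reporting
# --------------------------------------------------------------------------

def vividness_correlation(tuning_delta, vviq_scores) -> dict:
    """Pearson correlation of tuning change (imagery - perception) with VVIQ.

    Two-sided test; returns r, t, df and p.
    """
    d = np.asarray(tuning_delta, dtype=np.float64)
    v = np.asarray(vviq_scores, dtype=np.float64)
    if d.shape != v.shape or d.ndim != 1:
        raise ValueError("tuning deltas and VVIQ scores must be equal-length vectors")
    n = len(d)
    if n < 4:
        raise ValueError("need at least 4 participants")
    if d.std() == 0 or v.std() == 0:
        raise ValueError("zero-variance input")
    res = _st.pearsonr(d, v)
    r = float(res.statistic)
    t = r * np.sqrt((n - 2) / max(1.0 - r**2, np.finfo(float).tiny))
    return {"r": r, "t": float(t), "df": n - 2, "p": float(res.pvalue)}


def kde(sample, bandwidth: float = 0.1, grid: np.ndarray | None = None,
        n_grid: int = 512) -> tuple:
    """Gaussian kernel density estimate with a fixed absolute bandwidth.

    Returns ``(grid, density)``; the density integrates to 1 over a wide
    grid (the default grid spans the data +/- 4 bandwidths).
    """
    x = np.asarray(sample, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        lo, hi = x.min() - 4 * bandwidth, x.max() + 4 * bandwidth
        grid = np.linspace(lo, hi, n_grid)
    z = (grid[:, None] - x[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (len(x) * bandwidth * np.sqrt(2 * np.pi))
    return grid, dens
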