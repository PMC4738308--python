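"""Representational-space analytics.

Pairwise pattern distances (1 - Spearman rho, inheriting the online
similarity metric), classical metric MDS, the DISTATIS compromise across
participants and conditions, rigid Procrustes alignment between spaces,
bootstrap confidence ellipses and neighbourhood projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .adaptive_search import rank_patterns
from .glm_engine import BetaMatrix

__all__ = [
    "DistanceMatrix",
    "Embedding",
    "CompromiseSpace",
    "correlation_distance_matrix",
    "mds_embed",
    "distatis",
    "procrustes_align",
    "bootstrap_ellipses",
    "project_neighbourhood",
]


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal matrix of 1 - Spearman rho distances."""

    D: np.ndarray
    ids: list
    metric: str = "1 - Spearman rho"

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=np.float64)
        if D.shape[0] != D.shape[1] or D.shape[0] != len(self.ids):
            raise ValueError("distance matrix / id length mismatch")
        if np.abs(D - D.T).max() > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(D)).max() > 1e-12:
            raise ValueError("distance matrix must have a zero diagonal")
        if D.min() < -1e-12 or D.max() > 2 + 1e-12:
            raise ValueError("correlation distances must lie in [0, 2]")
        self.D = D


def correlation_distance_matrix(betas: BetaMatrix, ids=None) -> DistanceMatrix:
    """All pairwise 1 - Spearman distances between stimulus beta patterns."""
    ids = list(ids) if ids is not None else betas.valid_stimulus_ids
    P = np.vstack([betas.pattern(s) for s in ids])
    if P.shape[1] < 3:
        raise ValueError("need at least 3 voxels")
    R = rank_patterns(P)
    R = R - R.mean(axis=1, keepdims=True)
    norms = np.sqrt((R**2).sum(axis=1))
    const = norms == 0
    if const.any():
        bad = [ids[i] for i in np.nonzero(const)[0]]
        raise ValueError(f"constant patterns for stimuli: {bad}")
    C = (R @ R.T) / np.outer(norms, norms)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D=np.clip((D + D.T) / 2.0, 0.0, 2.0), ids=ids)


@dataclass
class Embedding:
    coordinates: pd.DataFrame  # ids x dims
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    variance_explained: np.ndarray  # per kept dimension


def _double_centre(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D**2) @ J


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords


def mds_embed(dist: DistanceMatrix, d: int = 2) -> Embedding:
    """Classical (Torgerson) scaling of a distance matrix.

    Eigen-decomposes the double-centred squared distances; the top-``d``
    positive eigenpairs give coordinates whose Euclidean distances
    approximate the input.  Negative eigenvalues are reported but not
    embedded; variance explained is lambda_k / sum |lambda|.
    """
    D = dist.D
    n = D.shape[0]
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} items for a {d}-D embedding")
    if not D.any():
        raise ValueError("all-zero distance matrix")
    B = _double_centre(D)
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam = np.maximum(evals[:d], 0.0)
    coords = _fix_signs(evecs[:, :d] * np.sqrt(lam))
    total = np.abs(evals).sum()
    return Embedding(
        coordinates=pd.DataFrame(coords, index=dist.ids,
                                 columns=[f"dim{k + 1}" for k in range(d)]),
        eigenvalues=evals,
        variance_explained=lam / total if total > 0 else lam,
    )


@dataclass
class CompromiseSpace:
    """DISTATIS compromise: optimally weighted average representational space."""

    coordinates: pd.DataFrame  # ids x dims
    weights: np.ndarray  # per input table, >= 0, sum 1
    eigenvalues: np.ndarray  # of the compromise, non-increasing
    variance_explained: np.ndarray
    C: np.ndarray  # cross-table (Rv) similarity matrix
    first_eigenvalue: float  # lambda_1 of C
    first_eigenvalue_share: float  # lambda_1 / trace(C)


def distatis(d_list: list, d: int = 2) -> CompromiseSpace:
    """Three-way MDS: combine per-participant distance matrices optimally.

    Each table's double-centred cross-product matrix is normalised by its
    first eigenvalue; the Rv inner-product similarities between tables form
    ``C``, whose dominant eigenvector (rescaled to sum 1) weights the tables
    in the compromise.  The share of C's first eigenvalue in its trace
    summarises cross-participant consistency of the representational spaces.
    """
    if not d_list:
        raise ValueError("need at least one distance matrix")
    ids = d_list[0].ids
    for dm in d_list[1:]:
        if dm.ids != ids:
            raise ValueError("all distance matrices must share ids in order")
    S_list = []
    for dm in d_list:
        S = _double_centre(dm.D)
        evals = np.linalg.eigvalsh(S)
        lam1 = evals[-1]
        if evals[0] < -1e-8 * max(lam1, 1.0):
            import warnings

            warnings.warn("non-PSD cross-product matrix; clipping negative part")
            w, V = np.linalg.eigh(S)
            S = (V * np.maximum(w, 0.0)) @ V.T
            lam1 = max(np.max(w), 0.0)
        if lam1 <= 0:
            raise ValueError("degenerate (zero) cross-product matrix")
        S_list.append(S / lam1)

    P = len(S_list)
    C = np.empty((P, P))
    flat = [S.ravel() for S in S_list]
    norms = np.array([np.linalg.norm(f) for f in flat])
    for i in range(P):
        for j in range(i, P):
            C[i, j] = C[j, i] = (flat[i] @ flat[j]) / (norms[i] * norms[j])
    evals_C, evecs_C = np.linalg.eigh(C)
    lam1_C = float(evals_C[-1])
    u = evecs_C[:, -1]
    if u.sum() < 0:
        u = -u
    weights = u / u.sum()

    S_star = sum(w * S for w, S in zip(weights, S_list))
    evals, evecs = np.linalg.eigh(S_star)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam = np.maximum(evals[:d], 0.0)
    coords = _fix_signs(evecs[:, :d] * np.sqrt(lam))
    total = np.abs(evals).sum()
    return CompromiseSpace(
        coordinates=pd.DataFrame(coords, index=ids,
                                 columns=[f"dim{k + 1}" for k in range(d)]),
        weights=weights,
        eigenvalues=evals,
        variance_explained=lam / total if total > 0 else lam,
        C=C,
        first_eigenvalue=lam1_C,
        first_eigenvalue_share=lam1_C / float(np.trace(C)),
    )


def procrustes_align(X: np.ndarray, Y: np.ndarray, allow_reflection: bool = True,
                     scaling: bool = False):
    """Rigidly align Y to X (rotation, optional reflection, translation).

    Returns ``(Y_aligned, residual)`` with residual the Frobenius norm of
    ``X - Y_aligned``.  Scaling is off by default: representational spaces
    are aligned rigidly.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape != Y.shape:
        raise ValueError("configurations must have the same shape")
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    if not Xc.any() or not Yc.any():
        raise ValueError("degenerate configuration: all points coincide")
    U, s, Vt = np.linalg.svd(Yc.T @ Xc)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        U2 = U.copy()
        U2[:, -1] = -U2[:, -1]
        s = s.copy()
        s[-1] = -s[-1]
        R = U2 @ Vt
    scale = s.sum() / (Yc**2).sum() if scaling else 1.0
    Y_aligned = scale * Yc @ R + mx
    residual = float(np.linalg.norm(X - Y_aligned))
    return Y_aligned, residual


def bootstrap_ellipses(points: np.ndarray, n_boot: int = 1000, level: float = 0.95,
                       seed: int = 0) -> dict:
    """Confidence ellipse of a 2-D group mean by resampling units.

    ``points`` is units x 2 (e.g., per-participant neighbourhood-centre
    coordinates).  Units are resampled with replacement; the ellipse is
    built from the covariance of the bootstrap means with axes scaled by
    sqrt(chi2_level,2).
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be units x 2")
    n = pts.shape[0]
    if n < 3:
        raise ValueError("need at least 3 resampling units")
    if n_boot < 100:
        import warnings

        warnings.warn("fewer than 100 bootstrap resamples")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = pts[idx].mean(axis=1)
    centre = pts.mean(axis=0)
    cov = np.cov(boot_means.T)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    evals = np.maximum(evals, 0.0)
    scale = np.sqrt(_st.chi2.ppf(level, df=2))
    axes = scale * np.sqrt(evals[::-1])  # major first
    major = evecs[:, -1]
    angle = float(np.arctan2(major[1], major[0]))
    return {
        "centre": centre,
        "semi_axes": axes,
        "angle": angle,
        "covariance": cov,
        "boot_means": boot_means,
    }


def project_neighbourhood(compromise: CompromiseSpace, nn_ids_per_participant: dict):
    """Mean compromise coordinate of each participant's neighbourhood items.

    The referent's own distances are not comparable to those among the
    stimulus set, so its location is illustrated as the centroid of its
    neighbourhood on the embedding dimensions.  Returns ``(per_participant,
    group_mean)``.
    """
    coords = compromise.coordinates
    rows = {}
    for pid, ids in nn_ids_per_participant.items():
        if isinstance(ids, dict):
            ids = ids["neighbourhood"]
        ids = list(ids)
        unknown = [s for s in ids if s not in coords.index]
        if unknown:
            raise ValueError(f"neighbourhood ids missing from compromise: {unknown}")
        rows[pid] = coords.loc[ids].mean(axis=0)
    per_part = pd.DataFrame(rows).T
    return per_part, per_part.mean(axis=0)
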