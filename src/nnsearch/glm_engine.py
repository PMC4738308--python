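"""General linear model for ROI time series.

Builds design matrices from event boxcars convolved with the canonical
double-gamma haemodynamic response, adds per-run cosine high-pass drift
regressors (128 s cut-off), per-run motion covariates and per-run
constants, and fits ordinary least squares over the scans of all runs
included so far.  Each stimulus has one regressor formed from all of its
presentations across the included runs, so betas are cumulative
estimates that sharpen as the adaptive session progresses.

No temporal autocorrelation correction is applied (plain OLS); serially
correlated noise therefore inflates beta variance, which the downstream
permutation tests absorb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .design_schedule import REFERENT_ID, RunDesign

__all__ = [
    "HrfParams",
    "DesignMatrix",
    "BetaMatrix",
    "canonical_hrf",
    "highpass_basis",
    "build_design_matrix",
    "fit_betas",
]

#: Micro-time oversampling factor for boxcar convolution.
_OVERSAMPLE = 16


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma HRF parameters (seconds)."""

    response_delay: float = 6.0
    undershoot_delay: float = 16.0
    response_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 6.0
    length: float = 32.0

    def __post_init__(self) -> None:
        if min(self.response_delay, self.undershoot_delay,
               self.response_dispersion, self.undershoot_dispersion,
               self.undershoot_ratio, self.length) <= 0:
            raise ValueError("all HRF parameters must be positive")


def _double_gamma(t: np.ndarray, p: HrfParams) -> np.ndarray:
    from scipy.stats import gamma

    peak = gamma.pdf(t, p.response_delay / p.response_dispersion,
                     scale=p.response_dispersion)
    under = gamma.pdf(t, p.undershoot_delay / p.undershoot_dispersion,
                      scale=p.undershoot_dispersion)
    return peak - under / p.undershoot_ratio


def canonical_hrf(TR: float, params: HrfParams | None = None) -> np.ndarray:
    """Sample the canonical double-gamma kernel at TR, normalised to unit sum."""
    if TR <= 0:
        raise ValueError("TR must be positive")
    p = params or HrfParams()
    n = math.ceil(p.length / TR)
    t = np.arange(n) * TR
    h = _double_gamma(t, p)
    return h / h.sum()


def highpass_basis(n_scans: int, TR: float, cutoff: float = 128.0) -> np.ndarray:
    """Orthonormal discrete-cosine drift columns with period above the cut-off.

    The constant term is excluded (modelled separately per run).  The number
    of columns is floor(2 * n_scans * TR / cutoff).
    """
    if n_scans < 4:
        raise ValueError("need at least 4 scans")
    if cutoff == np.inf:
        return np.empty((n_scans, 0))
    k_max = int(np.floor(2.0 * n_scans * TR / cutoff))
    n = np.arange(n_scans)
    cols = [
        np.cos(np.pi * k * (2 * n + 1) / (2 * n_scans)) * np.sqrt(2.0 / n_scans)
        for k in range(1, k_max + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


@dataclass
class DesignMatrix:
    """Scans x regressors matrix with labelled columns and run boundaries."""

    X: np.ndarray
    labels: list
    stimulus_columns: dict  # stimulus id -> column index
    run_boundaries: list  # (start_scan, end_scan) per included run
    zero_presentation: list = field(default_factory=list)

    @property
    def n_scans(self) -> int:
        return self.X.shape[0]


def _convolved_regressor(
    events, n_scans: int, TR: float, hrf_micro: np.ndarray
) -> np.ndarray:
    """Boxcars for one item within one run, convolved at micro-time."""
    dt = TR / _OVERSAMPLE
    n_micro = n_scans * _OVERSAMPLE
    box = np.zeros(n_micro)
    for onset, duration in events:
        a = int(round(onset / dt))
        b = int(round((onset + duration) / dt))
        box[a:min(b, n_micro)] = 1.0
    conv = np.convolve(box, hrf_micro)[:n_micro]
    return conv[::_OVERSAMPLE]


def build_design_matrix(
    runs: list,
    stimulus_ids: list,
    TR: float,
    hrf_params: HrfParams | None = None,
    cutoff: float = 128.0,
    nuisance: list | None = None,
) -> DesignMatrix:
    """Design matrix over all included runs.

    ``runs`` are :class:`RunDesign` objects; ``stimulus_ids`` fixes the
    stimulus-regressor order (the referent column is always appended).
    Each stimulus regressor pools every presentation across the included
    runs; drift, motion and constant columns are per-run block-diagonal.
    ``nuisance`` optionally gives one scans x k covariate matrix per run.
    """
    if not runs:
        raise ValueError("need at least one run")
    if nuisance is not None and len(nuisance) != len(runs):
        raise ValueError("need one nuisance matrix per run (or None)")
    p = hrf_params or HrfParams()
    # Unit-sum micro-time kernel: a sustained boxcar plateaus at 1
    # regardless of the oversampling factor.
    hrf_micro = canonical_hrf(TR / _OVERSAMPLE, p)

    scans_per_run = [r.n_scans for r in runs]
    total = int(sum(scans_per_run))
    starts = np.concatenate([[0], np.cumsum(scans_per_run)]).astype(int)
    boundaries = [(int(starts[i]), int(starts[i + 1])) for i in range(len(runs))]

    item_ids = list(stimulus_ids) + [REFERENT_ID]
    kind_for = {REFERENT_ID: "referent"}

    columns: list = []
    labels: list = []

    # Stimulus + referent regressors (pooled over runs).
    stim_cols: dict = {}
    zero_pres: list = []
    for sid in item_ids:
        col = np.zeros(total)
        seen = False
        for run, (a, b) in zip(runs, boundaries):
            ev = [
                (e.onset, e.duration)
                for e in run.events
                if (e.kind == "referent" and sid == REFERENT_ID)
                or (e.kind == "stimulus" and e.stimulus_id == sid)
            ]
            if ev:
                seen = True
                col[a:b] = _convolved_regressor(ev, run.n_scans, TR, hrf_micro)
        stim_cols[sid] = len(columns)
        if not seen:
            zero_pres.append(sid)
        columns.append(col)
        labels.append(sid)

    # Per-run motion covariates (block diagonal).
    if nuisance is not None:
        for i, (cov, (a, b)) in enumerate(zip(nuisance, boundaries)):
            cov = np.asarray(cov, dtype=np.float64)
            if cov.ndim == 1:
                cov = cov[:, None]
            if cov.shape[0] != b - a:
                raise ValueError(f"nuisance for run {i + 1} has wrong scan count")
            cov = cov - cov.mean(axis=0)
            for j in range(cov.shape[1]):
                col = np.zeros(total)
                col[a:b] = cov[:, j]
                columns.append(col)
                labels.append(f"run{i + 1}_nuisance{j + 1}")

    # Per-run high-pass drift columns.
    for i, (run, (a, b)) in enumerate(zip(runs, boundaries)):
        drift = highpass_basis(run.n_scans, TR, cutoff)
        for j in range(drift.shape[1]):
            col = np.zeros(total)
            col[a:b] = drift[:, j]
            columns.append(col)
            labels.append(f"run{i + 1}_drift{j + 1}")

    # Per-run constants.
    for i, (a, b) in enumerate(boundaries):
        col = np.zeros(total)
        col[a:b] = 1.0
        columns.append(col)
        labels.append(f"run{i + 1}_constant")

    X = np.column_stack(columns)
    return DesignMatrix(
        X=X,
        labels=labels,
        stimulus_columns=stim_cols,
        run_boundaries=boundaries,
        zero_presentation=zero_pres,
    )


@dataclass
class BetaMatrix:
    """Per-item GLM estimates: items x voxels, addressable by stimulus id."""

    betas: np.ndarray
    item_ids: list
    residual_variance: np.ndarray
    invalid_items: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {sid: i for i, sid in enumerate(self.item_ids)}
        if REFERENT_ID not in self._index:
            raise ValueError("referent row missing from beta matrix")

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    def pattern(self, stimulus_id: str) -> np.ndarray:
        if stimulus_id in self.invalid_items:
            raise KeyError(f"no valid betas for {stimulus_id!r}")
        return self.betas[self._index[stimulus_id]]

    @property
    def valid_stimulus_ids(self) -> list:
        return [
            s for s in self.item_ids
            if s != REFERENT_ID and s not in self.invalid_items
        ]


def fit_betas(Y: np.ndarray, design: DesignMatrix) -> BetaMatrix:
    """Ordinary least squares fit of all voxels at once.

    ``Y`` is voxels x scans (stacked over the included runs, in run order).
    Betas for zero-presentation stimuli are undefined and flagged invalid.
    Raises if the stimulus columns are rank deficient beyond the flagged
    zero-presentation columns.
    """
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim != 2 or Y.shape[1] != design.n_scans:
        raise ValueError(
            f"Y must be voxels x {design.n_scans} scans, got {Y.shape}"
        )
    X = design.X
    keep = np.ones(X.shape[1], dtype=bool)
    for sid in design.zero_presentation:
        keep[design.stimulus_columns[sid]] = False
    Xk = X[:, keep]

    coef, _, rank, _ = np.linalg.lstsq(Xk, Y.T, rcond=None)
    if rank < Xk.shape[1]:
        # Identify colliding stimulus columns by correlating against others.
        stim_idx = [
            design.stimulus_columns[s]
            for s in design.stimulus_columns
            if s not in design.zero_presentation
        ]
        G = X[:, stim_idx]
        gram = G.T @ G
        norms = np.sqrt(np.diag(gram))
        corr = gram / np.outer(norms, norms)
        np.fill_diagonal(corr, 0.0)
        ii, jj = np.nonzero(np.abs(corr) > 1 - 1e-10)
        ids = list(design.stimulus_columns)
        pairs = sorted({tuple(sorted((ids[a], ids[b]))) for a, b in zip(ii, jj)})
        raise ValueError(f"rank-deficient design; colliding stimulus columns: {pairs}")

    full = np.full((X.shape[1], Y.shape[0]), np.nan)
    full[keep] = coef
    resid = Y.T - Xk @ coef
    dof = max(design.n_scans - int(rank), 1)
    resid_var = (resid**2).sum(axis=0) / dof

    item_ids = list(design.stimulus_columns)
    rows = np.array([design.stimulus_columns[s] for s in item_ids])
    return BetaMatrix(
        betas=full[rows],
        item_ids=item_ids,
        residual_variance=resid_var,
        invalid_items=list(design.zero_presentation),
    )
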