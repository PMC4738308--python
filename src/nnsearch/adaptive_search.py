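"""Closed-loop adaptive search for the neural neighbourhood of a referent.

After each run, every item's cumulative beta pattern is compared to the
referent's by Spearman correlation across voxels; the most similar items
form the next (smaller) run, following the shrinking schedule.  The final
neighbourhood is the top ten items of the similarity vector computed after
the last run's cumulative fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .design_schedule import (
    REFERENT_ID,
    SessionDesign,
    TimingConfig,
    build_session,
)
from .glm_engine import BetaMatrix, HrfParams, build_design_matrix, fit_betas

__all__ = [
    "SimilarityVector",
    "NeighbourhoodResult",
    "spearman",
    "rank_patterns",
    "rank_by_similarity",
    "select_subset",
    "run_adaptive_session",
]

NN_SIZE = 10


def rank_patterns(x: np.ndarray) -> np.ndarray:
    """Average ranks (ties share their mean rank), along the last axis."""
    x = np.asarray(x, dtype=np.float64)
    order = np.argsort(x, axis=-1, kind="stable")
    ranks = np.empty_like(x)
    rng_idx = np.arange(1, x.shape[-1] + 1, dtype=np.float64)
    np.put_along_axis(ranks, order, np.broadcast_to(rng_idx, x.shape), axis=-1)
    # average ties
    sorted_x = np.take_along_axis(x, order, axis=-1)
    if x.ndim == 1:
        ranks = _average_ties(sorted_x, ranks, order)
    else:
        flatr = ranks.reshape(-1, x.shape[-1])
        flats = sorted_x.reshape(-1, x.shape[-1])
        flato = order.reshape(-1, x.shape[-1])
        for i in range(flatr.shape[0]):
            flatr[i] = _average_ties(flats[i], flatr[i], flato[i])
        ranks = flatr.reshape(x.shape)
    return ranks


def _average_ties(sorted_x, ranks, order):
    out = ranks.copy()
    n = len(sorted_x)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        if j > i:
            mean_rank = (i + j) / 2.0 + 1.0
            out[order[i:j + 1]] = mean_rank
        i = j + 1
    return out


def spearman(pattern_a: np.ndarray, pattern_b: np.ndarray) -> float:
    """Spearman rho: Pearson correlation of average-ranked values."""
    a = np.asarray(pattern_a, dtype=np.float64)
    b = np.asarray(pattern_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("patterns must be 1-D and equal length")
    if a.size < 3:
        raise ValueError("need at least 3 voxels")
    ra, rb = rank_patterns(a), rank_patterns(b)
    if ra.std() == 0 or rb.std() == 0:
        raise ValueError("Spearman undefined for constant patterns")
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))


@dataclass
class SimilarityVector:
    """Spearman rho with the referent pattern, per stimulus, at one iteration."""

    rho: dict  # stimulus id -> rho
    iteration: int

    def __post_init__(self) -> None:
        bad = {s: r for s, r in self.rho.items() if not -1 - 1e-12 <= r <= 1 + 1e-12}
        if bad:
            raise ValueError(f"rho outside [-1, 1]: {bad}")

    def sorted_ids(self) -> list:
        """Stimulus ids by descending rho, ties broken by ascending id."""
        return [s for s, _ in sorted(self.rho.items(), key=lambda kv: (-kv[1], kv[0]))]


def rank_by_similarity(betas: BetaMatrix, referent_id: str = REFERENT_ID,
                       iteration: int = 0) -> SimilarityVector:
    """Spearman similarity of every valid stimulus pattern to the referent's."""
    ref = betas.pattern(referent_id)
    if ref.size < 3:
        raise ValueError("need at least 3 voxels")
    rho = {}
    ref_rank = rank_patterns(ref)
    ref_c = ref_rank - ref_rank.mean()
    ref_ss = ref_c @ ref_c
    if ref_ss == 0:
        raise ValueError("referent pattern is constant")
    for sid in betas.valid_stimulus_ids:
        r = rank_patterns(betas.pattern(sid))
        rc = r - r.mean()
        ss = rc @ rc
        if ss == 0:
            raise ValueError(f"constant pattern for stimulus {sid!r}")
        rho[sid] = float((ref_c @ rc) / np.sqrt(ref_ss * ss))
    return SimilarityVector(rho=rho, iteration=iteration)


def select_subset(sims: SimilarityVector, k: int) -> list:
    """The k most referent-similar stimuli; boundary ties broken by id."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(sims.rho):
        raise ValueError(f"cannot select {k} from {len(sims.rho)} similarities")
    return sims.sorted_ids()[:k]


@dataclass
class NeighbourhoodResult:
    """Outcome of one adaptive session."""

    neighbourhood: list  # final NN stimulus ids
    final_similarity: SimilarityVector
    selection_history: list  # per-iteration selected subsets (run 2 onward)
    similarity_history: list = field(default_factory=list)
    condition: str = "perception"
    participant_id: str | None = None
    first_run_betas: BetaMatrix | None = None  # kept only on request
    final_betas: BetaMatrix | None = None

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "condition": self.condition,
            "neighbourhood": list(self.neighbourhood),
            "final_similarity": dict(self.final_similarity.rho),
            "selection_history": [list(s) for s in self.selection_history],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NeighbourhoodResult":
        d = json.loads(Path(path).read_text())
        final = SimilarityVector(rho=d["final_similarity"],
                                 iteration=len(d["selection_history"]) + 1)
        return cls(
            neighbourhood=d["neighbourhood"],
            final_similarity=final,
            selection_history=d["selection_history"],
            condition=d["condition"],
            participant_id=d["participant_id"],
        )


def run_adaptive_session(
    data_source,
    schedule,
    condition: str = "perception",
    seed: int = 0,
    stimulus_ids=None,
    timing_cfg: TimingConfig | None = None,
    hrf_params: HrfParams | None = None,
    cutoff: float = 128.0,
    nn_size: int = NN_SIZE,
    referent_id: str = REFERENT_ID,
    keep_betas: bool = False,
) -> NeighbourhoodResult:
    """Run the full closed loop over one session.

    ``data_source`` is a callable mapping a :class:`RunDesign` to a pair
    ``(Y, nuisance)`` where ``Y`` is voxels x scans and ``nuisance`` is a
    scans x k covariate matrix (or None) — either a simulator or a replay
    of recorded runs.  Run 1 presents every stimulus; after each run a
    cumulative GLM is fitted over all runs so far and the next subset of
    the schedule is selected by referent similarity.
    """
    schedule = tuple(schedule)
    if nn_size > schedule[-1]:
        raise ValueError(
            f"final neighbourhood size {nn_size} exceeds last run size {schedule[-1]}"
        )
    session: SessionDesign = build_session(
        schedule, condition, timing_cfg, seed=seed, stimulus_ids=stimulus_ids
    )
    all_ids = session.runs[0].stimulus_ids
    TR = session.timing.TR

    ys: list = []
    covs: list = []
    selection_history: list = []
    similarity_history: list = []
    sims = None

    for k in range(len(schedule)):
        if k > 0:
            subset = select_subset(sims, schedule[k])
            selection_history.append(subset)
            session.add_run(subset)
        run = session.runs[k]
        out = data_source(run)
        if hasattr(out, "data"):  # RoiTimeseries-like
            Y, nuis = out.data, getattr(out, "nuisance", None)
        else:
            Y, nuis = out
        Y = np.asarray(Y, dtype=np.float64)
        if Y.shape[1] != run.n_scans:
            raise ValueError(
                f"data source returned {Y.shape[1]} scans for run {run.run_index}, "
                f"expected {run.n_scans}"
            )
        ys.append(Y)
        covs.append(nuis)

        design = build_design_matrix(
            session.runs[: k + 1],
            sorted(all_ids),
            TR,
            hrf_params=hrf_params,
            cutoff=cutoff,
            nuisance=None if all(c is None for c in covs) else [
                c if c is not None else np.empty((y.shape[1], 0))
                for c, y in zip(covs, ys)
            ],
        )
        betas = fit_betas(np.concatenate(ys, axis=1), design)
        if k == 0:
            first_betas = betas
        sims = rank_by_similarity(betas, referent_id, iteration=k + 1)
        similarity_history.append(sims)

    neighbourhood = select_subset(sims, nn_size)
    return NeighbourhoodResult(
        neighbourhood=neighbourhood,
        final_similarity=sims,
        selection_history=selection_history,
        similarity_history=similarity_history,
        condition=condition,
        first_run_betas=first_betas if keep_betas else None,
        final_betas=betas if keep_betas else None,
    )
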