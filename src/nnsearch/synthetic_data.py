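"""Synthetic stimulus sets, tuned participants and ROI BOLD simulation.

Everything downstream of image acquisition can be exercised without any
real data: parametric shape images with traced masks (so the sensory
features span a wide range), a latent category model for the rated
semantic/emotional features, a linear feature -> voxel-pattern tuning
model per participant, and BOLD run simulation as the convolved true
design plus cosine drift and AR(1) Gaussian noise.

The tuning model is the minimal structure under which the analyses are
well-posed: a participant's pattern for stimulus *s* is ``W f_s + b``
where the columns of ``W`` carry the planted per-feature tuning
strengths.  A ground-truth neighbourhood (top items by noiseless
Spearman similarity to the referent pattern, ties broken by ascending
stimulus id) acts as the oracle for parameter-recovery tests.

Two simulation depths are provided:

* :func:`simulate_run` — full BOLD time series, fed to the GLM and the
  closed loop (used for recovery and oracle-equivalence suites).
* :func:`sample_neighbourhoods` — noiseless pattern similarities plus
  Gaussian similarity noise, then top-k (used for large replicate
  calibration and power studies, where re-simulating BOLD adds nothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse
from skimage.draw import polygon as _draw_polygon

from .adaptive_search import rank_patterns
from .design_schedule import REFERENT_ID, RunDesign
from .glm_engine import HrfParams, build_design_matrix, highpass_basis
from .stimulus_features import (
    EMOTIONAL_FEATURES,
    SEMANTIC_FEATURES,
    FeatureTable,
    build_feature_table,
    compute_sensory_features,
    zscore_columns,
)

__all__ = [
    "StimulusSet",
    "TuningModel",
    "GroundTruth",
    "Participant",
    "NoiseConfig",
    "CohortSpec",
    "generate_stimulus_set",
    "generate_participant",
    "simulate_run",
    "make_data_source",
    "generate_cohort",
    "sample_neighbourhoods",
]


# --------------------------------------------------------------------------
# Stimulus set
# --------------------------------------------------------------------------

@dataclass
class StimulusSet:
    """Images, masks, category labels and rated features for all stimuli.

    The referent is a 201st stimulus held out of the comparison set; its
    image/ratings are stored separately under the reserved id "REF".
    """

    images: dict
    masks: dict
    categories: pd.Series
    semantic: pd.DataFrame
    emotional: pd.DataFrame
    referent_image: np.ndarray
    referent_mask: np.ndarray
    referent_semantic: pd.Series
    referent_emotional: pd.Series
    seed: int

    @property
    def stimulus_ids(self) -> list:
        return sorted(self.images)

    def feature_table(self, standardized: bool = False) -> FeatureTable:
        sensory = compute_sensory_features(self.images, self.masks)
        table = build_feature_table(sensory, self.semantic, self.emotional)
        return zscore_columns(table) if standardized else table

    def referent_features(self, table: FeatureTable) -> pd.Series:
        """Referent feature vector on the (possibly z-scored) table's scale."""
        sensory = compute_sensory_features(
            {REFERENT_ID: self.referent_image}, {REFERENT_ID: self.referent_mask}
        ).loc[REFERENT_ID]
        raw = pd.concat([sensory, self.referent_semantic, self.referent_emotional])
        raw = raw[table.feature_names]
        if not table.standardized:
            return raw
        base = build_feature_table(
            compute_sensory_features(self.images, self.masks),
            self.semantic,
            self.emotional,
        ).values
        return (raw - base.mean()) / base.std(ddof=1)


def _draw_shape(canvas, mask, rng, centre, size, elongation, angle, colour, kind):
    h, w = mask.shape
    r0, c0 = centre
    a = size * elongation
    b = size / elongation
    if kind == "ellipse":
        rr, cc = _draw_ellipse(r0, c0, a, b, shape=(h, w), rotation=angle)
    elif kind == "rectangle":
        corners = np.array(
            [[-a, -b], [-a, b], [a, b], [a, -b]], dtype=np.float64
        )
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        pts = corners @ rot.T + np.array([r0, c0])
        rr, cc = _draw_polygon(pts[:, 0], pts[:, 1], shape=(h, w))
    else:  # blob: union of three jittered ellipses
        rr_list, cc_list = [], []
        for _ in range(3):
            dr, dc = rng.normal(scale=size / 3, size=2)
            e = _draw_ellipse(r0 + dr, c0 + dc, a * 0.7, b * 0.7,
                              shape=(h, w), rotation=angle + rng.normal(scale=0.5))
            rr_list.append(e[0])
            cc_list.append(e[1])
        rr = np.concatenate(rr_list)
        cc = np.concatenate(cc_list)
    canvas[rr, cc] = colour
    mask[rr, cc] = True


def _render_stimulus(rng, params, img_size: int = 64):
    """Render one parametric shape stimulus; returns (rgb float image, mask)."""
    bg = params["background"]
    canvas = np.full((img_size, img_size, 3), bg, dtype=np.float64)
    mask = np.zeros((img_size, img_size), dtype=bool)
    n_obj = params["n_objects"]
    for i in range(n_obj):
        centre = (
            img_size / 2 + rng.normal(scale=img_size / 8),
            img_size * (i + 1) / (n_obj + 1) + rng.normal(scale=img_size / 12),
        )
        _draw_shape(
            canvas, mask, rng, centre,
            size=params["size"] * img_size / (2.2 + 0.8 * n_obj),
            elongation=params["elongation"],
            angle=params["angle"],
            colour=params["colour"],
            kind=params["shape"],
        )
    if not mask.any():  # degenerate draw: guarantee a visible object
        _draw_shape(canvas, mask, rng, (img_size / 2, img_size / 2),
                    size=img_size / 5, elongation=params["elongation"],
                    angle=params["angle"], colour=params["colour"],
                    kind="ellipse")
    if mask.all():
        mask[0, :] = False  # keep some background for contrast features
        canvas[0, :] = bg
    # texture inside the object drives JPEG complexity
    noise = rng.normal(scale=params["texture"], size=canvas.shape)
    canvas[mask] += noise[mask]
    return np.clip(canvas, 0.0, 1.0), mask


def _likert(latent: np.ndarray, lo: int = 1, hi: int = 5) -> np.ndarray:
    """Map latent normals to an integer rating scale via equiprobable bins."""
    from scipy.stats import norm

    n_levels = hi - lo + 1
    edges = norm.ppf(np.linspace(0, 1, n_levels + 1)[1:-1])
    return (lo + np.searchsorted(edges, latent)).astype(int)


def generate_stimulus_set(
    n_categories: int = 100,
    per_category: int = 2,
    seed: int = 0,
    img_size: int = 64,
) -> StimulusSet:
    """Parametric stimulus set: two exemplars from each of 100 categories.

    Category-level latents give the rated features block structure
    (animacy in {0, 1, 2}; valence/arousal/motion correlated with
    animacy; graded associations with each referent), while the shape
    parameters vary the computed sensory features widely.
    """
    if n_categories * per_category < 20:
        raise ValueError("need at least 20 stimuli")
    rng = np.random.default_rng(seed)

    shapes = ("ellipse", "rectangle", "blob")
    animacy_levels = rng.permuted(np.arange(n_categories) % 3)

    images: dict = {}
    masks: dict = {}
    cats: dict = {}
    sem_rows: dict = {}
    emo_rows: dict = {}

    def make_one(sid, cat_idx, cat_latents):
        params = {
            "background": rng.uniform(0.15, 0.85),
            "colour": rng.uniform(0.0, 1.0, size=3),
            "size": rng.uniform(0.5, 1.1),
            "elongation": np.exp(rng.uniform(-1.0, 1.0)),
            "angle": rng.uniform(0, np.pi),
            "shape": shapes[cat_idx % 3],
            "texture": rng.uniform(0.0, 0.35),
            "n_objects": int(rng.integers(1, 4)),
        }
        img, mask = _render_stimulus(rng, params, img_size)
        jitter = rng.normal(scale=0.5, size=5)
        animacy = animacy_levels[cat_idx]
        sem = {
            "real_world_size": int(_likert(np.array([cat_latents[0] + jitter[0]]))[0]),
            "object_number": int(np.clip(params["n_objects"] - 1, 0, 2)),
            "animacy": int(animacy),
            "association_referent_1": int(_likert(np.array([cat_latents[1] + jitter[1]]))[0]),
            "association_referent_2": int(_likert(np.array([cat_latents[2] + jitter[2]]))[0]),
            "implied_motion": int(_likert(np.array([
                0.8 * (animacy - 1) + 0.6 * cat_latents[3] + jitter[3]]))[0]),
        }
        emo = {
            "valence": int(_likert(np.array([cat_latents[4] + jitter[4]]))[0]),
            "arousal": int(_likert(np.array([
                0.6 * cat_latents[3] + 0.4 * (animacy - 1) + rng.normal(scale=0.5)]))[0]),
        }
        return img, mask, sem, emo

    for c in range(n_categories):
        cat_latents = rng.normal(size=5)
        for e in range(per_category):
            sid = f"stim{c * per_category + e:03d}"
            img, mask, sem, emo = make_one(sid, c, cat_latents)
            images[sid] = img
            masks[sid] = mask
            cats[sid] = f"cat{c:03d}"
            sem_rows[sid] = sem
            emo_rows[sid] = emo

    ref_img, ref_mask, ref_sem, ref_emo = make_one(
        REFERENT_ID, int(rng.integers(n_categories)), rng.normal(size=5)
    )
    order = sorted(images)
    return StimulusSet(
        images=images,
        masks=masks,
        categories=pd.Series(cats).loc[order],
        semantic=pd.DataFrame.from_dict(sem_rows, orient="index").loc[order, list(SEMANTIC_FEATURES)],
        emotional=pd.DataFrame.from_dict(emo_rows, orient="index").loc[order, list(EMOTIONAL_FEATURES)],
        referent_image=ref_img,
        referent_mask=ref_mask,
        referent_semantic=pd.Series(ref_sem)[list(SEMANTIC_FEATURES)],
        referent_emotional=pd.Series(ref_emo)[list(EMOTIONAL_FEATURES)],
        seed=seed,
    )


# --------------------------------------------------------------------------
# Tuning models and ground truth
# --------------------------------------------------------------------------

@dataclass
class TuningModel:
    """Linear feature -> pattern map for one participant and condition."""

    W: np.ndarray  # voxels x features
    strengths: dict  # feature -> tuning strength (scale of its W column)
    baseline: np.ndarray  # voxels
    feature_names: list
    seed: int | None = None


@dataclass
class GroundTruth:
    """Noiseless patterns and the brute-force neighbourhood they imply."""

    patterns: pd.DataFrame  # items (incl. REF) x voxels
    true_similarity: pd.Series  # stimulus id -> noiseless Spearman rho with REF
    true_neighbourhood: list  # top-k ids, ties broken by ascending id
    nn_size: int

    @classmethod
    def from_model(cls, model: TuningModel, table: FeatureTable,
                   referent_features: pd.Series, nn_size: int = 10) -> "GroundTruth":
        F = table.values[model.feature_names].to_numpy(dtype=np.float64)
        ids = table.stimulus_ids
        pats = F @ model.W.T + model.baseline  # items x voxels
        ref = model.W @ referent_features[model.feature_names].to_numpy(dtype=np.float64) \
            + model.baseline
        all_pats = np.vstack([pats, ref])
        ranks = rank_patterns(all_pats)
        ranks = ranks - ranks.mean(axis=1, keepdims=True)
        norms = np.sqrt((ranks**2).sum(axis=1))
        norms[norms == 0] = 1.0
        rho = (ranks[:-1] @ ranks[-1]) / (norms[:-1] * norms[-1])
        sims = pd.Series(rho, index=ids)
        nn = sorted(sorted(ids), key=lambda s: (-sims[s], s))[:nn_size]
        patterns = pd.DataFrame(all_pats, index=ids + [REFERENT_ID])
        return cls(patterns=patterns, true_similarity=sims,
                   true_neighbourhood=nn, nn_size=nn_size)


@dataclass
class Participant:
    """One synthetic participant: tuning per condition plus noise traits."""

    id: str
    n_voxels: int
    tuning: dict  # condition -> TuningModel
    noise_sd: float
    ar1: float
    vviq: int
    seed: int

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if not -1 < self.ar1 < 1:
            raise ValueError("|AR(1) coefficient| must be < 1")
        if not 16 <= self.vviq <= 80:
            raise ValueError("VVIQ total must lie in 16..80")


def generate_participant(
    table: FeatureTable,
    referent_features,
    tuning_spec: dict,
    n_voxels: int | None = None,
    noise_sd: float = 1.0,
    ar1: float = 0.3,
    vviq: int = 48,
    nn_size: int = 10,
    seed: int = 0,
    participant_id: str = "sub-01",
) -> tuple:
    """Draw one participant and the ground truth their tuning implies.

    ``tuning_spec`` maps condition name -> {feature: strength}; features
    absent from a condition's dict get a zero column in that condition's
    ``W``.  Both conditions share random tuning directions and baseline,
    so condition contrasts isolate the planted strength differences.
    ``referent_features`` is a Series on the table's feature scale, or a
    dict condition -> Series when the imagined referent differs from the
    perceived one (participants can imagine the same object with
    different feature content).  Default voxel count is drawn from the
    223-371 range typical of an occipitotemporal ROI.
    """
    if not table.standardized:
        table = zscore_columns(table)
    if not isinstance(referent_features, dict):
        referent_features = {cond: referent_features for cond in tuning_spec}
    rng = np.random.default_rng(seed)
    V = int(n_voxels) if n_voxels is not None else int(rng.integers(223, 372))
    feats = table.feature_names
    for cond, strengths in tuning_spec.items():
        unknown = sorted(set(strengths) - set(feats))
        if unknown:
            raise ValueError(f"tuning features not in table ({cond}): {unknown}")

    U = rng.normal(size=(V, len(feats)))  # shared unit-variance directions
    baseline = rng.normal(size=V)
    tuning = {}
    truths = {}
    for cond, strengths in tuning_spec.items():
        scale = np.array([strengths.get(f, 0.0) for f in feats])
        model = TuningModel(W=U * scale, strengths=dict(strengths),
                            baseline=baseline, feature_names=feats, seed=seed)
        tuning[cond] = model
        truths[cond] = GroundTruth.from_model(model, table, referent_features[cond],
                                              nn_size)

    participant = Participant(
        id=participant_id, n_voxels=V, tuning=tuning,
        noise_sd=noise_sd, ar1=ar1, vviq=vviq, seed=seed,
    )
    return participant, truths


# --------------------------------------------------------------------------
# BOLD simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseConfig:
    """Additive noise structure of a simulated run."""

    sd: float = 1.0
    ar1: float = 0.3
    drift_amplitude: float = 0.0
    motion_step_sd: float = 0.02
    cutoff: float = 128.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise SD must be >= 0")
        if not -1 < self.ar1 < 1:
            raise ValueError("|ar1| must be < 1")


def _ar1_noise(rng, shape, sd, ar1):
    if sd == 0:
        return np.zeros(shape)
    innov = rng.normal(scale=sd, size=shape)
    out = np.empty(shape)
    out[..., 0] = innov[..., 0]
    c = np.sqrt(1.0 - ar1**2)
    for t in range(1, shape[-1]):
        out[..., t] = ar1 * out[..., t - 1] + c * innov[..., t]
    return out


def simulate_run(
    run: RunDesign,
    ground_truth: GroundTruth,
    noise_cfg: NoiseConfig | None = None,
    seed: int = 0,
    hrf_params: HrfParams | None = None,
) -> tuple:
    """Simulate one ROI run: true design times true patterns plus noise.

    Returns ``(Y, nuisance)``: ``Y`` voxels x scans, ``nuisance`` scans x 6
    synthetic motion covariates (smooth random walks; used downstream only
    as nuisance regressors).  The boxcar design is convolved with the same
    canonical HRF the GLM uses, so at zero noise the GLM recovers the true
    patterns exactly.
    """
    cfg = noise_cfg or NoiseConfig()
    if run.TR <= 0:
        raise ValueError("TR must be positive")
    rng = np.random.default_rng(seed)

    present = sorted(set(run.stimulus_ids))
    design = build_design_matrix([run], present, run.TR,
                                 hrf_params=hrf_params, cutoff=np.inf)
    item_ids = [sid for sid in present + [REFERENT_ID]
                if sid not in design.zero_presentation]
    Xs = np.column_stack([design.X[:, design.stimulus_columns[s]] for s in item_ids])
    B = ground_truth.patterns.loc[item_ids].to_numpy(dtype=np.float64)
    Y = (Xs @ B).T  # voxels x scans

    V = Y.shape[0]
    if cfg.drift_amplitude > 0:
        basis = highpass_basis(run.n_scans, run.TR, cfg.cutoff)
        if basis.shape[1]:
            Y += (basis @ rng.normal(scale=cfg.drift_amplitude,
                                     size=(basis.shape[1], V))).T
    Y += _ar1_noise(rng, (V, run.n_scans), cfg.sd, cfg.ar1)

    steps = rng.normal(scale=cfg.motion_step_sd, size=(run.n_scans, 6))
    kernel = np.ones(5) / 5.0
    motion = np.cumsum(steps, axis=0)
    motion = np.column_stack([
        np.convolve(motion[:, j], kernel, mode="same") for j in range(6)
    ])
    return Y, motion


def make_data_source(ground_truth: GroundTruth, noise_cfg: NoiseConfig | None = None,
                     seed: int = 0, hrf_params: HrfParams | None = None):
    """Callable RunDesign -> (Y, nuisance) for :func:`run_adaptive_session`.

    Per-run seeds derive from ``seed`` and the run index, so identical
    schedules replay identical data.
    """

    def source(run: RunDesign):
        run_seed = np.random.SeedSequence([seed, run.run_index]).generate_state(1)[0]
        return simulate_run(run, ground_truth, noise_cfg, seed=int(run_seed),
                            hrf_params=hrf_params)

    return source


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Condition-specific planted tuning for a whole participant group.

    ``mixture`` optionally makes participants imagine the referent with one
    of two feature values (for bimodality studies): ``(feature, value_a,
    value_b, p_a)`` replaces that feature of the *imagined* referent.  A
    sign flip of the tuning strength itself would leave neighbourhoods
    unchanged (rank similarity orders items by |f - f_ref| under the shared
    linear model), so across-participant clusters require differing
    imagined content.  ``vviq_link`` makes one feature's imagery strength a
    monotone function of VVIQ: ``(feature, intercept, slope)`` gives
    ``a + b * (VVIQ - mean VVIQ)``; a negative slope mirrors the
    empirically weaker tuning of vivid imagers.
    """

    n_participants: int = 21
    perception_tuning: dict = field(default_factory=dict)
    imagery_tuning: dict = field(default_factory=dict)
    mixture: tuple | None = None
    vviq_link: tuple | None = None
    n_voxels: int | None = None
    noise_sd: float = 1.0
    ar1: float = 0.3
    nn_size: int = 10


@dataclass
class Cohort:
    participants: list  # Participant
    truths: list  # dict condition -> GroundTruth, parallel to participants
    table: FeatureTable  # z-scored
    referent_features: pd.Series
    spec: CohortSpec
    seed: int

    @property
    def vviq(self) -> np.ndarray:
        return np.array([p.vviq for p in self.participants])


def generate_cohort(
    table: FeatureTable,
    referent_features: pd.Series,
    spec: CohortSpec | None = None,
    seed: int = 0,
) -> Cohort:
    """Draw a full two-condition cohort ready for the pipeline."""
    spec = spec or CohortSpec()
    if not table.standardized:
        table = zscore_columns(table)
    rng = np.random.default_rng(seed)
    vviq = rng.integers(25, 76, size=spec.n_participants)
    vviq_c = vviq - vviq.mean()

    participants = []
    truths = []
    for i in range(spec.n_participants):
        imagery = dict(spec.imagery_tuning)
        ref_by_cond = {"perception": referent_features, "imagery": referent_features}
        if spec.mixture is not None:
            feat, val_a, val_b, p_a = spec.mixture
            imagined = referent_features.copy()
            imagined[feat] = val_a if rng.random() < p_a else val_b
            ref_by_cond["imagery"] = imagined
        if spec.vviq_link is not None:
            feat, a, b = spec.vviq_link
            imagery[feat] = a + b * float(vviq_c[i])
        p_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        participant, truth = generate_participant(
            table,
            ref_by_cond,
            {"perception": dict(spec.perception_tuning), "imagery": imagery},
            n_voxels=spec.n_voxels,
            noise_sd=spec.noise_sd,
            ar1=spec.ar1,
            vviq=int(vviq[i]),
            nn_size=spec.nn_size,
            seed=p_seed,
            participant_id=f"sub-{i + 1:02d}",
        )
        participants.append(participant)
        truths.append(truth)
    return Cohort(participants=participants, truths=truths, table=table,
                  referent_features=referent_features, spec=spec, seed=seed)


def sample_neighbourhoods(
    cohort: Cohort,
    condition: str,
    sim_noise_sd: float = 0.0,
    nn_size: int | None = None,
    seed: int = 0,
) -> dict:
    """Neighbourhood-level simulation: noisy similarity ranking, then top-k.

    Each participant's observed similarity vector is their noiseless
    pattern similarity plus iid Gaussian noise of SD ``sim_noise_sd``;
    the neighbourhood is its top ``nn_size`` (ties by ascending id).
    Returns {participant id: {"neighbourhood": [...], "similarity": Series}}.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for participant, truth in zip(cohort.participants, cohort.truths):
        gt = truth[condition]
        k = nn_size if nn_size is not None else gt.nn_size
        sims = gt.true_similarity + rng.normal(scale=sim_noise_sd,
                                               size=len(gt.true_similarity))
        ids = list(sims.index)
        nn = sorted(ids, key=lambda s: (-sims[s], s))[:k]
        out[participant.id] = {"neighbourhood": nn, "similarity": sims}
    return out
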