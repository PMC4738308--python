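"""Offline feature-tuning statistics for neural neighbourhoods.

Whether a stimulus enters the referent's neighbourhood is treated as a
binary outcome to be predicted from its features: a diagonal-covariance,
class-specific-variance Gaussian classifier ("diagonal quadratic" naive
Bayes) is trained leave-one-item-out, pooling items over participants,
and summarised by the bias-free sensitivity d' = Phi^-1(hit rate) -
Phi^-1(false-alarm rate).  Chance is calibrated by a permutation null
that reshuffles neighbourhood labels within participant, preserving the
10-in / 190-out class counts; testing proceeds hierarchically (feature
sets, then features within significant sets) with Holm-Bonferroni
control inside each branch.  Direction of tuning is assessed by the mean
z-scored feature value over each participant's ten neighbourhood items,
compared to zero across participants.  A pairwise identity-decoding
check (linear SVM, leave-one-run-out) quantifies pattern reliability
across repeated presentations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .design_schedule import REFERENT_ID
from .glm_engine import BetaMatrix, build_design_matrix, fit_betas
from .stimulus_features import FeatureTable

__all__ = [
    "GaussianDiscriminant",
    "DprimeResult",
    "PermutationNull",
    "TuningReport",
    "membership_from_neighbourhoods",
    "dprime_from_rates",
    "gaussian_discriminant",
    "loo_dprime",
    "permutation_null",
    "holm_reject",
    "hierarchical_feature_tests",
    "mean_nn_feature",
    "tuning_contrast",
    "fit_per_run_betas",
    "pairwise_identity_decode",
    "group_identity_decode",
]

_VAR_FLOOR_FRAC = 1e-6


# --------------------------------------------------------------------------
# Classifier
# --------------------------------------------------------------------------

@dataclass
class GaussianDiscriminant:
    """Class-conditional diagonal Gaussians with class-specific variances."""

    means: np.ndarray  # 2 x F
    variances: np.ndarray  # 2 x F (floored)
    log_priors: np.ndarray  # 2

    def log_posterior(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        out = np.empty((X.shape[0], 2))
        for c in range(2):
            z = (X - self.means[c]) ** 2 / self.variances[c]
            out[:, c] = self.log_priors[c] - 0.5 * (
                np.log(2 * np.pi * self.variances[c]).sum() + z.sum(axis=1)
            )
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        lp = self.log_posterior(X)
        return (lp[:, 1] > lp[:, 0]).astype(int)


def gaussian_discriminant(
    X: np.ndarray, y: np.ndarray, priors: str = "uniform",
    var_floor_frac: float = _VAR_FLOOR_FRAC,
) -> GaussianDiscriminant:
    """Fit the diagonal quadratic classifier on labelled feature vectors."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y lengths differ")
    if priors not in ("empirical", "uniform"):
        raise ValueError("priors must be 'empirical' or 'uniform'")
    counts = np.array([(y == 0).sum(), (y == 1).sum()])
    if (counts < 2).any():
        raise ValueError("need at least 2 training samples in each class")
    pooled = X.var(axis=0, ddof=1)
    floor = var_floor_frac * np.where(pooled > 0, pooled, 1.0)
    means = np.stack([X[y == c].mean(axis=0) for c in (0, 1)])
    variances = np.stack([
        np.maximum(X[y == c].var(axis=0, ddof=1), floor) for c in (0, 1)
    ])
    if priors == "empirical":
        log_priors = np.log(counts / counts.sum())
    else:
        log_priors = np.log(np.array([0.5, 0.5]))
    return GaussianDiscriminant(means=means, variances=variances, log_priors=log_priors)


# --------------------------------------------------------------------------
# Membership labels and d'
# --------------------------------------------------------------------------

def membership_from_neighbourhoods(neighbourhoods: dict, stimulus_ids) -> pd.DataFrame:
    """Boolean items x participants membership table.

    ``neighbourhoods`` maps participant id -> iterable of in-NN stimulus ids
    (or the dicts produced by ``sample_neighbourhoods``).
    """
    ids = list(stimulus_ids)
    cols = {}
    for pid, nn in neighbourhoods.items():
        if isinstance(nn, dict):
            nn = nn["neighbourhood"]
        nn = set(nn)
        unknown = nn - set(ids)
        if unknown:
            raise ValueError(f"unknown neighbourhood ids for {pid}: {sorted(unknown)}")
        cols[pid] = [s in nn for s in ids]
    return pd.DataFrame(cols, index=ids, dtype=bool)


def dprime_from_rates(hit: float, fa: float, n_pos: int | None = None,
                      n_neg: int | None = None,
                      edge_correction: bool = True) -> float:
    """d' with 1/(2N) edge correction for rates of exactly 0 or 1."""
    if edge_correction:
        if hit >= 1.0:
            hit = 1.0 - 1.0 / (2 * n_pos)
        elif hit <= 0.0:
            hit = 1.0 / (2 * n_pos)
        if fa >= 1.0:
            fa = 1.0 - 1.0 / (2 * n_neg)
        elif fa <= 0.0:
            fa = 1.0 / (2 * n_neg)
    elif hit in (0.0, 1.0) or fa in (0.0, 1.0):
        raise ValueError("degenerate hit/false-alarm rate with edge correction off")
    return float(_st.norm.ppf(hit) - _st.norm.ppf(fa))


@dataclass
class DprimeResult:
    dprime: float
    hit_rate: float
    fa_rate: float
    predictions: pd.Series  # per item: predicted in-NN (shared across folds)
    n_pos: int
    n_neg: int


def _loo_dprime_arrays(
    X: np.ndarray, c: np.ndarray, P: int, priors: str,
    edge_correction: bool = True, return_predictions: bool = False,
):
    """Fast pooled leave-one-item-out d'.

    ``c[i]`` counts the participants whose neighbourhood contains item i.
    Folds are participant x item; excluding the held-out item removes all
    of its P copies, so the per-fold classifier depends only on the item,
    and class statistics follow from totals by subtraction.
    """
    n, F = X.shape
    N1 = int(c.sum())
    N0 = int((P - c).sum())
    if N1 == 0 or N0 == 0:
        raise ValueError("both classes must occur in the labels")

    pooled = X.var(axis=0, ddof=1)
    floor = _VAR_FLOOR_FRAC * np.where(pooled > 0, pooled, 1.0)

    cf = c.astype(np.float64)[:, None]
    c0 = (P - c).astype(np.float64)[:, None]
    S1 = (cf * X).sum(axis=0)
    Q1 = (cf * X**2).sum(axis=0)
    S0 = (c0 * X).sum(axis=0)
    Q0 = (c0 * X**2).sum(axis=0)

    n1 = N1 - cf  # training class-1 count per held-out item
    n0 = N0 - c0
    if (n1 < 2).any() or (n0 < 2).any():
        raise ValueError("a class has fewer than 2 training samples in some fold")
    mu1 = (S1 - cf * X) / n1
    mu0 = (S0 - c0 * X) / n0
    v1 = np.maximum((Q1 - cf * X**2 - n1 * mu1**2) / (n1 - 1), floor)
    v0 = np.maximum((Q0 - c0 * X**2 - n0 * mu0**2) / (n0 - 1), floor)

    if priors == "empirical":
        lp1 = np.log(n1 / (n1 + n0))
        lp0 = np.log(n0 / (n1 + n0))
    else:
        lp1 = lp0 = np.zeros_like(n1)
    s1 = lp1[:, 0] - 0.5 * (np.log(2 * np.pi * v1) + (X - mu1) ** 2 / v1).sum(axis=1)
    s0 = lp0[:, 0] - 0.5 * (np.log(2 * np.pi * v0) + (X - mu0) ** 2 / v0).sum(axis=1)
    pred = s1 > s0

    hit = float((pred * c).sum() / N1)
    fa = float((pred * (P - c)).sum() / N0)
    d = dprime_from_rates(hit, fa, N1, N0, edge_correction)
    if return_predictions:
        return d, hit, fa, pred
    return d


def loo_dprime(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    priors: str = "uniform",
    edge_correction: bool = True,
) -> DprimeResult:
    """Pooled leave-one-item-out classification sensitivity.

    ``features`` is an items x features frame (z-scored), ``labels`` the
    boolean items x participants membership table.  On each fold the
    classifier is tested on one item for one participant after training on
    all other items over all participants; the held-out item's feature
    vector is excluded from training for every participant, so its single
    shared prediction is scored against each participant's label.  Hit and
    false-alarm rates are pooled over all folds.
    """
    if features.shape[1] == 0:
        raise ValueError("empty feature subset")
    if not features.index.equals(labels.index):
        labels = labels.reindex(features.index)
        if labels.isna().any().any():
            raise ValueError("labels do not cover all feature-table items")
    X = features.to_numpy(dtype=np.float64)
    c = labels.to_numpy(dtype=bool).sum(axis=1)
    P = labels.shape[1]
    d, hit, fa, pred = _loo_dprime_arrays(
        X, c, P, priors, edge_correction, return_predictions=True
    )
    return DprimeResult(
        dprime=d, hit_rate=hit, fa_rate=fa,
        predictions=pd.Series(pred, index=features.index),
        n_pos=int(c.sum()), n_neg=int((P - c).sum()),
    )


# --------------------------------------------------------------------------
# Permutation null
# --------------------------------------------------------------------------

@dataclass
class PermutationNull:
    observed: float
    null: np.ndarray
    p_value: float
    percentile_95: float
    n_perm: int
    seed: int


def _permuted_counts(rng, n: int, per_participant_counts) -> np.ndarray:
    c = np.zeros(n, dtype=np.int64)
    for k in per_participant_counts:
        c[rng.choice(n, size=k, replace=False)] += 1
    return c


def permutation_null(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    priors: str = "uniform",
) -> PermutationNull:
    """Null d' distribution from within-participant label reshuffling.

    Each permutation reassigns every participant's in-NN labels to a fresh
    random subset of the same size, destroying any feature-label relation
    while preserving the 10/190 class counts.  p = (1 + #{null >= obs}) /
    (n_perm + 1), never exactly zero.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if not features.index.equals(labels.index):
        labels = labels.reindex(features.index)
    X = features.to_numpy(dtype=np.float64)
    lab = labels.to_numpy(dtype=bool)
    n, P = lab.shape
    k_p = lab.sum(axis=0)
    c_obs = lab.sum(axis=1)
    observed = _loo_dprime_arrays(X, c_obs, P, priors)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _loo_dprime_arrays(X, _permuted_counts(rng, n, k_p), P, priors)
    p = (1.0 + (null >= observed).sum()) / (n_perm + 1.0)
    return PermutationNull(
        observed=observed, null=null, p_value=float(p),
        percentile_95=float(np.percentile(null, 95)), n_perm=n_perm, seed=seed,
    )


# --------------------------------------------------------------------------
# Hierarchical testing
# --------------------------------------------------------------------------

def holm_reject(p_values, alpha: float = 0.05):
    """Holm-Bonferroni step-down decisions; returns (reject, adjusted p)."""
    p = np.asarray(p_values, dtype=np.float64)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj <= alpha, adj


@dataclass
class TuningReport:
    """Full offline tuning report for one condition of one experiment."""

    set_results: pd.DataFrame  # per feature set: dprime, p, percentile, Holm
    feature_results: pd.DataFrame  # per feature within significant sets
    mean_nn: pd.DataFrame  # per feature: group mean, CI, t, p
    per_participant_means: pd.DataFrame  # participants x features
    alpha: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "set_results": self.set_results.to_dict(orient="index"),
            "feature_results": self.feature_results.to_dict(orient="index"),
            "mean_nn": self.mean_nn.to_dict(orient="index"),
        }


def hierarchical_feature_tests(
    table: FeatureTable,
    labels: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    priors: str = "uniform",
) -> TuningReport:
    """Two-stage gatekeeping analysis of neighbourhood feature tuning.

    Stage 1 trains one multivariate classifier per feature set (sensory,
    semantic, emotional) with a permutation p-value each; the three set
    p-values form one Holm family.  Stage 2 runs univariate classifiers
    only for features inside significant sets, Holm-corrected within the
    set.  Mean-feature-in-NN statistics are reported for every feature.
    """
    if not table.standardized:
        raise ValueError("feature table must be z-scored before tuning tests")
    values = table.values
    sets = sorted(set(table.sets.values()))
    rng = np.random.SeedSequence(seed)
    seeds = iter(int(s % (2**31)) for s in rng.generate_state(len(sets) * (1 + values.shape[1])))

    set_rows = {}
    for set_name in sets:
        cols = table.features_in_set(set_name)
        perm = permutation_null(values[cols], labels, n_perm, next(seeds), priors)
        set_rows[set_name] = {
            "dprime": perm.observed,
            "p": perm.p_value,
            "percentile_95": perm.percentile_95,
            "n_features": len(cols),
        }
    set_results = pd.DataFrame.from_dict(set_rows, orient="index")
    rej, adj = holm_reject(set_results["p"].to_numpy(), alpha)
    set_results["p_holm"] = adj
    set_results["significant"] = rej

    feat_rows = {}
    for set_name in sets:
        cols = table.features_in_set(set_name)
        if not set_results.loc[set_name, "significant"]:
            for f in cols:
                feat_rows[f] = {
                    "set": set_name, "dprime": np.nan, "p": np.nan,
                    "percentile_95": np.nan, "p_holm": np.nan,
                    "significant": False, "tested": False,
                }
            continue
        ps = []
        for f in cols:
            perm = permutation_null(values[[f]], labels, n_perm, next(seeds), priors)
            feat_rows[f] = {
                "set": set_name, "dprime": perm.observed, "p": perm.p_value,
                "percentile_95": perm.percentile_95, "tested": True,
            }
            ps.append(perm.p_value)
        rej_f, adj_f = holm_reject(ps, alpha)
        for f, r, a in zip(cols, rej_f, adj_f):
            feat_rows[f]["p_holm"] = a
            feat_rows[f]["significant"] = bool(r)
    feature_results = pd.DataFrame.from_dict(feat_rows, orient="index")

    per_part, mean_nn = mean_nn_feature(table, labels)
    return TuningReport(
        set_results=set_results,
        feature_results=feature_results,
        mean_nn=mean_nn,
        per_participant_means=per_part,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Mean feature value in the neighbourhood
# --------------------------------------------------------------------------

def mean_nn_feature(table: FeatureTable, labels: pd.DataFrame):
    """Direction of tuning: mean z-scored feature value over NN items.

    Returns ``(per_participant_means, group_stats)`` where group_stats has
    the across-participant mean, 95% CI and one-sample t-test against the
    zero expected under random selection.
    """
    if not table.standardized:
        raise ValueError("feature table must be z-scored across all stimuli")
    if not table.values.index.equals(labels.index):
        labels = labels.reindex(table.values.index)
        if labels.isna().any().any():
            raise ValueError("labels do not cover the feature table's items")
    V = table.values.to_numpy(dtype=np.float64)
    L = labels.to_numpy(dtype=bool)
    counts = L.sum(axis=0)
    if (counts == 0).any():
        empty = labels.columns[counts == 0].tolist()
        raise ValueError(f"participants with empty neighbourhood: {empty}")
    means = (L.T.astype(np.float64) @ V) / counts[:, None]
    per_part = pd.DataFrame(means, index=labels.columns, columns=table.feature_names)

    n = per_part.shape[0]
    gmean = per_part.mean(axis=0)
    sem = per_part.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = _st.t.ppf(0.975, n - 1)
    tt = _st.ttest_1samp(per_part.to_numpy(), 0.0, axis=0)
    group = pd.DataFrame({
        "mean": gmean,
        "ci_low": gmean - tcrit * sem,
        "ci_high": gmean + tcrit * sem,
        "t": tt.statistic,
        "p": tt.pvalue,
        "df": n - 1,
    })
    return per_part, group


def tuning_contrast(values_a, values_b, paired: bool = False):
    """t-contrast of per-participant tuning values (two-sided).

    Paired for within-participant condition contrasts, two-sample for
    between-experiment referent contrasts.  Returns ``(t, df, p)``.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired contrast needs equal-length vectors")
        if len(a) < 3:
            raise ValueError("need at least 3 participants")
        if np.ptp(a - b) == 0 and (a - b)[0] == 0:
            return 0.0, len(a) - 1, 1.0  # identical vectors: no evidence
        res = _st.ttest_rel(a, b)
        df = len(a) - 1
    else:
        if min(len(a), len(b)) < 3:
            raise ValueError("need at least 3 participants per group")
        res = _st.ttest_ind(a, b)
        df = len(a) + len(b) - 2
    return float(res.statistic), int(df), float(res.pvalue)


# --------------------------------------------------------------------------
# Pattern-consistency QA: pairwise identity decoding
# --------------------------------------------------------------------------

def fit_per_run_betas(runs, ys, TR: float, nuisance=None, cutoff: float = 128.0,
                      hrf_params=None) -> list:
    """One independent GLM per run, with run-specific stimulus regressors.

    The cumulative model has a single regressor per stimulus, so run-wise
    patterns for the consistency check come from separate per-run fits.
    """
    out = []
    for i, (run, Y) in enumerate(zip(runs, ys)):
        present = sorted(set(run.stimulus_ids))
        nuis = None if nuisance is None else [nuisance[i]]
        design = build_design_matrix([run], present, TR, hrf_params=hrf_params,
                                     cutoff=cutoff, nuisance=nuis)
        out.append(fit_betas(Y, design))
    return out


def pairwise_identity_decode(per_run_betas: list, min_runs: int = 4) -> dict:
    """Leave-one-run-out SVM decoding of stimulus identity for one participant.

    For every stimulus pair repeated in at least ``min_runs`` runs, a linear
    SVM is trained on the per-run beta patterns of the other runs and tested
    on the held-out run's two patterns; accuracies are averaged over splits
    and pairs.  Chance is 0.5 by construction of the two-class folds.
    """
    from sklearn.svm import SVC

    runs_for: dict = {}
    for r, bm in enumerate(per_run_betas):
        for sid in bm.valid_stimulus_ids:
            runs_for.setdefault(sid, []).append(r)
    eligible = sorted(s for s, rs in runs_for.items() if len(rs) >= min_runs)

    pair_accs = []
    n_pairs = 0
    for i, a in enumerate(eligible):
        for b in eligible[i + 1:]:
            shared = sorted(set(runs_for[a]) & set(runs_for[b]))
            if len(shared) < min_runs:
                continue
            n_pairs += 1
            correct = 0
            total = 0
            for held in shared:
                X_tr, y_tr = [], []
                for r in shared:
                    if r == held:
                        continue
                    X_tr.append(per_run_betas[r].pattern(a))
                    y_tr.append(0)
                    X_tr.append(per_run_betas[r].pattern(b))
                    y_tr.append(1)
                clf = SVC(kernel="linear", C=1.0)
                clf.fit(np.asarray(X_tr), np.asarray(y_tr))
                pred = clf.predict(np.vstack([
                    per_run_betas[held].pattern(a),
                    per_run_betas[held].pattern(b),
                ]))
                correct += int(pred[0] == 0) + int(pred[1] == 1)
                total += 2
            pair_accs.append(correct / total)
    if n_pairs == 0:
        raise ValueError(f"no stimulus pair repeated in >= {min_runs} runs")
    return {"accuracy": float(np.mean(pair_accs)), "n_pairs": n_pairs}


def group_identity_decode(per_participant_accuracies) -> dict:
    """Group t-test of mean decoding accuracy against chance (0.5)."""
    acc = np.asarray(per_participant_accuracies, dtype=np.float64)
    if len(acc) < 3:
        raise ValueError("need at least 3 participants")
    res = _st.ttest_1samp(acc, 0.5)
    return {
        "mean_accuracy": float(acc.mean()),
        "t": float(res.statistic),
        "df": len(acc) - 1,
        "p": float(res.pvalue),
    }
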