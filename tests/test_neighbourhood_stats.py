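"""Feature-tuning statistics: classifier, d', permutations, Holm, decoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as _st

from nnsearch.neighbourhood_stats import (
    dprime_from_rates,
    fit_per_run_betas,
    gaussian_discriminant,
    group_identity_decode,
    hierarchical_feature_tests,
    holm_reject,
    loo_dprime,
    mean_nn_feature,
    membership_from_neighbourhoods,
    pairwise_identity_decode,
    permutation_null,
    tuning_contrast,
)
from nnsearch.glm_engine import BetaMatrix
from nnsearch.stimulus_features import FeatureTable


def _ztable(rng, n=40, F=3, names=None):
    names = names or [f"f{k}" for k in range(F)]
    df = pd.DataFrame(rng.normal(size=(n, len(names))), columns=names,
                      index=[f"s{i:03d}" for i in range(n)])
    df = (df - df.mean()) / df.std(ddof=1)
    return FeatureTable(values=df, sets={c: "sensory" for c in names},
                        standardized=True)


def _random_labels(rng, ids, P=6, k=4):
    return membership_from_neighbourhoods(
        {f"sub{p}": rng.choice(ids, size=k, replace=False) for p in range(P)},
        ids,
    )


class TestGaussianDiscriminant:
    def test_equal_variance_boundary_at_midpoint(self):
        X = np.concatenate([np.linspace(-3, 3, 200), np.linspace(-2, 4, 200)])
        y = np.array([0] * 200 + [1] * 200)
        clf = gaussian_discriminant(X[:, None], y, priors="uniform")
        # classes N(0, v) vs N(1, v): boundary at 0.5 under equal priors
        clf.means[:] = [[0.0], [1.0]]
        clf.variances[:] = [[1.0], [1.0]]
        assert clf.predict(np.array([[0.49]]))[0] == 0
        assert clf.predict(np.array([[0.51]]))[0] == 1

    def test_duplicate_columns_do_not_change_predictions(self, rng):
        # naive independence: a duplicated column doubles every
        # log-likelihood difference, leaving the decision unchanged
        # (under uniform priors, where the decision is a pure sign test)
        X = rng.normal(size=(60, 1))
        y = (rng.random(60) > 0.5).astype(int)
        y[:2] = [0, 1]
        single = gaussian_discriminant(X, y, priors="uniform")
        double = gaussian_discriminant(np.hstack([X, X]), y, priors="uniform")
        probe = rng.normal(size=(30, 1))
        assert np.array_equal(single.predict(probe),
                              double.predict(np.hstack([probe, probe])))

    def test_unequal_variances_give_quadratic_boundary(self, rng):
        # brute-force density-ratio oracle on a grid
        X = np.concatenate([rng.normal(0, 1, 300), rng.normal(0, 3, 300)])
        y = np.array([0] * 300 + [1] * 300)
        clf = gaussian_discriminant(X[:, None], y, priors="uniform")
        grid = np.linspace(-8, 8, 400)
        m, v = clf.means[:, 0], clf.variances[:, 0]
        ll = np.stack([
            -0.5 * (np.log(2 * np.pi * v[c]) + (grid - m[c]) ** 2 / v[c])
            for c in (0, 1)
        ])
        oracle = (ll[1] > ll[0]).astype(int)
        assert np.array_equal(clf.predict(grid[:, None]), oracle)
        # far tails belong to the wide class on both sides
        assert clf.predict(np.array([[-7.0]]))[0] == 1
        assert clf.predict(np.array([[7.0]]))[0] == 1

    def test_matches_sklearn_gaussian_nb(self, rng):
        from sklearn.naive_bayes import GaussianNB

        X = rng.normal(size=(200, 4))
        y = (X[:, 0] + 0.5 * rng.normal(size=200) > 0).astype(int)
        ours = gaussian_discriminant(X, y, priors="empirical",
                                     var_floor_frac=1e-12)
        skl = GaussianNB(var_smoothing=1e-12).fit(X, y)
        probe = rng.normal(size=(100, 4))
        assert np.array_equal(ours.predict(probe), skl.predict(probe))

    def test_missing_class_rejected(self, rng):
        with pytest.raises(ValueError):
            gaussian_discriminant(rng.normal(size=(10, 2)), np.zeros(10, int))

    def test_feature_order_invariance(self, rng):
        X = rng.normal(size=(80, 3))
        y = (rng.random(80) > 0.5).astype(int)
        y[:2] = [0, 1]
        a = gaussian_discriminant(X, y)
        b = gaussian_discriminant(X[:, ::-1], y)
        probe = rng.normal(size=(40, 3))
        assert np.array_equal(a.predict(probe), b.predict(probe[:, ::-1]))


class TestDprime:
    def test_standard_normal_quantile_oracle(self):
        # d'(hit=.8, fa=.2) = 2 * Phi^-1(.8)
        assert dprime_from_rates(0.8, 0.2) == pytest.approx(1.683, abs=5e-4)
        assert dprime_from_rates(0.8, 0.2) == pytest.approx(
            _st.norm.ppf(0.8) - _st.norm.ppf(0.2))

    def test_edge_correction(self):
        d = dprime_from_rates(1.0, 0.0, n_pos=40, n_neg=200)
        expected = _st.norm.ppf(1 - 1 / 80) - _st.norm.ppf(1 / 400)
        assert np.isfinite(d) and d == pytest.approx(expected)
        with pytest.raises(ValueError):
            dprime_from_rates(1.0, 0.2, edge_correction=False)

    def test_null_dprime_near_zero(self, rng):
        table = _ztable(rng, n=40, F=2)
        ids = table.stimulus_ids
        ds = [
            loo_dprime(table.values, _random_labels(rng, ids)).dprime
            for _ in range(100)
        ]
        assert abs(np.mean(ds)) < 0.15

    def test_perfectly_separating_feature_is_finite(self, rng):
        ids = [f"s{i:03d}" for i in range(40)]
        vals = np.linspace(-1, 1, 40)
        df = pd.DataFrame({"f": (vals - vals.mean()) / vals.std(ddof=1)}, index=ids)
        table = FeatureTable(values=df, sets={"f": "sensory"}, standardized=True)
        top4 = list(df["f"].nlargest(4).index)
        labels = membership_from_neighbourhoods(
            {f"sub{p}": top4 for p in range(5)}, ids)
        res = loo_dprime(table.values, labels)
        assert np.isfinite(res.dprime)
        assert res.dprime > 2.0

    @pytest.mark.parametrize("priors", ["uniform", "empirical"])
    def test_fast_path_equals_naive_refit(self, rng, priors):
        # oracle: per-fold refit with the public classifier op
        table = _ztable(rng, n=25, F=3)
        ids = table.stimulus_ids
        labels = _random_labels(rng, ids, P=4, k=5)
        X = table.values.to_numpy()
        L = labels.to_numpy()
        fast = loo_dprime(table.values, labels, priors=priors)
        hits = fas = npos = nneg = 0
        for i in range(len(ids)):
            keep = np.arange(len(ids)) != i
            X_tr = np.repeat(X[keep], L.shape[1], axis=0)
            y_tr = L[keep].ravel().astype(int)
            clf = gaussian_discriminant(X_tr, y_tr, priors=priors)
            pred = clf.predict(X[i][None, :])[0]
            assert pred == int(fast.predictions.iloc[i])
            for p in range(L.shape[1]):
                if L[i, p]:
                    npos += 1
                    hits += pred
                else:
                    nneg += 1
                    fas += pred
        assert fast.hit_rate == pytest.approx(hits / npos)
        assert fast.fa_rate == pytest.approx(fas / nneg)

    def test_swapping_rate_roles_negates_dprime(self, rng):
        # at fixed predictions, relabelling classes exchanges hit and
        # false-alarm rates, negating d' (symmetric edge correction)
        for _ in range(25):
            hit, fa = rng.random(2)
            d = dprime_from_rates(hit, fa, 40, 40)
            assert dprime_from_rates(fa, hit, 40, 40) == pytest.approx(-d)
        assert dprime_from_rates(0.0, 1.0, 40, 40) == pytest.approx(
            -dprime_from_rates(1.0, 0.0, 40, 40))

    @given(st.integers(0, 10_000))
    def test_retrained_label_swap_leaves_dprime_invariant(self, seed):
        # with the classifier retrained on swapped labels its predictions
        # flip too, so hit' = 1 - FA and FA' = 1 - hit: d' is unchanged
        r = np.random.default_rng(seed)
        table = _ztable(r, n=20, F=2)
        ids = table.stimulus_ids
        labels = _random_labels(r, ids, P=3, k=10)  # balanced classes
        d_pos = loo_dprime(table.values, labels, priors="uniform").dprime
        d_neg = loo_dprime(table.values, ~labels, priors="uniform").dprime
        assert d_pos == pytest.approx(d_neg, abs=1e-10)


class TestPermutationNull:
    def test_p_value_extremes(self, rng):
        table = _ztable(rng, n=30, F=1)
        ids = table.stimulus_ids
        # plant a perfectly tuned labelling: top items on f0
        top = list(table.values["f0"].nlargest(5).index)
        strong = membership_from_neighbourhoods(
            {f"sub{p}": top for p in range(4)}, ids)
        res = permutation_null(table.values, strong, n_perm=100, seed=0)
        assert res.p_value == pytest.approx(1 / 101)
        assert res.p_value >= 1 / (res.n_perm + 1)

    def test_counts_preserved_within_participant(self, rng):
        table = _ztable(rng, n=20, F=1)
        labels = _random_labels(rng, table.stimulus_ids, P=3, k=4)
        res = permutation_null(table.values, labels, n_perm=100, seed=1)
        assert len(res.null) == 100
        assert res.percentile_95 >= np.median(res.null)

    def test_minimum_permutations(self, rng):
        table = _ztable(rng, n=20, F=1)
        labels = _random_labels(rng, table.stimulus_ids)
        with pytest.raises(ValueError):
            permutation_null(table.values, labels, n_perm=10)


class TestHolm:
    def test_hand_applied_sequence(self):
        # thresholds alpha/3, alpha/2, alpha -> all three rejected
        reject, adj = holm_reject([0.01, 0.02, 0.04], alpha=0.05)
        assert reject.all()
        assert adj == pytest.approx([0.03, 0.04, 0.04])

    def test_partial_rejection(self):
        reject, _ = holm_reject([0.001, 0.03, 0.4], alpha=0.05)
        assert list(reject) == [True, False, False]

    @given(st.integers(0, 10_000))
    def test_between_bonferroni_and_unadjusted(self, seed):
        r = np.random.default_rng(seed)
        p = r.random(6)
        alpha = 0.05
        holm_n = holm_reject(p, alpha)[0].sum()
        bonf_n = (p <= alpha / len(p)).sum()
        raw_n = (p <= alpha).sum()
        assert bonf_n <= holm_n <= raw_n


class TestHierarchical:
    def test_gatekeeping_blocks_features_of_null_sets(self, rng):
        ids = [f"s{i:03d}" for i in range(40)]
        df = pd.DataFrame(rng.normal(size=(40, 4)),
                          columns=["a1", "a2", "b1", "b2"], index=ids)
        df = (df - df.mean()) / df.std(ddof=1)
        table = FeatureTable(
            values=df,
            sets={"a1": "sensory", "a2": "sensory",
                  "b1": "semantic", "b2": "semantic"},
            standardized=True)
        top = list(df["a1"].nlargest(4).index)
        labels = membership_from_neighbourhoods(
            {f"sub{p}": top for p in range(6)}, ids)
        report = hierarchical_feature_tests(table, labels, n_perm=100, seed=0)
        assert report.set_results.loc["sensory", "significant"]
        assert report.feature_results.loc["a1", "significant"]
        if not report.set_results.loc["semantic", "significant"]:
            assert not report.feature_results.loc["b1", "tested"]
            assert np.isnan(report.feature_results.loc["b1", "dprime"])

    def test_requires_standardized_table(self, rng):
        df = pd.DataFrame({"f": rng.normal(size=20) + 5},
                          index=[f"s{i}" for i in range(20)])
        table = FeatureTable(values=df, sets={"f": "sensory"}, standardized=False)
        labels = membership_from_neighbourhoods(
            {"sub0": df.index[:4]}, list(df.index))
        with pytest.raises(ValueError):
            hierarchical_feature_tests(table, labels)


class TestMeanNNFeature:
    def test_top_k_matches_analytic_mean(self, rng):
        table = _ztable(rng, n=30, F=2)
        ids = table.stimulus_ids
        top = list(table.values["f0"].nlargest(10).index)
        labels = membership_from_neighbourhoods({"sub0": top, "sub1": top}, ids)
        per_part, group = mean_nn_feature(table, labels)
        expected = table.values["f0"].nlargest(10).mean()
        assert per_part.loc["sub0", "f0"] == pytest.approx(expected)
        assert group.loc["f0", "mean"] == pytest.approx(expected)

    def test_ci_covers_mean_and_df(self, rng):
        table = _ztable(rng, n=30, F=1)
        labels = _random_labels(rng, table.stimulus_ids, P=8, k=5)
        _, group = mean_nn_feature(table, labels)
        row = group.loc["f0"]
        assert row.ci_low <= row["mean"] <= row.ci_high
        assert row.df == 7

    def test_unstandardized_rejected(self, rng):
        df = pd.DataFrame({"f": rng.normal(size=12)},
                          index=[f"s{i}" for i in range(12)])
        table = FeatureTable(values=df, sets={"f": "sensory"}, standardized=False)
        labels = membership_from_neighbourhoods({"sub0": df.index[:3]},
                                                list(df.index))
        with pytest.raises(ValueError):
            mean_nn_feature(table, labels)


class TestTuningContrast:
    def test_identical_vectors_paired(self):
        t, df, p = tuning_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert t == 0.0 and p == 1.0 and df == 2

    def test_paired_detects_planted_drop(self, rng):
        a = rng.normal(loc=1.0, scale=0.2, size=15)
        b = rng.normal(loc=0.0, scale=0.2, size=15)
        t, df, p = tuning_contrast(a, b, paired=True)
        assert p < 0.001 and t > 0 and df == 14

    def test_two_sample_type_i_calibration(self, rng):
        rejections = 0
        for _ in range(500):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            _, _, p = tuning_contrast(a, b, paired=False)
            rejections += p < 0.05
        assert 0.02 <= rejections / 500 <= 0.08

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            tuning_contrast([1.0, 2.0], [0.5, 1.0], paired=True)


def _per_run_betas(patterns_by_run, ids, n_vox):
    out = []
    for pats in patterns_by_run:
        item_ids = list(pats) + ["REF"]
        out.append(BetaMatrix(
            betas=np.vstack([pats[s] for s in pats] + [np.zeros(n_vox)]),
            item_ids=item_ids,
            residual_variance=np.zeros(n_vox),
        ))
    return out


class TestPairwiseIdentityDecode:
    def test_identical_patterns_decode_perfectly(self, rng):
        pa, pb = rng.normal(size=20), rng.normal(size=20)
        runs = [{"a": pa, "b": pb} for _ in range(4)]
        res = pairwise_identity_decode(_per_run_betas(runs, ["a", "b"], 20))
        assert res["accuracy"] == 1.0
        assert res["n_pairs"] == 1

    def test_pure_noise_is_at_chance(self, rng):
        accs = []
        for _ in range(100):
            runs = [{"a": rng.normal(size=12), "b": rng.normal(size=12)}
                    for _ in range(4)]
            accs.append(pairwise_identity_decode(
                _per_run_betas(runs, ["a", "b"], 12))["accuracy"])
        ci = 1.96 * np.std(accs) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.5) < max(ci, 0.06)

    def test_min_runs_requirement(self, rng):
        runs = [{"a": rng.normal(size=8), "b": rng.normal(size=8)}
                for _ in range(3)]
        with pytest.raises(ValueError):
            pairwise_identity_decode(_per_run_betas(runs, ["a", "b"], 8),
                                     min_runs=4)

    def test_group_test_against_chance(self):
        out = group_identity_decode([0.9, 0.8, 0.85, 0.95])
        assert out["p"] < 0.01 and out["t"] > 0
        with pytest.raises(ValueError):
            group_identity_decode([0.9, 0.8])


def test_fit_per_run_betas_gives_run_specific_patterns(rng, table_z):
    from nnsearch import synthetic_data as sd
    from nnsearch.design_schedule import build_run

    _, truths = sd.generate_participant(
        table_z, table_z.values.iloc[0] * 0.0, {"perception": {"animacy": 1.0}},
        n_voxels=30, seed=0, nn_size=4)
    gt = truths["perception"]
    ids = table_z.stimulus_ids[:8]
    runs = [build_run(ids, k + 1, rng=np.random.default_rng(k)) for k in range(2)]
    ys = [sd.simulate_run(r, gt, sd.NoiseConfig(sd=0.0, ar1=0.0), seed=k)[0]
          for k, r in enumerate(runs)]
    betas = fit_per_run_betas(runs, ys, TR=1.0)
    assert len(betas) == 2
    for bm in betas:
        for sid in ids:
            true = gt.patterns.loc[sid].to_numpy()
            assert np.abs(bm.pattern(sid) - true).max() < 1e-6
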