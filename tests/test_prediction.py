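"""Prediction workflow: FC features, ridge engines, CV design, statistics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge

from bwasplan.cohort import CohortConfig, generate_cohort, observe_fc
from bwasplan.prediction import (
    CVScheme,
    PredictorSpec,
    _krr_solve,
    by_fdr,
    compute_fc,
    corrected_resampled_ttest,
    family_folds,
    haufe_transform,
    nested_cv_accuracy,
    randomized_run_fit_change,
    site_clusters,
    unvectorize_fc,
    vectorize_fc,
)


class TestComputeFc:
    def test_identical_series_correlate_perfectly(self, rng):
        x = rng.normal(size=300)
        fc = compute_fc(np.vstack([x, x, rng.normal(size=300)]), 2.0, 0.8)
        assert fc[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(fc), 1.0)
        assert np.allclose(fc, fc.T)

    def test_constant_parcel_named(self, rng):
        ts = rng.normal(size=(3, 200))
        ts[1] = 5.0
        with pytest.raises(ValueError, match=r"parcels \[1\]"):
            compute_fc(ts, 2.0, 0.8)

    def test_frame_budget_enforced(self, rng):
        with pytest.raises(ValueError, match="not enough frames"):
            compute_fc(rng.normal(size=(3, 100)), 2.0, 0.8)  # needs 150

    def test_white_noise_off_diagonal_small(self, rng):
        frames = 4000
        fc = compute_fc(rng.normal(size=(4, frames)), frames * 0.8 / 60, 0.8)
        off = vectorize_fc(fc)
        assert np.all(np.abs(off) < 3 / np.sqrt(frames))

    def test_doubling_scan_time_halves_edge_variance(self, rng):
        """Edge sampling variance of stationary series scales like 1/T."""
        var = {}
        for t_min, n_sim in [(1.0, 120), (2.0, 120)]:
            edges = [
                vectorize_fc(compute_fc(rng.normal(size=(4, 300)), t_min, 0.8))
                for _ in range(n_sim)
            ]
            var[t_min] = np.var(edges, axis=0).mean()
        assert var[2.0] / var[1.0] == pytest.approx(0.5, rel=0.25)


class TestVectorize:
    def test_small_matrix_length(self, rng):
        m = np.eye(3)
        assert vectorize_fc(m).shape == (3,)

    @pytest.mark.parametrize("p", [5, 20, 419])
    def test_length_formula(self, p):
        assert unvectorize_fc(np.zeros(p * (p - 1) // 2)).shape == (p, p)

    def test_round_trip(self, rng):
        a = rng.normal(size=(7, 7))
        fc = (a + a.T) / 2
        np.fill_diagonal(fc, 1.0)
        np.testing.assert_allclose(unvectorize_fc(vectorize_fc(fc)), fc)

    def test_non_square_rejected(self, rng):
        with pytest.raises(ValueError):
            vectorize_fc(rng.normal(size=(3, 4)))


class TestFolding:
    def test_families_never_split(self, rng):
        fam = rng.integers(0, 40, size=200)
        folds = family_folds(fam, 10, rng)
        assert sorted(np.concatenate(folds).tolist()) == list(range(200))
        fold_of = {}
        for k, f in enumerate(folds):
            for idx in f:
                fold_of[fam[idx]] = fold_of.get(fam[idx], k)
                assert fold_of[fam[idx]] == k

    def test_fold_sizes_balanced(self, rng):
        folds = family_folds(np.arange(100), 10, rng)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_site_clusters_balanced(self, rng):
        sites = rng.integers(0, 22, size=1000)
        clusters = site_clusters(sites, 10)
        _, counts = np.unique(clusters, return_counts=True)
        assert counts.min() > 0.5 * counts.max()
        # a site maps to exactly one cluster
        assert all(
            len(np.unique(clusters[sites == s])) == 1 for s in np.unique(sites)
        )


class TestRidgeEngines:
    def test_krr_linear_kernel_matches_primal_ridge(self, rng):
        """Kernel/primal duality: linear-kernel KRR equals Ridge at the same
        regularization (centered target, no penalized intercept)."""
        X = rng.normal(size=(40, 7))
        y = X @ rng.normal(size=7) + 0.3 * rng.normal(size=40)
        X_te = rng.normal(size=(10, 7))
        lam = 2.5
        krr = _krr_solve(X @ X.T, y, X_te @ X.T, lam)
        ridge = Ridge(alpha=lam, fit_intercept=False).fit(X, y - y.mean())
        np.testing.assert_allclose(krr, ridge.predict(X_te) + y.mean(), atol=1e-8)

    def test_noiseless_linear_phenotype_predicted_almost_perfectly(self, rng):
        X = rng.normal(size=(220, 30))
        y = X @ rng.normal(size=30)
        feats = {5.0: X}
        scheme = CVScheme(n_folds=4, n_reps=1, seed=0)
        res = nested_cv_accuracy(feats, y, scheme, PredictorSpec(inner_folds=4))
        assert res.rep_accuracies["pearson"].mean() > 0.98

    def test_permuted_phenotype_gives_null_accuracy(self, rng):
        X = rng.normal(size=(150, 40))
        y = rng.permutation(X @ rng.normal(size=40))
        res = nested_cv_accuracy(
            {5.0: X}, y, CVScheme(n_folds=3, n_reps=8, seed=1),
            PredictorSpec(inner_folds=4),
        )
        acc = res.rep_accuracies["pearson"]
        assert abs(acc.mean()) < 2 * acc.std() / np.sqrt(len(acc))

    def test_metrics_bounded(self, rng):
        X = rng.normal(size=(90, 25))
        y = X @ rng.normal(size=25) + rng.normal(size=90)
        res = nested_cv_accuracy(
            {2.0: X}, y, CVScheme(n_folds=3, n_reps=2, seed=0),
            PredictorSpec(inner_folds=3),
        )
        assert res.rep_accuracies["pearson"].between(-1, 1).all()
        assert (res.rep_accuracies["cod"] <= 1).all()

    def test_lrr_runs_and_correlates_with_krr(self, rng):
        X = rng.normal(size=(120, 20))
        y = X @ rng.normal(size=20) + 0.5 * rng.normal(size=120)
        scheme = CVScheme(n_folds=3, n_reps=1, seed=0)
        krr = nested_cv_accuracy({1.0: X}, y, scheme, PredictorSpec(inner_folds=3))
        lrr = nested_cv_accuracy(
            {1.0: X}, y, scheme, PredictorSpec(model="lrr", inner_folds=3)
        )
        assert abs(
            krr.rep_accuracies["pearson"].mean()
            - lrr.rep_accuracies["pearson"].mean()
        ) < 0.15


class TestCVDesign:
    def test_results_invariant_to_other_subsample_sizes(self, rng):
        """Accuracies at a given training size do not depend on which other
        sizes were requested (the test folds are fixed within a rep)."""
        X = rng.normal(size=(120, 15))
        y = X @ rng.normal(size=15) + rng.normal(size=120)
        spec = PredictorSpec(inner_folds=3)
        a = nested_cv_accuracy(
            {3.0: X}, y, CVScheme(n_folds=3, subsample_sizes=(40,), seed=7), spec
        )
        b = nested_cv_accuracy(
            {3.0: X}, y,
            CVScheme(n_folds=3, subsample_sizes=(40, 70), seed=7), spec,
        )
        a40 = a.rep_accuracies.query("n_train == 40").reset_index(drop=True)
        b40 = b.rep_accuracies.query("n_train == 40").reset_index(drop=True)
        pd.testing.assert_frame_equal(a40, b40)

    def test_subsample_exceeding_pool_rejected(self, rng):
        X = rng.normal(size=(30, 5))
        with pytest.raises(ValueError, match="exceeds"):
            nested_cv_accuracy(
                {1.0: X}, rng.normal(size=30),
                CVScheme(n_folds=3, subsample_sizes=(25,), seed=0),
                PredictorSpec(inner_folds=2),
            )

    def test_site_regression_requires_labels(self, rng):
        X = rng.normal(size=(30, 5))
        with pytest.raises(ValueError, match="site"):
            nested_cv_accuracy(
                {1.0: X}, rng.normal(size=30),
                CVScheme(n_folds=3, site_regression=True, seed=0),
                PredictorSpec(inner_folds=2),
            )

    def test_site_regression_removes_site_effect(self, rng):
        n = 150
        sites = rng.integers(0, 3, size=n)
        X = rng.normal(size=(n, 20))
        # phenotype = pure site effect: after residualization, nothing left
        y = sites * 10.0 + 0.1 * rng.normal(size=n)
        res = nested_cv_accuracy(
            {1.0: X}, y,
            CVScheme(n_folds=3, n_reps=4, site_regression=True, seed=2),
            PredictorSpec(inner_folds=3),
            site_ids=sites,
        )
        assert abs(res.rep_accuracies["pearson"].mean()) < 0.12

    def test_leave_p_siteclusters_out_split_count(self, rng):
        n = 200
        clusters = rng.integers(0, 6, size=n)
        X = rng.normal(size=(n, 10))
        y = X @ rng.normal(size=10)
        res = nested_cv_accuracy(
            {1.0: X}, y,
            CVScheme(kind="leave_p_siteclusters_out", p=3, n_reps=1, seed=0),
            PredictorSpec(inner_folds=3),
            site_cluster_ids=clusters,
        )
        assert res.rep_accuracies["fold"].nunique() == 20  # C(6, 3)


class TestHaufe:
    def test_single_standardized_feature(self):
        x = np.array([-1.0, 0.0, 1.0])
        x = x / x.std(ddof=1)
        act = haufe_transform(x[:, None], x)
        assert act[0] == pytest.approx(1.0)

    def test_identity_covariance_recovers_weights(self, rng):
        X = rng.normal(size=(20000, 6))
        w = rng.normal(size=6)
        act = haufe_transform(X, X @ w)
        np.testing.assert_allclose(act, w, atol=0.15)  # Monte Carlo tolerance

    def test_sign_flip(self, rng):
        X = rng.normal(size=(50, 4))
        yhat = X @ np.ones(4)
        np.testing.assert_allclose(
            haufe_transform(X, -yhat), -haufe_transform(X, yhat)
        )

    def test_zero_variance_prediction_rejected(self, rng):
        with pytest.raises(ValueError):
            haufe_transform(rng.normal(size=(10, 3)), np.ones(10))


class TestCorrectedResampledTTest:
    def test_all_zero_diffs(self):
        assert corrected_resampled_ttest([0.0] * 10, 90, 10) == (0.0, 1.0)

    def test_hand_value(self):
        """mean 0.05, var 0.01, J=100, n_test/n_train = 1/9."""
        d = np.zeros(100)
        d[::2], d[1::2] = 0.05 + 0.1, 0.05 - 0.1
        d = 0.05 + (d - d.mean()) * (0.1 / d.std(ddof=1))
        assert d.var(ddof=1) == pytest.approx(0.01)
        t, p = corrected_resampled_ttest(d, n_train=9, n_test=1)
        assert t == pytest.approx(0.05 / np.sqrt((0.01 + 1 / 9) * 0.01), rel=1e-9)
        assert t == pytest.approx(1.4367, abs=2e-4)

    def test_reduces_to_classical_t_when_test_fraction_vanishes(self, rng):
        d = rng.normal(0.1, 0.3, size=30)
        t_corr, _ = corrected_resampled_ttest(d, n_train=10**9, n_test=1)
        classical = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t_corr == pytest.approx(classical, rel=1e-4)

    def test_degenerate_nonzero_mean(self):
        with pytest.raises(ValueError):
            corrected_resampled_ttest([0.2, 0.2, 0.2], 9, 1)


class TestByFdr:
    def test_all_ones_no_rejections(self):
        assert not by_fdr([1.0, 1.0, 1.0], 0.05).any()

    def test_single_small_p(self):
        assert by_fdr([0.01], 0.05).tolist() == [True]

    def test_hand_example(self):
        """c(3) = 11/6; thresholds i*0.05/(3*11/6); only p=0.001 passes."""
        assert by_fdr([0.001, 0.02, 0.8], 0.05).tolist() == [True, False, False]

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.random(50) ** 2
        ours = by_fdr(p, 0.05)
        theirs = sm.multipletests(p, alpha=0.05, method="fdr_by")[0]
        np.testing.assert_array_equal(ours, theirs)

    def test_never_more_rejections_than_bh(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        for _ in range(5):
            p = rng.random(30) ** 3
            bh = sm.multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert by_fdr(p, 0.05).sum() <= bh.sum()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            by_fdr([0.5, 1.2], 0.05)


class TestRunOrderProbe:
    def test_single_run_cohort_rejected(self):
        cohort = generate_cohort(CohortConfig(n_subjects=30, n_runs=1, seed=0))
        with pytest.raises(ValueError):
            randomized_run_fit_change(
                cohort, CVScheme(n_folds=3, seed=0), PredictorSpec(inner_folds=2),
                [2.0],
            )

    def test_identity_permutation_leaves_grid_unchanged(self):
        """Full-session scan times are permutation-invariant: FC from all
        runs does not depend on their order."""
        cohort = generate_cohort(CohortConfig(n_subjects=40, n_runs=2, seed=1))
        from bwasplan.cohort import randomize_run_order

        full_t = cohort.config.max_usable_t_min
        a = observe_fc(cohort, full_t)
        b = observe_fc(randomize_run_order(cohort, 123), full_t)
        np.testing.assert_allclose(a, b, atol=1e-12)
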