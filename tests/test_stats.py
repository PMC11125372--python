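"""PCA, stepwise Wilks' lambda selection, LDA, LOOCV, allocation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vitimorph.stats import (
    StepwiseLDA,
    classify_unknown,
    fit_lda,
    loocv_classify,
    round_report,
    run_pca,
    stepwise_select,
    threshold_allocate,
)


def two_gaussians(rng, delta, n, dims=4):
    """Spherical groups separated by Mahalanobis distance delta."""
    X = rng.standard_normal((2 * n, dims))
    X[:n, 0] += delta / 2.0
    X[n:, 0] -= delta / 2.0
    y = np.array(["A"] * n + ["B"] * n)
    return X, y


class TestPCA:
    def test_known_variances_give_known_fractions(self, rng):
        n = 200_000  # large so sample variances are essentially exact
        X = np.column_stack(
            [2.0 * rng.standard_normal(n), rng.standard_normal(n)]
        )
        r = run_pca(X)
        assert np.allclose(r.explained_variance_ratio, [0.8, 0.2], atol=5e-3)

    def test_fractions_sum_to_one_scores_centered_uncorrelated(self, rng):
        X = rng.standard_normal((50, 24)) @ rng.standard_normal((24, 24))
        r = run_pca(X)
        assert abs(r.explained_variance_ratio.sum() - 1.0) < 1e-10
        assert np.all(np.diff(r.explained_variance_ratio) <= 1e-12)
        assert np.abs(r.scores.mean(axis=0)).max() < 1e-10
        c = np.corrcoef(r.scores[:, :10], rowvar=False)
        assert np.abs(c - np.eye(10)).max() < 1e-8

    def test_agrees_with_svd_oracle_up_to_sign(self, rng):
        X = rng.standard_normal((50, 24))
        r = run_pca(X)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        for j in range(5):
            v = Vt[j]
            sign = np.sign(v[np.argmax(np.abs(v))])
            assert np.abs(r.loadings[:, j] - sign * v).max() < 1e-8
            assert np.abs(r.scores[:, j] - sign * U[:, j] * s[j]).max() < 1e-8

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            run_pca(np.ones((10, 3)))


class TestStepwise:
    def test_informative_variable_enters_first(self, rng):
        n = 30
        X = rng.standard_normal((2 * n, 11))
        y = np.array(["A"] * n + ["B"] * n)
        X[:n, 3] += 5.0
        X[n:, 3] -= 5.0
        sel = stepwise_select(X, y)
        assert sel[0] == 3
        # exhaustive one-variable Wilks' lambda scan as an oracle
        lams = []
        for j in range(11):
            xj = X[:, j]
            tot = np.sum((xj - xj.mean()) ** 2)
            within = sum(
                np.sum((xj[y == g] - xj[y == g].mean()) ** 2) for g in "AB"
            )
            lams.append(within / tot)
        assert int(np.argmin(lams)) == 3

    def test_duplicated_informative_column_selected_once(self, rng):
        n = 30
        X = rng.standard_normal((2 * n, 8))
        y = np.array(["A"] * n + ["B"] * n)
        X[:n, 2] += 4.0
        X[n:, 2] -= 4.0
        X[:, 6] = X[:, 2]
        sel = stepwise_select(X, y)
        assert 2 in sel and 6 not in sel

    def test_constant_column_never_selected(self, rng):
        X, y = two_gaussians(rng, 3.0, 30)
        X[:, 2] = 7.0
        assert 2 not in stepwise_select(X, y)

    def test_pure_noise_false_entry_rate(self, rng):
        """With all variables pure noise the chance that anything enters
        matches the max-partial-F rate implied by the F-to-enter threshold
        (independence approximation; band fixed a priori at the 99% binomial
        interval plus 0.03 for the approximation)."""
        n, p, reps = 30, 10, 300
        entered = 0
        for _ in range(reps):
            X = rng.standard_normal((2 * n, p))
            y = np.array(["A"] * n + ["B"] * n)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                sel = stepwise_select(X, y)
            entered += bool(sel)
        p_enter = sps.f.sf(3.84, 1, 2 * n - 2)
        p_any = 1.0 - (1.0 - p_enter) ** p
        half = 2.576 * np.sqrt(p_any * (1 - p_any) / reps) + 0.03
        assert abs(entered / reps - p_any) < half

    def test_no_entry_returns_empty_with_warning(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array(["A"] * 10 + ["B"] * 10)
        with pytest.warns(UserWarning, match="no variable"):
            sel = stepwise_select(X, y, f_enter=1e6, f_remove=1e5)
        assert sel == []

    def test_enter_must_exceed_remove(self, rng):
        X, y = two_gaussians(rng, 2.0, 10)
        with pytest.raises(ValueError):
            stepwise_select(X, y, f_enter=2.0, f_remove=3.0)


class TestLDA:
    def test_equal_prior_boundary_is_perpendicular_bisector(self, rng):
        X, y = two_gaussians(rng, 4.0, 200, dims=3)
        m = fit_lda(X, y)
        pts = rng.uniform(-4, 4, size=(200, 3))
        post = m.predict_proba(pts)
        mu_a = X[y == "A"].mean(axis=0)
        mu_b = X[y == "B"].mean(axis=0)
        d_a = np.linalg.norm(pts - mu_a, axis=1)
        d_b = np.linalg.norm(pts - mu_b, axis=1)
        # spherical sample covariance: nearer mean has the higher posterior
        margin = np.abs(d_a - d_b) > 0.35
        agree = (post[:, 0] > 0.5) == (d_a < d_b)
        assert agree[margin].all()

    def test_posterior_at_far_group_mean_is_decisive(self, rng):
        X, y = two_gaussians(rng, 10.0, 100)
        m = fit_lda(X, y)
        post = m.predict_proba(X[y == "A"].mean(axis=0)[None, :])
        assert post[0, list(m.classes_).index("A")] > 0.999

    def test_classification_functions_match_normal_equations_oracle(self, rng):
        # 3 groups, 4 variables; oracle solves the linear systems directly
        n = 20
        X = rng.standard_normal((3 * n, 4))
        X[:n, 0] += 2.0
        X[n:2 * n, 1] += 2.0
        y = np.repeat(["a", "b", "c"], n)
        m = fit_lda(X, y)
        means = np.vstack([X[y == g].mean(axis=0) for g in ("a", "b", "c")])
        W = np.zeros((4, 4))
        for g in ("a", "b", "c"):
            Z = X[y == g] - X[y == g].mean(axis=0)
            W += Z.T @ Z
        S = W / (3 * n - 3)
        coef = np.linalg.solve(S, means.T).T
        intercept = -0.5 * np.einsum("ij,ij->i", coef, means) + np.log(1 / 3)
        assert np.abs(m.coef_ - coef).max() < 1e-8
        assert np.abs(m.intercept_ - intercept).max() < 1e-8

    def test_posteriors_match_sklearn_reference(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        n = 30
        X = rng.standard_normal((3 * n, 5))
        X[:n, 0] += 1.5
        X[2 * n:, 2] -= 1.5
        y = np.repeat(["a", "b", "c"], n)
        mine = fit_lda(X, y, priors="proportional").predict_proba(X)
        ref = LinearDiscriminantAnalysis().fit(X, y).predict_proba(X)
        assert np.abs(mine - ref).max() < 1e-10

    def test_posteriors_normalized_and_translation_invariant(self, rng):
        X, y = two_gaussians(rng, 2.0, 50)
        m1 = fit_lda(X, y)
        m2 = fit_lda(X + 13.5, y)
        p1, p2 = m1.predict_proba(X), m2.predict_proba(X + 13.5)
        assert np.abs(p1.sum(axis=1) - 1.0).max() < 1e-10
        assert np.abs(p1 - p2).max() < 1e-8

    def test_singular_covariance_falls_back_to_ridge(self, rng):
        X, y = two_gaussians(rng, 3.0, 20, dims=3)
        X = np.column_stack([X, X[:, 0]])  # exactly collinear
        m = fit_lda(X, y)
        assert np.isfinite(m.predict_proba(X)).all()

    def test_tiny_groups_rejected(self, rng):
        X = rng.standard_normal((3, 2))
        with pytest.raises(ValueError):
            fit_lda(X, np.array(["a", "a", "b"]))


class TestLOOCV:
    def test_identical_distributions_classify_at_chance(self, rng):
        X = rng.standard_normal((200, 4))
        y = np.array(["A"] * 100 + ["B"] * 100)
        rep = loocv_classify(X, y)
        half = 100 * 2.576 * np.sqrt(0.25 / 200)
        assert abs(rep.correct_pct - 50.0) < half

    @pytest.mark.parametrize("delta", [1.0, 2.0, 4.0])
    def test_accuracy_tracks_gaussian_bayes_rate(self, rng, delta):
        n = 200
        X, y = two_gaussians(rng, delta, n)
        rep = loocv_classify(X, y)
        p = sps.norm.cdf(delta / 2.0)
        half = 100 * 2.576 * np.sqrt(p * (1 - p) / (2 * n))
        assert abs(rep.correct_pct - 100 * p) < half + 1.0

    def test_confusion_rows_sum_to_100_posteriors_to_1(self, rng):
        X, y = two_gaussians(rng, 2.0, 30)
        rep = loocv_classify(X, y)
        assert np.allclose(rep.confusion_pct.sum(axis=1), 100.0, atol=0.1)
        assert np.abs(rep.posteriors.sum(axis=1) - 1.0).max() < 1e-10

    def test_specimen_order_irrelevant(self, rng):
        X, y = two_gaussians(rng, 1.5, 25)
        perm = rng.permutation(len(y))
        a = loocv_classify(X, y)
        b = loocv_classify(X[perm], y[perm])
        assert np.allclose(a.confusion_pct.values, b.confusion_pct.values)
        assert a.correct_pct == b.correct_pct

    def test_group_below_three_rejected(self, rng):
        X = rng.standard_normal((12, 3))
        y = np.array(["A"] * 10 + ["B"] * 2)
        with pytest.raises(ValueError, match="too small"):
            loocv_classify(X, y)


class TestAllocation:
    def test_unknowns_from_a_reference_group_return_home(self, rng):
        n = 100
        X, y = two_gaussians(rng, 6.0, n)
        m = fit_lda(X, y)
        unknown = rng.standard_normal((200, 4))
        unknown[:, 0] += 3.0  # group A's generator
        post, table = classify_unknown(m, unknown)
        assert table.percentages["A"] >= 95.0

    def test_equidistant_unknown_splits_posteriors_evenly(self, rng):
        Z = rng.standard_normal((50, 3))
        X = np.vstack([Z + [2, 0, 0], Z - [2, 0, 0]])  # mirror-symmetric
        y = np.array(["A"] * 50 + ["B"] * 50)
        m = fit_lda(X, y)
        midpoint = Z.mean(axis=0)[None, :]  # equidistant from both means
        post = m.predict_proba(midpoint)
        assert abs(post[0, 0] - 0.5) < 1e-8

    def test_threshold_boundary_inclusive(self):
        post = pd.DataFrame([[0.91, 0.05, 0.04], [0.89, 0.06, 0.05],
                             [0.90, 0.05, 0.05]], columns=list("ABC"))
        table = threshold_allocate(post, p_min=0.90)
        assert table.counts["A"] == 2          # 0.91 and the exact 0.90
        assert table.counts["unassigned"] == 1  # 0.89 falls short
        assert abs(table.percentages.sum() - 100.0) < 0.1

    def test_vanishing_threshold_reproduces_argmax_allocation(self, rng):
        raw = rng.dirichlet(np.ones(4), size=40)
        post = pd.DataFrame(raw, columns=list("ABCD"))
        argmax = threshold_allocate(post, p_min=None)
        tiny = threshold_allocate(post, p_min=1e-12)
        for g in "ABCD":
            assert tiny.counts[g] == argmax.counts[g]
        assert tiny.counts["unassigned"] == 0

    def test_invalid_threshold_rejected(self):
        post = pd.DataFrame([[0.6, 0.4]], columns=list("AB"))
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                threshold_allocate(post, p_min=bad)


class TestAllocationProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        raw=st.lists(
            st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
            min_size=1, max_size=30,
        ),
        p_min=st.floats(0.05, 1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_percentages_partition_the_unknown_set(self, raw, p_min):
        post = pd.DataFrame(np.asarray(raw), columns=list("ABC"))
        post = post.div(post.sum(axis=1), axis=0)
        table = threshold_allocate(post, p_min=p_min)
        assert abs(table.percentages.sum() - 100.0) < 0.1
        assert table.counts.sum() == len(post)
        assert table.counts["unassigned"] >= 0
        # tightening the threshold never reassigns anyone back
        looser = threshold_allocate(post, p_min=p_min / 2.0)
        assert looser.counts["unassigned"] <= table.counts["unassigned"]


def test_round_report_half_away_from_zero():
    assert round_report(0.05, 1) == 0.1
    assert round_report(-0.05, 1) == -0.1
    assert round_report(2.25, 1) == 2.3
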