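"""Shrinkage moments, CAT scores, selection, discriminant, partial correlations."""

import numpy as np
import pytest

from minf.slda import (
    cat_scores,
    crossval_select,
    fit_slda,
    partial_correlations,
    predict_slda,
    shrink_moments,
    t_scores,
)


def _two_class(rng, n=40, p=5, shift=None):
    X = rng.standard_normal((n, p))
    y = np.array(["a", "b"] * (n // 2))
    if shift is not None:
        X[y == "b"] += shift
    return X, y


class TestShrinkMoments:
    def test_lambdas_in_unit_interval(self):
        rng = np.random.default_rng(0)
        X, y = _two_class(rng, n=20, p=10)
        m = shrink_moments(X, y)
        assert 0.0 <= m.lambda_corr <= 1.0
        assert 0.0 <= m.lambda_var <= 1.0

    def test_correlation_approaches_identity_for_independent_features(self):
        rng = np.random.default_rng(1)
        X, y = _two_class(rng, n=2000, p=5)
        m = shrink_moments(X, y)
        assert np.abs(m.correlation - np.eye(5)).max() < 0.1

    def test_lambda_small_for_strongly_correlated_features(self):
        # true correlation signal: the data-driven intensity must not erase it
        rng = np.random.default_rng(30)
        base = rng.standard_normal((2000, 1))
        X = 0.9 * base + 0.45 * rng.standard_normal((2000, 5))
        y = np.array(["a", "b"] * 1000)
        m = shrink_moments(X, y)
        assert m.lambda_corr < 0.2
        assert m.correlation[0, 1] > 0.5

    def test_perfect_correlation_shrunk_below_one(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(8)
        X = np.column_stack([base, base])
        y = np.array(["a", "b"] * 4)
        m = shrink_moments(X, y)
        assert abs(m.correlation[0, 1]) < 1.0
        assert m.lambda_corr > 0.0

    def test_single_feature_degenerate(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((10, 1))
        y = np.array(["a", "b"] * 5)
        m = shrink_moments(X, y)
        assert m.correlation.shape == (1, 1)
        assert m.correlation[0, 0] == 1.0
        assert m.lambda_corr == 0.0

    def test_constant_feature_floored(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((12, 3))
        X[:, 1] = 7.0
        y = np.array(["a", "b"] * 6)
        m = shrink_moments(X, y)
        assert np.isfinite(m.variances).all()
        assert (m.variances > 0).all()

    def test_correlation_psd_unit_diagonal(self):
        rng = np.random.default_rng(5)
        X, y = _two_class(rng, n=16, p=12)
        m = shrink_moments(X, y)
        np.testing.assert_allclose(np.diag(m.correlation), 1.0)
        np.testing.assert_allclose(m.correlation, m.correlation.T)
        assert np.linalg.eigvalsh(m.correlation).min() > 0


class TestCATScores:
    def test_equals_t_under_identity_correlation(self):
        rng = np.random.default_rng(6)
        X, y = _two_class(rng, n=30, p=4, shift=[1.0, 0, 0, 0])
        m = shrink_moments(X, y, lambda_corr=1.0)
        np.testing.assert_allclose(cat_scores(m), t_scores(m))

    def test_correlated_duplicates_share_mass(self):
        # closed form for a 2x2 correlation [[1, r], [r, 1]]:
        # P^(-1/2) maps equal t-scores t0 to t0/sqrt(1+r)
        rng = np.random.default_rng(7)
        base = rng.standard_normal(40)
        noise = 0.05 * rng.standard_normal(40)
        y = np.array(["a", "b"] * 20)
        shift = (y == "b") * 1.0
        X = np.column_stack([base + shift, base + noise + shift])
        m = shrink_moments(X, y)
        tau = cat_scores(m)
        t = t_scores(m)
        assert np.all(np.abs(tau) < np.abs(t))
        r = m.correlation[0, 1]
        t_mean = t.mean()
        expected = t_mean / np.sqrt(1 + r)
        assert tau[0] == pytest.approx(expected, rel=0.15)

    def test_sign_matches_mean_difference_when_identity(self):
        rng = np.random.default_rng(8)
        X, y = _two_class(rng, n=60, p=3, shift=[2.0, -2.0, 0.0])
        m = shrink_moments(X, y, lambda_corr=1.0)
        tau = cat_scores(m)
        diff = m.means[0] - m.means[1]
        assert np.sign(tau[0]) == np.sign(diff[0])
        assert np.sign(tau[1]) == np.sign(diff[1])

    def test_label_swap_negates_tau(self):
        rng = np.random.default_rng(9)
        X, y = _two_class(rng, n=30, p=4, shift=[1.5, 0, 0, 0])
        tau_ab = cat_scores(shrink_moments(X, y))
        y_swapped = np.where(y == "a", "z", "a")  # 'a'<'z' flips class order
        tau_ba = cat_scores(shrink_moments(X, y_swapped))
        np.testing.assert_allclose(tau_ab, -tau_ba, atol=1e-10)

    def test_affine_feature_rescaling_invariance(self):
        # t-scores standardize by the per-feature spread, so tau is invariant
        # to affine rescaling; variance shrinkage toward the cross-feature
        # median is the one non-equivariant step, so it is switched off here
        rng = np.random.default_rng(10)
        X, y = _two_class(rng, n=30, p=4, shift=[1.0, 0.5, 0, 0])
        tau = cat_scores(shrink_moments(X, y, lambda_var=0.0))
        X2 = X * np.array([3.0, 0.2, 10.0, 1.0]) + np.array([5.0, -2.0, 0.0, 1.0])
        tau2 = cat_scores(shrink_moments(X2, y, lambda_var=0.0))
        np.testing.assert_allclose(tau, tau2, atol=1e-8)


class TestCrossvalSelect:
    def test_pure_noise_rarely_selects(self):
        empty = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X, y = _two_class(rng, n=40, p=10)
            res = crossval_select(X, y, folds=5, seed=seed)
            empty += res.included.size == 0
        assert empty >= int(0.9 * n_seeds)

    def test_strong_feature_always_selected(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            X, y = _two_class(rng, n=40, p=10, shift=[3.0] + [0.0] * 9)
            res = crossval_select(X, y, folds=5, seed=seed)
            hits += 0 in res.included
        assert hits >= int(0.95 * n_seeds)

    def test_zero_threshold_includes_everything(self):
        rng = np.random.default_rng(11)
        X, y = _two_class(rng, n=20, p=6)
        res = crossval_select(X, y, threshold=0.0)
        assert res.included.size == 6

    def test_inclusion_frequencies_in_unit_interval(self):
        rng = np.random.default_rng(12)
        X, y = _two_class(rng, n=30, p=5, shift=[2.0, 0, 0, 0, 0])
        res = crossval_select(X, y)
        assert ((res.inclusion_frequency >= 0) & (res.inclusion_frequency <= 1)).all()


class TestSLDAPredict:
    def test_zero_shrinkage_equals_classical_lda(self):
        rng = np.random.default_rng(13)
        X, y = _two_class(rng, n=60, p=4, shift=[1.0, 0.5, 0, 0])
        model = fit_slda(X, y, lambda_corr=0.0, lambda_var=0.0)
        Xt = rng.standard_normal((50, 4)) + [0.5, 0.25, 0, 0]
        pred, _ = predict_slda(model, Xt)
        # oracle: classical pooled-covariance LDA, solved directly
        mu_a, mu_b = X[y == "a"].mean(0), X[y == "b"].mean(0)
        xc = X.copy()
        xc[y == "a"] -= mu_a
        xc[y == "b"] -= mu_b
        sigma = xc.T @ xc / (60 - 2)
        w = np.linalg.solve(sigma, mu_b - mu_a)
        scores = Xt @ w - w @ (mu_a + mu_b) / 2
        expected = np.where(scores > 0, "b", "a")
        assert (pred == expected).all()

    def test_full_shrinkage_equals_diagonal_da(self):
        rng = np.random.default_rng(14)
        X, y = _two_class(rng, n=40, p=3, shift=[1.0, -1.0, 0.2])
        model = fit_slda(X, y, lambda_corr=1.0)
        Xt = rng.standard_normal((30, 3))
        pred, _ = predict_slda(model, Xt)
        v = model.moments.variances
        mu = model.moments.means
        d0 = -0.5 * np.sum((Xt - mu[0]) ** 2 / v, axis=1)
        d1 = -0.5 * np.sum((Xt - mu[1]) ** 2 / v, axis=1)
        expected = np.where(d1 > d0, "b", "a")
        assert (pred == expected).all()

    def test_class_mean_classified_with_high_posterior(self):
        rng = np.random.default_rng(15)
        X, y = _two_class(rng, n=40, p=4, shift=[2.0, 0, 0, 0])
        model = fit_slda(X, y)
        pred, post = predict_slda(model, model.moments.means[0])
        assert pred[0] == "a"
        assert post[0, 0] > 0.5

    def test_empty_selection_majority_fallback(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((21, 5))
        y = np.array(["a"] * 11 + ["b"] * 10)
        model = fit_slda(X, y, selected=np.array([], dtype=int))
        pred, post = predict_slda(model, rng.standard_normal((7, 5)))
        assert (pred == "a").all()

    def test_feature_mismatch_rejected(self):
        rng = np.random.default_rng(17)
        X, y = _two_class(rng, n=20, p=4)
        model = fit_slda(X, y, selected=np.array([0, 2]))
        with pytest.raises(ValueError, match="mismatch"):
            predict_slda(model, np.zeros((1, 7)))

    def test_swapping_labels_swaps_predictions(self):
        rng = np.random.default_rng(18)
        X, y = _two_class(rng, n=40, p=3, shift=[1.5, 0, 0])
        Xt = rng.standard_normal((20, 3))
        p1, _ = predict_slda(fit_slda(X, y), Xt)
        y2 = np.where(y == "a", "b", "a")
        p2, _ = predict_slda(fit_slda(X, y2), Xt)
        assert (p1 != p2).all()


class TestPartialCorrelations:
    def test_single_feature_reduces_to_pearson(self):
        rng = np.random.default_rng(19)
        x = rng.standard_normal(30)
        score = 0.6 * x + rng.standard_normal(30)
        out = partial_correlations(x[:, None], score)
        assert out[0]["partial_r"] == pytest.approx(np.corrcoef(x, score)[0, 1])

    def test_outcome_identical_to_feature(self):
        rng = np.random.default_rng(20)
        X = rng.standard_normal((25, 2))
        out = partial_correlations(X, X[:, 0].copy())
        assert out[0]["partial_r"] == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        # 3-variable toy table: residualize by explicit normal equations
        X = np.array([[1.0, 2.0], [2.0, 1.5], [3.0, 3.5], [4.0, 3.0], [5.0, 5.5],
                      [6.0, 5.0], [7.0, 7.5], [8.0, 6.5], [9.0, 9.0], [10.0, 8.0]])
        rng = np.random.default_rng(21)
        score = X[:, 0] - 0.5 * X[:, 1] + 0.1 * rng.standard_normal(10)
        out = partial_correlations(X, score)
        for j in range(2):
            z = X[:, 1 - j]
            A = np.column_stack([np.ones(10), z])
            bx = np.linalg.solve(A.T @ A, A.T @ X[:, j])
            by = np.linalg.solve(A.T @ A, A.T @ score)
            rx, ry = X[:, j] - A @ bx, score - A @ by
            r_expected = (rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry))
            assert out[j]["partial_r"] == pytest.approx(r_expected)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(22)
        X = rng.standard_normal((40, 3))
        score = X @ [0.5, -0.3, 0.2] + rng.standard_normal(40)
        out = partial_correlations(X, score, names=["f0", "f1", "f2"])
        df = pd.DataFrame(X, columns=["f0", "f1", "f2"]).assign(score=score)
        for j, name in enumerate(["f0", "f1", "f2"]):
            covar = [c for c in ["f0", "f1", "f2"] if c != name]
            ref = pingouin.partial_corr(df, x=name, y="score", covar=covar)
            assert out[j]["partial_r"] == pytest.approx(ref["r"].iloc[0], abs=1e-9)
            assert out[j]["p"] == pytest.approx(ref["p_val"].iloc[0], abs=1e-9)

    def test_collinear_controls_rejected(self):
        X = np.column_stack([np.arange(10.0), np.arange(10.0), np.ones(10)])
        with pytest.raises(ValueError, match="collinear"):
            partial_correlations(X, np.arange(10.0))


def test_parameter_recovery_two_informative_regions():
    """Cohorts with two d=1.5 regions put them in the top-2 mean |tau|."""
    from minf.regions import region_names
    from minf.synthetic_data import CohortSimConfig, generate_fa_cohort

    names = list(region_names())
    targets = {names.index("Tapetum L"), names.index("Genu of corpus callosum")}
    hits = 0
    n_seeds = 10
    for seed in range(n_seeds):
        cfg = CohortSimConfig(
            n_subjects=40, seed=300 + seed, include_covariates=False,
            informative_regions={"Tapetum L": 1.5, "Genu of corpus callosum": 1.5})
        t = generate_fa_cohort(cfg)
        res = crossval_select(t[names].to_numpy(), t["label"].to_numpy(), seed=seed)
        top2 = set(np.argsort(res.mean_abs_cat)[-2:])
        hits += top2 == targets
    assert hits >= int(0.8 * n_seeds)
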