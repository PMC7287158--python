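"""LDA, multiclass LDA, Gaussian Naive Bayes, Ledoit-Wolf shrinkage."""

import numpy as np
import pytest

from mvpakit import (
    LDA,
    GaussianNaiveBayes,
    MulticlassLDA,
    crossvalidate,
    ledoit_wolf_shrinkage,
    synth,
)
from mvpakit.base import DataError, HyperparameterError, LabelError


def _lw_reference(Xc):
    """Step-by-step transcription of the Ledoit-Wolf closed form with a
    scaled-identity target (independent of the implementation)."""
    n, p = Xc.shape
    S = Xc.T @ Xc / n
    nu = np.trace(S) / p
    d2 = np.linalg.norm(S - nu * np.eye(p), "fro") ** 2 / p
    b2 = 0.0
    for k in range(n):
        b2 += np.linalg.norm(np.outer(Xc[k], Xc[k]) - S, "fro") ** 2
    b2 /= n**2 * p
    return min(b2, d2) / d2


class TestLedoitWolf:
    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((50, 10))
        Xc = X - X.mean(axis=0)
        lam = ledoit_wolf_shrinkage(Xc)
        assert lam == pytest.approx(_lw_reference(Xc), abs=1e-12)
        assert 0.0 <= lam <= 1.0

    def test_matches_sklearn_oracle(self):
        sklearn_cov = pytest.importorskip("sklearn.covariance")
        rng = np.random.default_rng(7)
        X = rng.standard_normal((60, 8))
        Xc = X - X.mean(axis=0)
        expected = sklearn_cov.ledoit_wolf_shrinkage(Xc, assume_centered=True)
        assert ledoit_wolf_shrinkage(Xc) == pytest.approx(expected, abs=1e-10)

    def test_zero_scatter_gives_full_shrinkage(self):
        assert ledoit_wolf_shrinkage(np.zeros((2, 4))) == 1.0

    def test_single_sample_rejected(self):
        with pytest.raises(DataError):
            ledoit_wolf_shrinkage(np.zeros((1, 4)))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((10, 30))  # p > n: heavy shrinkage
        assert 0.0 <= ledoit_wolf_shrinkage(X - X.mean(0)) <= 1.0


class TestBinaryLDA:
    def test_mirrored_classes_give_zero_bias(self, rng):
        X1 = rng.standard_normal((30, 3)) + [2, 0, 0]
        X = np.vstack([X1, -X1])
        y = np.repeat([1, 2], 30)
        model = LDA(shrinkage=0.5).fit(X, y)
        assert model.b_ == pytest.approx(0.0, abs=1e-10)

    def test_full_shrinkage_recovers_mean_difference_direction(self, rng):
        X = np.vstack(
            [rng.standard_normal((50, 2)) + [1, 0],
             rng.standard_normal((50, 2)) + [-1, 0]]
        )
        y = np.repeat([1, 2], 50)
        model = LDA(shrinkage=1.0).fit(X, y)
        # with Sigma_reg = nu*I, w is parallel to m1 - m2
        m_diff = model.class_means_[0] - model.class_means_[1]
        cosine = model.w_ @ m_diff / (
            np.linalg.norm(model.w_) * np.linalg.norm(m_diff)
        )
        assert cosine == pytest.approx(1.0, abs=1e-12)

    def test_sign_agrees_with_least_squares_regression(self, rng):
        """Binary LDA is equivalent to linear regression on +-1 labels:
        identical decision signs sample by sample."""
        X = np.vstack(
            [rng.standard_normal((28, 4)) + 0.8, rng.standard_normal((28, 4)) - 0.4]
        )
        y = np.repeat([1, 2], 28)
        model = LDA(shrinkage=0.0).fit(X, y)
        y_pm = np.where(y == 1, 1.0, -1.0)
        Xa = np.hstack([X, np.ones((len(X), 1))])
        coef, *_ = np.linalg.lstsq(Xa, y_pm, rcond=None)
        ls_dval = Xa @ coef
        np.testing.assert_array_equal(
            np.sign(model.decision_function(X)), np.sign(ls_dval)
        )

    def test_midpoint_has_half_probability(self):
        X = np.array([[1.0, 0], [1, 1], [-1, 0], [-1, 1]])
        y = np.array([1, 1, 2, 2])
        model = LDA(shrinkage=1.0, prior="equal").fit(X, y)
        mid = model.class_means_.mean(axis=0)
        assert model.predict_proba([mid])[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_hand_worked_decision_value(self):
        """m1=(1,0), m2=(-1,0), Sigma_reg = I -> dval(x=(2,0)) = 2.

        The 4-point configuration has exact class means (+-1, 0) and,
        at full shrinkage, exactly the identity regularized covariance;
        projected class means sit at +-1, so x=(2,0) scores 2."""
        X = np.array([[1.0, 1], [1, -1], [-1, 1], [-1, -1]])
        y = np.array([1, 1, 2, 2])
        model = LDA(shrinkage=1.0).fit(X, y)
        np.testing.assert_allclose(model.cov_, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(model.w_, [1.0, 0.0], atol=1e-12)
        assert model.b_ == pytest.approx(0.0, abs=1e-12)
        assert model.decision_function([[2.0, 0.0]])[0] == pytest.approx(2.0)
        assert model.predict([[2.0, 0.0]])[0] == 1

    def test_positive_dval_is_first_class(self, gaussian_pair):
        Xtr, ytr, Xte, _ = gaussian_pair
        model = LDA().fit(Xtr, ytr)
        dv = model.decision_function(Xte)
        pred = model.predict(Xte)
        np.testing.assert_array_equal(pred[dv > 0], 1)
        np.testing.assert_array_equal(pred[dv < 0], 2)

    def test_invalid_lambda_rejected(self, gaussian_pair):
        Xtr, ytr, *_ = gaussian_pair
        with pytest.raises(HyperparameterError):
            LDA(shrinkage=1.5).fit(Xtr, ytr)

    def test_sample_order_invariance(self, gaussian_pair, rng):
        Xtr, ytr, Xte, _ = gaussian_pair
        perm = rng.permutation(len(ytr))
        d1 = LDA(shrinkage=0.1).fit(Xtr, ytr).decision_function(Xte)
        d2 = LDA(shrinkage=0.1).fit(Xtr[perm], ytr[perm]).decision_function(Xte)
        np.testing.assert_allclose(d1, d2, atol=1e-10)

    def test_shrinkage_moves_covariance_monotonically_to_target(self, rng):
        X = rng.standard_normal((40, 6)) @ rng.standard_normal((6, 6))
        y = np.repeat([1, 2], 20)
        dists = []
        for lam in [0.0, 0.25, 0.5, 0.75, 1.0]:
            m = LDA(shrinkage=lam).fit(X, y)
            nu = np.trace(m.cov_) / 6 if lam == 1.0 else None
            target = np.trace(m.cov_) / 6 * np.eye(6)
            dists.append(np.linalg.norm(m.cov_ - target, "fro"))
        assert all(a >= b - 1e-12 for a, b in zip(dists, dists[1:]))
        assert dists[-1] == pytest.approx(0.0, abs=1e-10)


class TestMulticlassLDA:
    def test_centroid_recovery(self):
        ds, y = synth.gen_gaussian_classes(
            n_per_class=40, p=4, separation=8.0, n_classes=3, seed=3
        )
        model = MulticlassLDA().fit(ds.values, y)
        centre_inputs = np.zeros((3, 4))
        centre_inputs[1, 0] = 8.0
        centre_inputs[2, 1] = 8.0
        np.testing.assert_array_equal(model.predict(centre_inputs), [1, 2, 3])

    def test_subspace_rank_is_k_minus_one(self):
        ds, y = synth.gen_gaussian_classes(
            n_per_class=20, p=6, separation=3.0, n_classes=3, seed=4
        )
        model = MulticlassLDA().fit(ds.values, y)
        assert model.subspace_.shape == (6, 2)
        assert np.all(np.isfinite(model.subspace_))

    def test_two_classes_redirected_to_binary_lda(self, gaussian_pair):
        Xtr, ytr, *_ = gaussian_pair
        with pytest.raises(LabelError, match="binary"):
            MulticlassLDA().fit(Xtr, ytr)

    def test_chance_level_on_label_independent_data(self):
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((150, 10))
            y = np.repeat([1, 2, 3], 50)
            g = crossvalidate(
                {"model": "multiclass_lda", "cv": "kfold", "k": 10, "seed": seed},
                X,
                y,
            )
            accs.append(g["accuracy"])
        assert np.mean(accs) == pytest.approx(1 / 3, abs=0.05)

    def test_posteriors_normalize(self):
        ds, y = synth.gen_gaussian_classes(
            n_per_class=20, p=4, separation=2.0, n_classes=4, seed=5
        )
        proba = MulticlassLDA().fit(ds.values, y).predict_proba(ds.values[:7])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-10)


class TestGaussianNaiveBayes:
    def test_symmetric_univariate_threshold(self, rng):
        X = np.concatenate(
            [rng.normal(1, 1, 300), rng.normal(-1, 1, 300)]
        )[:, None]
        y = np.repeat([1, 2], 300)
        model = GaussianNaiveBayes(prior="equal").fit(X, y)
        assert model.predict([[2.0]])[0] == 1
        assert model.predict([[-2.0]])[0] == 2

    def test_posterior_equals_hand_computed_product(self):
        """2-feature toy: posterior = product of univariate densities
        times prior, normalized by the evidence."""
        X = np.array(
            [[0.0, 1.0], [1.0, 2.0], [2.0, 0.0], [3.0, 1.0], [4.0, 4.0], [5.0, 3.0]]
        )
        y = np.array([1, 1, 1, 2, 2, 2])
        model = GaussianNaiveBayes().fit(X, y)
        x = np.array([1.5, 1.5])

        def norm_pdf(v, m, var):
            return np.exp(-((v - m) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)

        lik = np.array(
            [
                np.prod(
                    [norm_pdf(x[j], model.means_[i, j], model.variances_[i, j])
                     for j in range(2)]
                )
                for i in range(2)
            ]
        )
        expected = lik * model.priors_ / (lik @ model.priors_)
        np.testing.assert_allclose(
            model.predict_proba([x])[0], expected, atol=1e-10
        )

    def test_posteriors_sum_to_one(self, gaussian_pair):
        Xtr, ytr, Xte, _ = gaussian_pair
        proba = GaussianNaiveBayes().fit(Xtr, ytr).predict_proba(Xte)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_variance_feature_floored_with_warning(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [4.0, 5.0]])
        y = np.array([1, 1, 2, 2])
        with pytest.warns(RuntimeWarning, match="floored"):
            model = GaussianNaiveBayes().fit(X, y)
        assert np.all(model.variances_ > 0)

    def test_agrees_with_lda_on_diagonal_equal_covariance_data(self):
        """With diagonal class covariances shared across classes, Naive
        Bayes approaches the LDA decision rule at large n."""
        rng = np.random.default_rng(99)
        n = 3000
        X = np.vstack(
            [rng.standard_normal((n, 3)) * [1, 2, 0.5] + [1, 0, 0],
             rng.standard_normal((n, 3)) * [1, 2, 0.5] + [-1, 0, 0]]
        )
        y = np.repeat([1, 2], n)
        Xte = rng.standard_normal((400, 3)) * [1, 2, 0.5]
        nb = GaussianNaiveBayes().fit(X, y).predict(Xte)
        lda = LDA(shrinkage=0.0).fit(X, y).predict(Xte)
        assert np.mean(nb == lda) > 0.97
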