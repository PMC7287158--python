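"""Logistic regression, SVM dual coordinate descent, Platt scaling,
ensembles."""

import numpy as np
import pytest
import scipy.optimize

from mvpakit import (
    LDA,
    SVM,
    Ensemble,
    LogisticRegression,
    fit_platt,
    platt_probability,
)
from mvpakit.base import CalibrationError, ConfigurationError, HyperparameterError
from mvpakit.estimators.logreg import _log1pexp


class TestLogisticRegression:
    def test_separable_data_stays_finite_with_logf(self):
        """Unpenalized MLE diverges on separable data; the log-F(1,1)
        penalty keeps the optimum finite."""
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([2, 2, 1, 1])
        model = LogisticRegression(reg="logf").fit(X, y)
        assert np.all(np.isfinite(model.w_)) and np.isfinite(model.b_)
        assert model.converged_

    def test_point_symmetric_data_has_zero_bias(self, rng):
        X1 = rng.standard_normal((40, 3)) + 1.0
        X = np.vstack([X1, -X1])
        y = np.repeat([1, 2], 40)
        model = LogisticRegression(reg="logf").fit(X, y)
        assert model.b_ == pytest.approx(0.0, abs=1e-5)

    def test_l2_optimum_matches_generic_convex_optimizer(self, rng):
        """Newton solution equals an independent BFGS minimization of
        the same written objective to 1e-6."""
        X = np.vstack(
            [rng.standard_normal((15, 3)) + 0.5, rng.standard_normal((15, 3)) - 0.5]
        )
        y = np.repeat([1, 2], 15)
        lam = 1.0
        model = LogisticRegression(reg="l2", lambda_=lam, tol=1e-10).fit(X, y)
        y_pm = np.where(y == 1, 1.0, -1.0)

        def objective(theta):
            w, b = theta[:3], theta[3]
            margins = y_pm * (X @ w + b)
            return np.sum(_log1pexp(-margins)) + lam * np.sum(w**2)

        res = scipy.optimize.minimize(
            objective, np.zeros(4), method="BFGS",
            options={"gtol": 1e-10, "maxiter": 2000},
        )
        np.testing.assert_allclose(model.w_, res.x[:3], atol=1e-6)
        assert model.b_ == pytest.approx(res.x[3], abs=1e-6)

    def test_logf_optimum_matches_generic_convex_optimizer(self, rng):
        X = np.vstack(
            [rng.standard_normal((12, 2)) + 0.7, rng.standard_normal((12, 2)) - 0.7]
        )
        y = np.repeat([1, 2], 12)
        model = LogisticRegression(reg="logf", tol=1e-10).fit(X, y)
        y_pm = np.where(y == 1, 1.0, -1.0)

        def objective(theta):
            w, b = theta[:2], theta[2]
            margins = y_pm * (X @ w + b)
            return np.sum(_log1pexp(-margins)) + np.sum(_log1pexp(w) - 0.5 * w)

        res = scipy.optimize.minimize(
            objective, np.zeros(3), method="BFGS",
            options={"gtol": 1e-10, "maxiter": 2000},
        )
        np.testing.assert_allclose(model.w_, res.x[:2], atol=1e-6)

    @pytest.mark.parametrize(
        "w,b,x,dval,prob",
        [
            ((1.0, 0.0), 0.0, (0.0, 0.0), 0.0, 0.5),
            ((2.0,), -1.0, (1.0,), 1.0, 1 / (1 + np.exp(-1))),
        ],
    )
    def test_sigmoid_outputs(self, w, b, x, dval, prob):
        model = LogisticRegression()
        model.classes_ = np.array([1, 2])
        model.w_ = np.array(w)
        model.b_ = b
        assert model.decision_function([x])[0] == pytest.approx(dval)
        assert model.predict_proba([x])[0, 0] == pytest.approx(prob, abs=1e-10)

    def test_negative_lambda_rejected(self, gaussian_pair):
        Xtr, ytr, *_ = gaussian_pair
        with pytest.raises(HyperparameterError):
            LogisticRegression(reg="l2", lambda_=-1.0).fit(Xtr, ytr)


class TestSVM:
    def test_two_point_solution_solved_by_hand(self):
        """x1=(1,0) y=+1, x2=(-1,0) y=-1, large c: the KKT conditions
        give alpha = (1/2, 1/2), hence w=(1,0), b=0, dval(x1)=1."""
        model = SVM(c=1e3).fit(np.array([[1.0, 0.0], [-1.0, 0.0]]), [1, 2])
        np.testing.assert_allclose(model.alpha_, [0.5, 0.5], atol=1e-6)
        np.testing.assert_allclose(model.w_, [1.0, 0.0], atol=1e-6)
        assert model.b_ == pytest.approx(0.0, abs=1e-6)
        assert model.decision_function([[1.0, 0.0]])[0] == pytest.approx(1.0, abs=1e-6)

    def test_alphas_respect_box_constraint(self, gaussian_pair):
        Xtr, ytr, *_ = gaussian_pair
        c = 0.3
        model = SVM(c=c).fit(Xtr, ytr)
        assert np.all(model.alpha_ >= -1e-12)
        assert np.all(model.alpha_ <= c + 1e-12)

    def test_margin_samples_have_zero_alpha(self, gaussian_pair):
        """Complementary slackness: samples strictly outside the margin
        (y(w.x+b) > 1) carry no dual weight."""
        Xtr, ytr, *_ = gaussian_pair
        model = SVM(c=1.0, tol=1e-6, max_sweeps=20_000).fit(Xtr, ytr)
        y_pm = np.where(ytr == 1, 1.0, -1.0)
        margins = y_pm * model.decision_function(Xtr)
        outside = margins > 1.0 + 1e-6
        assert np.all(model.alpha_[outside] <= 1e-8)

    def test_linear_dvals_agree_between_w_and_dual_expansion(self, gaussian_pair):
        Xtr, ytr, Xte, _ = gaussian_pair
        model = SVM(c=1.0).fit(Xtr, ytr)
        via_w = Xte @ model.w_ + model.b_
        y_pm = np.where(ytr == 1, 1.0, -1.0)
        via_dual = (Xte @ Xtr.T) @ (model.alpha_ * y_pm) + model.b_
        np.testing.assert_allclose(via_w, via_dual, atol=1e-8)

    def test_dual_matches_box_qp_oracle(self, rng):
        """On a tiny instance, the coordinate-descent solution matches a
        generic box-constrained QP solve of the same dual to 1e-4 in
        objective and satisfies the KKT conditions."""
        X = np.vstack(
            [rng.standard_normal((6, 2)) + 1.0, rng.standard_normal((6, 2)) - 1.0]
        )
        y = np.repeat([1, 2], 6)
        c = 0.7
        model = SVM(c=c, tol=1e-8, max_sweeps=10_000).fit(X, y)
        y_pm = np.where(y == 1, 1.0, -1.0)
        Q = ((X @ X.T) + 1.0) * np.outer(y_pm, y_pm)

        def neg_dual(a):
            return 0.5 * a @ Q @ a - a.sum(), Q @ a - 1.0

        res = scipy.optimize.minimize(
            neg_dual, np.zeros(12), jac=True, method="L-BFGS-B",
            bounds=[(0, c)] * 12, options={"ftol": 1e-15, "gtol": 1e-12},
        )
        assert -neg_dual(model.alpha_)[0] >= -res.fun - 1e-4
        g = Q @ model.alpha_ - 1.0
        interior = (model.alpha_ > 1e-6) & (model.alpha_ < c - 1e-6)
        assert np.all(np.abs(g[interior]) < 1e-4)
        assert np.all(g[model.alpha_ <= 1e-6] > -1e-4)
        assert np.all(g[model.alpha_ >= c - 1e-6] < 1e-4)

    def test_rbf_solves_xor_where_linear_cannot(self):
        X = np.array([[0.0, 0], [1, 1], [0, 1], [1, 0]])
        y = np.array([1, 1, 2, 2])
        rbf = SVM(c=10.0, kernel="rbf", gamma=10.0).fit(X, y)
        linear = SVM(c=10.0).fit(X, y)
        assert np.mean(rbf.predict(X) == y) == 1.0
        assert np.mean(linear.predict(X) == y) < 1.0

    def test_invalid_c_rejected(self, gaussian_pair):
        Xtr, ytr, *_ = gaussian_pair
        with pytest.raises(HyperparameterError):
            SVM(c=0.0).fit(Xtr, ytr)

    def test_probability_requires_platt_fit(self, gaussian_pair):
        Xtr, ytr, Xte, _ = gaussian_pair
        with pytest.raises(CalibrationError):
            SVM(c=1.0).fit(Xtr, ytr).predict_proba(Xte)
        proba = SVM(c=1.0, probability=True).fit(Xtr, ytr).predict_proba(Xte)
        assert np.all((proba > 0) & (proba < 1))

    def test_dual_objective_non_decreasing_over_sweeps(self, gaussian_pair):
        """More sweeps can only improve the dual objective."""
        Xtr, ytr, *_ = gaussian_pair
        objs = [
            SVM(c=1.0, max_sweeps=s, tol=0.0).fit(Xtr, ytr).dual_objective()
            for s in (1, 3, 10, 50)
        ]
        assert all(b >= a - 1e-10 for a, b in zip(objs, objs[1:]))


class TestPlatt:
    def test_probabilities_monotone_in_dval(self, rng):
        dv = np.concatenate([rng.normal(1, 1, 40), rng.normal(-1, 1, 40)])
        labels = np.repeat([1, 2], 40)
        A, B = fit_platt(dv, labels)
        assert A < 0
        grid = np.linspace(-3, 3, 50)
        p = platt_probability(grid, A, B)
        assert np.all(np.diff(p) > 0)

    def test_separated_dvals_stay_strictly_inside_unit_interval(self):
        dv = np.concatenate([np.linspace(1, 2, 10), np.linspace(-2, -1, 10)])
        labels = np.repeat([1, 2], 10)
        A, B = fit_platt(dv, labels)
        p = platt_probability(dv, A, B)
        assert np.all(p > 0) and np.all(p < 1)

    def test_matches_generic_optimizer_on_smoothed_objective(self, rng):
        """Parameters agree with a direct minimization of the smoothed
        cross-entropy to 1e-4."""
        dv = np.concatenate([rng.normal(0.8, 1, 30), rng.normal(-0.8, 1, 30)])
        labels = np.repeat([1, 2], 30)
        A, B = fit_platt(dv, labels)
        t = np.where(labels == 1, 31.0 / 32.0, 1.0 / 32.0)

        def objective(theta):
            z = theta[0] * dv + theta[1]
            return np.sum(
                np.where(z >= 0, t * z + np.log1p(np.exp(-z)),
                         (t - 1) * z + np.log1p(np.exp(z)))
            )

        res = scipy.optimize.minimize(
            objective, [0.0, 0.0], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000},
        )
        assert A == pytest.approx(res.x[0], abs=1e-4)
        assert B == pytest.approx(res.x[1], abs=1e-4)

    def test_degenerate_dvals_rejected(self):
        with pytest.raises(CalibrationError):
            fit_platt(np.ones(10), np.repeat([1, 2], 5))


class TestEnsemble:
    def test_degenerate_ensemble_reproduces_base_learner(self, gaussian_pair):
        Xtr, ytr, Xte, _ = gaussian_pair
        ens = Ensemble(learner=LDA(), n_learners=1).fit(Xtr, ytr)
        base = LDA().fit(Xtr, ytr)
        np.testing.assert_array_equal(ens.predict(Xte), base.predict(Xte))

    def test_full_data_learners_all_agree_with_base(self, gaussian_pair):
        Xtr, ytr, Xte, _ = gaussian_pair
        ens = Ensemble(learner=LDA(), n_learners=7).fit(Xtr, ytr)
        base = LDA().fit(Xtr, ytr)
        np.testing.assert_array_equal(ens.predict(Xte), base.predict(Xte))

    def test_plurality_vote(self):
        """Learners voting [1, 1, 2] elect class 1."""
        ens = Ensemble(n_learners=3, strategy="vote")

        class Stub:
            def __init__(self, out):
                self.out = out

            def predict(self, X):
                return np.full(len(X), self.out)

        ens.classes_ = np.array([1, 2])
        ens.learners_ = [Stub(1), Stub(1), Stub(2)]
        ens.feature_idx_ = [np.arange(2)] * 3
        ens.n_features_ = 2
        assert ens.predict(np.zeros((4, 2)))[0] == 1

    def test_tie_goes_to_smallest_class(self):
        ens = Ensemble(n_learners=2, strategy="vote")

        class Stub:
            def __init__(self, out):
                self.out = out

            def predict(self, X):
                return np.full(len(X), self.out)

        ens.classes_ = np.array([1, 2])
        ens.learners_ = [Stub(1), Stub(2)]
        ens.feature_idx_ = [np.arange(2)] * 2
        ens.n_features_ = 2
        np.testing.assert_array_equal(ens.predict(np.zeros((3, 2))), [1, 1, 1])

    def test_dval_strategy_averages_decision_values(self, gaussian_pair):
        Xtr, ytr, Xte, _ = gaussian_pair
        ens = Ensemble(
            learner=LDA(), n_learners=5, nsamples=0.8, nfeatures=0.8,
            strategy="dval", random_state=3,
        ).fit(Xtr, ytr)
        dv = ens.decision_function(Xte)
        np.testing.assert_array_equal(
            ens.predict(Xte), np.where(dv >= 0, 1, 2)
        )

    def test_dval_strategy_needs_dval_learner(self, gaussian_pair):
        from mvpakit import NearestCentroid

        Xtr, ytr, *_ = gaussian_pair
        y3 = ytr.copy()
        y3[:5] = 3  # three classes
        with pytest.raises(ConfigurationError):
            Ensemble(learner=NearestCentroid(), strategy="dval").fit(Xtr, y3)

    def test_subset_draws_are_seeded(self, gaussian_pair):
        Xtr, ytr, Xte, _ = gaussian_pair
        a = Ensemble(learner=LDA(), n_learners=4, nsamples=0.7, nfeatures=0.6,
                     random_state=9).fit(Xtr, ytr)
        b = Ensemble(learner=LDA(), n_learners=4, nsamples=0.7, nfeatures=0.6,
                     random_state=9).fit(Xtr, ytr)
        np.testing.assert_array_equal(a.predict(Xte), b.predict(Xte))
        for fa, fb in zip(a.feature_idx_, b.feature_idx_):
            np.testing.assert_array_equal(fa, fb)
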