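import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logit

from c2dx import (
    CohortSpec,
    ElasticNetSpec,
    ResamplingRecord,
    TrainingData,
    convergence_summary,
    fit_elastic_net,
    generate_cohort,
    lambda_path,
    normalize_matrix,
    penalized_objective,
    resample_cv,
    select_model,
)
from c2dx import _solver


def make_data(n=10, p=3, seed=0, balance=0.5):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"G{j}" for j in range(p)]
    )
    y = np.zeros(n)
    y[: max(1, int(n * balance))] = 1.0
    rng.shuffle(y)
    if y.sum() in (0, n):
        y[0] = 1.0 - y[0]
    return TrainingData(X=X, y=y)


def brute_force_min(data, lam, alpha):
    """Independent general-purpose minimizer of the penalized objective."""
    f = lambda t: penalized_objective(t[0], t[1:], data, lam, alpha)
    best = np.inf
    for x0 in (np.zeros(data.X.shape[1] + 1), 0.3 * np.ones(data.X.shape[1] + 1)):
        res = minimize(
            f, x0, method="Nelder-Mead",
            options={"maxiter": 50_000, "fatol": 1e-13, "xatol": 1e-11},
        )
        best = min(best, res.fun)
    return best


class TestPenalizedObjective:
    def test_null_model_single_sample(self):
        # one sample, y = 1, null parameters, no penalty -> log 2
        val = _solver.objective(0.0, np.zeros(1), np.zeros((1, 1)), np.ones(1), 0.0, 0.5)
        assert val == pytest.approx(np.log(2.0), abs=1e-12)

    def test_l1_penalty_arithmetic(self):
        data = make_data()
        base = penalized_objective(0.0, [0.5, -0.5, 0.0], data, 0.0, 1.0)
        withpen = penalized_objective(0.0, [0.5, -0.5, 0.0], data, 1.0, 1.0)
        assert withpen - base == pytest.approx(1.0, abs=1e-12)

    def test_l2_penalty_arithmetic(self):
        data = make_data()
        base = penalized_objective(0.0, [2.0, 0.0, 0.0], data, 0.0, 0.0)
        withpen = penalized_objective(0.0, [2.0, 0.0, 0.0], data, 1.0, 0.0)
        assert withpen - base == pytest.approx(2.0, abs=1e-12)  # lam*||b||^2/2

    def test_nonfinite_rejected(self):
        data = make_data()
        with pytest.raises(ValueError):
            penalized_objective(np.nan, [0.0, 0.0, 0.0], data, 0.1, 0.5)


class TestFitElasticNet:
    def test_full_shrinkage_at_lambda_max(self):
        data = make_data(n=20, seed=3, balance=0.6)
        for alpha in (0.5, 1.0):
            lmax = _solver.lambda_max(data.X.to_numpy(), data.y, alpha)
            model = fit_elastic_net(data, lmax * 1.01, alpha)
            assert all(b == 0.0 for b in model.coefficients.values())
            assert model.intercept == pytest.approx(logit(data.y.mean()), abs=1e-6)

    def test_unregularized_fit_matches_numeric_mle(self):
        # tiny non-separable (XOR-patterned) instance: 4 samples, 2 genes
        X = pd.DataFrame({"G0": [0.0, 1.0, 0.0, 1.0], "G1": [0.0, 0.0, 1.0, 1.0]})
        data = TrainingData(X=X, y=np.array([0.0, 1.0, 1.0, 0.0]))
        model = fit_elastic_net(data, 0.0, 0.5)
        f = lambda t: penalized_objective(t[0], t[1:], data, 0.0, 0.5)
        res = minimize(f, np.zeros(3), method="BFGS", options={"gtol": 1e-12})
        np.testing.assert_allclose(
            [model.intercept] + [model.coefficients[g] for g in X.columns],
            res.x, atol=1e-4,
        )

    def test_duplicating_samples_leaves_solution_unchanged(self):
        data = make_data(n=8, seed=5)
        doubled = TrainingData(
            X=pd.concat([data.X, data.X], ignore_index=True),
            y=np.concatenate([data.y, data.y]),
        )
        m1 = fit_elastic_net(data, 0.0, 0.5)
        m2 = fit_elastic_net(doubled, 0.0, 0.5)
        np.testing.assert_allclose(
            list(m1.coefficients.values()), list(m2.coefficients.values()), atol=1e-6
        )

    @pytest.mark.parametrize("lam,alpha", [(0.02, 0.0), (0.02, 0.5), (0.02, 1.0),
                                           (0.2, 0.3), (0.1, 1.0)])
    def test_matches_generic_minimizer(self, lam, alpha):
        data = make_data(n=10, p=3, seed=11)
        model = fit_elastic_net(data, lam, alpha)
        ours = penalized_objective(
            model.intercept, model.coefficients, data, lam, alpha
        )
        assert ours <= brute_force_min(data, lam, alpha) + 1e-6

    def test_l1_norm_shrinks_along_lambda(self):
        data = make_data(n=30, p=3, seed=2, balance=0.5)
        lams = lambda_path(data, 0.7)
        norms = []
        for lam in lams[::10]:
            model = fit_elastic_net(data, lam, 0.7)
            norms.append(sum(abs(b) for b in model.coefficients.values()))
        # path is decreasing in lambda, so L1 norms must be non-decreasing
        assert all(b >= a - 1e-8 for a, b in zip(norms, norms[1:]))


class TestResampleCv:
    def test_same_seed_reproduces_records(self, small_cohort):
        matrix, truth = small_cohort
        nm = normalize_matrix(matrix, truth.panel)
        data = TrainingData.from_normalized(nm)
        spec = ElasticNetSpec(alpha_grid=(0.0, 0.5, 1.0), n_resamples=3, seed=9)
        assert resample_cv(data, spec) == resample_cv(data, spec)

    def test_class_smaller_than_folds_rejected(self):
        data = make_data(n=8, balance=0.25, seed=1)
        with pytest.raises(ValueError, match="k_folds"):
            resample_cv(data, ElasticNetSpec(n_resamples=1, k_folds=5))

    def test_near_separable_regime_has_high_accuracy(self):
        """Very large effects (log2FC = 4, n = 60): mean accuracy >= 0.95.

        Scaled to 10 resamples to keep the default run fast; the full-scale
        check lives in the acceptance suite.
        """
        matrix, truth = generate_cohort(
            CohortSpec(n_luad=30, n_lusc=30, n_nos=0, effect_log2fc=4.0, seed=21)
        )
        data = TrainingData.from_normalized(normalize_matrix(matrix, truth.panel))
        records = resample_cv(
            data, ElasticNetSpec(alpha_grid=(0.1, 0.5, 1.0), n_resamples=10, seed=21)
        )
        assert np.mean([r.cv_accuracy for r in records]) >= 0.95

    def test_records_within_bounds(self, small_cohort):
        matrix, truth = small_cohort
        data = TrainingData.from_normalized(normalize_matrix(matrix, truth.panel))
        records = resample_cv(
            data, ElasticNetSpec(alpha_grid=(0.5,), n_resamples=2, seed=0)
        )
        for r in records:
            assert 0.0 <= r.cv_accuracy <= 1.0
            assert 0 <= r.complexity <= len(data.genes)
            assert r.best_lambda > 0


class TestSelectModel:
    @staticmethod
    def records_for(alpha_to_acc, lam=0.05):
        return [
            ResamplingRecord(resample_id=i, alpha=a, best_lambda=lam,
                             cv_accuracy=acc, complexity=3)
            for a, acc in alpha_to_acc.items()
            for i in range(2)
        ]

    def test_argmax_alpha_chosen(self, small_cohort):
        matrix, truth = small_cohort
        data = TrainingData.from_normalized(normalize_matrix(matrix, truth.panel))
        records = self.records_for({0.2: 0.8, 0.5: 0.9, 0.8: 0.8})
        chosen, summary, model = select_model(records, data, ElasticNetSpec())
        assert chosen == 0.5
        assert summary.attrs["final_lambda"] == 0.05

    def test_tie_goes_to_smaller_alpha(self, small_cohort):
        matrix, truth = small_cohort
        data = TrainingData.from_normalized(normalize_matrix(matrix, truth.panel))
        records = self.records_for({0.3: 0.9, 0.7: 0.9})
        chosen, _, _ = select_model(records, data, ElasticNetSpec())
        assert chosen == 0.3

    def test_final_lambda_is_median_of_best(self, small_cohort):
        matrix, truth = small_cohort
        data = TrainingData.from_normalized(normalize_matrix(matrix, truth.panel))
        records = [
            ResamplingRecord(resample_id=i, alpha=0.5, best_lambda=lam,
                             cv_accuracy=0.9, complexity=3)
            for i, lam in enumerate((0.01, 0.04, 0.20))
        ]
        _, summary, _ = select_model(records, data, ElasticNetSpec())
        assert summary.attrs["final_lambda"] == 0.04

    def test_empty_records_rejected(self, small_cohort):
        matrix, truth = small_cohort
        data = TrainingData.from_normalized(normalize_matrix(matrix, truth.panel))
        with pytest.raises(ValueError):
            select_model([], data, ElasticNetSpec())


class TestConvergenceSummary:
    @staticmethod
    def records_with_accuracies(accs, alpha=0.5):
        return [
            ResamplingRecord(resample_id=i, alpha=alpha, best_lambda=0.1,
                             cv_accuracy=a, complexity=5)
            for i, a in enumerate(accs)
        ]

    def test_constant_records_have_zero_width(self):
        records = self.records_with_accuracies([0.9] * 50)
        out = convergence_summary(records, [10, 50])
        assert np.allclose(out["ci_hi"] - out["ci_lo"], 0.0)

    def test_single_resample_has_undefined_sd(self):
        records = self.records_with_accuracies([0.9, 0.8])
        out = convergence_summary(records, [1])
        assert out["sd"].isna().all()

    def test_checkpoint_zero_rejected(self):
        records = self.records_with_accuracies([0.9, 0.8])
        with pytest.raises(ValueError):
            convergence_summary(records, [0])

    def test_half_width_matches_closed_form(self):
        """i.i.d. accuracies with sd 0.05: half-width at k=1000 near 0.0031."""
        rng = np.random.default_rng(0)
        accs = np.clip(rng.normal(0.8, 0.05, 1000), 0.0, 1.0)
        records = self.records_with_accuracies(accs)
        out = convergence_summary(records, [1000])
        row = out[(out["metric"] == "cv_accuracy")].iloc[0]
        half = (row["ci_hi"] - row["ci_lo"]) / 2
        assert half == pytest.approx(1.96 * 0.05 / np.sqrt(1000), rel=0.05)

    def test_ci_width_shrinks_with_resamples(self):
        rng = np.random.default_rng(1)
        records = self.records_with_accuracies(
            np.clip(rng.normal(0.85, 0.05, 400), 0, 1)
        )
        out = convergence_summary(records, [20, 400])
        acc = out[out["metric"] == "cv_accuracy"].set_index("checkpoint")
        width = acc["ci_hi"] - acc["ci_lo"]
        assert width.loc[400] < width.loc[20]

    def test_per_resample_optimum_prefers_smaller_alpha_on_tie(self):
        records = [
            ResamplingRecord(resample_id=0, alpha=0.8, best_lambda=0.1,
                             cv_accuracy=0.9, complexity=5),
            ResamplingRecord(resample_id=0, alpha=0.2, best_lambda=0.1,
                             cv_accuracy=0.9, complexity=7),
        ]
        out = convergence_summary(records, [1])
        alpha_row = out[out["metric"] == "alpha"].iloc[0]
        assert alpha_row["mean"] == 0.2
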