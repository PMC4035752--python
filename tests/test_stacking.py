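"""Design-matrix expansion, the L1 logistic path, CV and penalty selection."""

import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from callstack.data_model import CallDataset, DataError, Site
from callstack.stacking import (
    FeatureConfig,
    StackedFit,
    binomial_deviance,
    build_design_matrix,
    cross_validate,
    default_lambda_path,
    fit_l1_logistic_path,
    fit_stacked_caller,
    kkt_violation,
    predict_proba,
    select_lambda_1se,
)

from conftest import make_dataset


def logistic_instance(seed, n=300, L=8, sparsity=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, L))
    beta = np.zeros(L)
    beta[rng.choice(L, sparsity, replace=False)] = rng.normal(scale=1.0, size=sparsity)
    y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
    if y.min() == y.max():  # pragma: no cover - extremely unlikely
        y[0] = 1 - y[0]
    return X, y, beta


class TestDesignMatrix:
    def test_default_config_gives_111_columns(self, sim_dataset):
        dm = build_design_matrix(sim_dataset)
        assert dm.shape == (sim_dataset.n, 111)
        from collections import Counter

        groups = Counter(dm.column_groups)
        assert groups == {"combo_status": 6, "genomic": 4, "substitution": 11, "interaction": 90}

    def test_combo_only_config_gives_6_columns(self, sim_dataset):
        dm = build_design_matrix(
            sim_dataset,
            FeatureConfig(include_genomic=False, include_substitution=False, include_interactions=False),
        )
        assert dm.shape[1] == 6
        assert dm.values.sum(axis=1).max() <= 1  # one indicator per site, reference level zeroed

    def test_marginal_encoding_keeps_all_callers(self, sim_dataset):
        dm = build_design_matrix(
            sim_dataset,
            FeatureConfig(combo_encoding="marginal", include_substitution=False),
        )
        # 3 marginal calls + 4 genomic + 3*4 interactions
        assert dm.shape[1] == 19

    def test_single_site_row_matches_hand_expansion(self):
        site = Site("1", 50, "G", "T")
        ds = CallDataset(
            sites=[site],
            caller_names=["A", "B", "C"],
            calls=np.array([[1, 0, 1]]),
            features=pd.DataFrame(
                [{"depth_tumor": 80.0, "depth_normal": 60.0, "vaf_tumor": 0.4,
                  "vaf_normal": 0.01, "substitution": "G>T"}]
            ),
        )
        dm = build_design_matrix(ds)
        row = dict(zip(dm.columns, dm.values[0]))
        assert row["status[A+C]"] == 1.0
        assert sum(v for c, v in row.items() if c.startswith("status[") and "*" not in c) == 1.0
        assert row["sub[G>T]"] == 1.0
        assert sum(v for c, v in row.items() if c.startswith("sub[")) == 1.0
        assert row["depth_tumor"] == 80.0 and row["vaf_tumor"] == 0.4
        assert row["status[A+C]*depth_tumor"] == 80.0  # product of indicator and feature
        assert row["status[A+B]*depth_tumor"] == 0.0
        assert row["status[A+C]*sub[G>T]"] == 1.0

    def test_missing_features_imputed_with_indicator(self, sim_dataset):
        ds = sim_dataset.subset(np.arange(200))
        ds.features = ds.features.copy()
        ds.features.loc[3, "depth_tumor"] = np.nan
        dm = build_design_matrix(ds)
        assert "missing[depth_tumor]" in dm.columns
        med = dm.medians["depth_tumor"]
        col = dm.columns.index("depth_tumor")
        assert dm.values[3, col] == med
        assert dm.values[3, dm.columns.index("missing[depth_tumor]")] == 1.0
        # prediction mode reuses training medians and the indicator layout
        dm2 = build_design_matrix(ds, medians=dm.medians, missing_indicator_cols=dm.missing_indicator_cols)
        assert dm2.columns == dm.columns

    def test_interactions_without_features_fatal(self):
        with pytest.raises(DataError):
            FeatureConfig(include_genomic=False, include_substitution=False, include_interactions=True)


class TestPathSolver:
    def test_null_model_at_lambda_max(self):
        X, y, _ = logistic_instance(0)
        path = fit_l1_logistic_path(X, y)
        assert np.all(path["coefs"][:, 0] == 0.0)
        assert path["intercepts"][0] == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-6)

    def test_kkt_holds_along_path(self):
        X, y, _ = logistic_instance(1)
        path = fit_l1_logistic_path(X, y, tol=1e-8)
        for j, lam in enumerate(path["lambdas"]):
            v = kkt_violation(X, y, path["intercepts"][j], path["coefs"][:, j], lam)
            assert v <= 1e-7

    def test_single_class_labels_fatal(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(DataError):
            fit_l1_logistic_path(X, np.ones(20))

    def test_unpenalized_end_matches_statsmodels(self):
        import statsmodels.api as sm

        X, y, _ = logistic_instance(2, n=400, L=6)
        path = fit_l1_logistic_path(X, y, lambdas=np.geomspace(100.0, 1e-6, 40), tol=1e-9,
                                    devmax=1.0, fdev=0.0)
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert path["coefs"][:, -1] == pytest.approx(mle.params[1:], abs=2e-3)
        assert path["intercepts"][-1] == pytest.approx(mle.params[0], abs=2e-3)

    def test_matches_r_glmnet_on_shared_grid(self, tmp_path):
        """Independent cross-check: coefficients along a shared penalty grid
        agree with R glmnet (the canonical penalized-GLM implementation)."""
        X, y, _ = logistic_instance(3, n=250, L=6)
        n = len(y)
        lambdas = default_lambda_path(X, y, n_lambdas=10, lambda_min_ratio=1e-2)
        path = fit_l1_logistic_path(X, y, lambdas=lambdas, tol=1e-9, devmax=1.0, fdev=0.0)
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        np.savetxt(tmp_path / "y.csv", y)
        np.savetxt(tmp_path / "lam.csv", lambdas / n)  # glmnet scales the loss by 1/n
        script = textwrap.dedent("""
            suppressMessages(library(glmnet))
            X <- as.matrix(read.csv(file.path('%s','X.csv'), header=FALSE))
            y <- scan(file.path('%s','y.csv'), quiet=TRUE)
            lam <- scan(file.path('%s','lam.csv'), quiet=TRUE)
            fit <- glmnet(X, y, family='binomial', lambda=lam, thresh=1e-12, standardize=TRUE)
            write.csv(as.matrix(coef(fit)), file.path('%s','coef.csv'))
        """) % ((tmp_path,) * 4)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        co = pd.read_csv(tmp_path / "coef.csv", index_col=0).to_numpy()
        assert co[1:, :] == pytest.approx(path["coefs"], abs=5e-4)
        assert co[0, :] == pytest.approx(path["intercepts"], abs=5e-4)


class TestCrossValidation:
    def test_null_lambda_deviance_matches_hand_formula(self):
        """With the penalty at or above lambda_max every fold fits the null
        model, so the CV error equals a closed-form average of deviances."""
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=float)
        X = np.random.default_rng(5).normal(size=(10, 2)) * 0.01
        lam = np.array([1e6])
        cv = cross_validate(X, y, lam, folds=5, seed=0)
        expected = []
        from sklearn.model_selection import StratifiedKFold

        for attempt in range(1):
            splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
            for tr, te in splitter.split(X, y):
                p = y[tr].mean()
                expected.append(np.mean([-2 * (yy * np.log(p) + (1 - yy) * np.log(1 - p)) for yy in y[te]]))
        assert cv["cv_mean_error"][0] == pytest.approx(np.mean(expected))

    def test_duplicating_every_site_leaves_curve_stable(self):
        X, y, _ = logistic_instance(6, n=200, L=5)
        lambdas = default_lambda_path(X, y, n_lambdas=20)
        cv1 = cross_validate(X, y, lambdas, folds=5, seed=3)
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        cv2 = cross_validate(X2, y2, lambdas * 2, folds=5, seed=3)
        assert cv2["cv_mean_error"] == pytest.approx(cv1["cv_mean_error"], abs=0.15)

    def test_fixed_seed_reproduces_curve(self):
        X, y, _ = logistic_instance(7, n=150, L=4)
        lambdas = default_lambda_path(X, y, n_lambdas=15)
        a = cross_validate(X, y, lambdas, folds=5, seed=11)
        b = cross_validate(X, y, lambdas, folds=5, seed=11)
        assert np.array_equal(a["cv_mean_error"], b["cv_mean_error"])
        assert np.array_equal(a["fold_errors"], b["fold_errors"])


class TestLambdaSelection:
    def test_flat_curve_selects_most_penalized(self):
        lam = np.array([10.0, 1.0, 0.1])
        assert select_lambda_1se([2.0, 2.0, 2.0], [0.1, 0.1, 0.1], lam) == (10.0, 0)

    def test_zero_se_selects_the_minimum(self):
        lam = np.array([10.0, 1.0, 0.1])
        assert select_lambda_1se([3.0, 2.0, 1.0], [0.0, 0.0, 0.0], lam) == (0.1, 2)

    def test_one_se_band_hand_example(self):
        lam = np.array([8.0, 4.0, 2.0, 1.0])
        # threshold = 2 + 0.5 = 2.5; qualifying errors are at indices 2, 3
        assert select_lambda_1se([5.0, 3.0, 2.0, 2.4], [1.0, 1.0, 0.5, 0.5], lam) == (2.0, 2)

    def test_never_less_penalized_than_cv_minimum(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            lam = np.sort(rng.uniform(0.01, 10, 12))[::-1]
            err = rng.uniform(1, 3, 12)
            se = rng.uniform(0.01, 0.5, 12)
            sel, idx = select_lambda_1se(err, se, lam)
            assert sel >= lam[int(np.argmin(err))]


def test_unpenalized_fit_invariant_to_feature_rescaling():
    """With no penalty the logistic model is reparametrization-invariant:
    affinely rescaling a numeric column leaves fitted probabilities alone.
    (With a penalty this no longer holds, which is why standardization is
    part of the solver contract.)"""
    X, y, _ = logistic_instance(9, n=300, L=5)
    lam = np.array([1e-8])
    p1 = fit_l1_logistic_path(X, y, lambdas=lam, tol=1e-10)
    X2 = X.copy()
    X2[:, 0] = 10.0 * X2[:, 0] - 3.0
    p2 = fit_l1_logistic_path(X2, y, lambdas=lam, tol=1e-10)
    eta1 = X @ p1["coefs"][:, 0] + p1["intercepts"][0]
    eta2 = X2 @ p2["coefs"][:, 0] + p2["intercepts"][0]
    assert 1 / (1 + np.exp(-eta1)) == pytest.approx(1 / (1 + np.exp(-eta2)), abs=1e-5)


def test_recovery_is_accurate_at_cv_minimum_and_biased_at_one_se():
    """On a sparse logistic model over an independent 111-column design the
    path recovers the true support; coefficients are accurate (<= 0.15) at
    the CV-minimum penalty, while the 1-SE penalty adds visible shrinkage."""
    rng = np.random.default_rng(10_000)
    n, L = 20000, 111
    X = rng.normal(size=(n, L))
    support = rng.choice(L, size=8, replace=False)
    beta = np.zeros(L)
    beta[support] = rng.choice([-1.0, 1.0], 8) * rng.uniform(0.5, 1.5, 8)
    y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta - 0.3)))).astype(float)
    path = fit_l1_logistic_path(X, y, tol=1e-6)
    cv = cross_validate(X, y, path["lambdas"], folds=10, seed=0, tol=3e-6)
    _, idx_1se = select_lambda_1se(cv["cv_mean_error"], cv["cv_se"], path["lambdas"])
    idx_min = int(np.argmin(cv["cv_mean_error"]))
    est_min = path["coefs"][:, idx_min]
    est_1se = path["coefs"][:, idx_1se]
    assert set(support.tolist()) <= set(np.flatnonzero(est_1se).tolist())
    assert np.abs(est_min - beta).max() <= 0.15
    # the 1-SE model is sparser and visibly more shrunken than the CV minimizer
    assert np.count_nonzero(est_1se) <= np.count_nonzero(est_min)
    assert np.abs(est_1se[support]).sum() < np.abs(est_min[support]).sum()


class TestStackedCaller:
    def test_combo_only_probabilities_take_at_most_seven_values(self, sim_dataset):
        config = FeatureConfig(include_genomic=False, include_substitution=False,
                               include_interactions=False)
        fit = fit_stacked_caller(sim_dataset, config, seed=0, n_lambdas=30)
        probs = predict_proba(fit, sim_dataset)
        assert len(np.unique(np.round(probs, 12))) <= 7

    def test_refit_matches_path_at_selected_lambda(self, sim_dataset):
        config = FeatureConfig(include_substitution=False, include_interactions=False)
        fit = fit_stacked_caller(sim_dataset, config, seed=1, n_lambdas=30)
        assert np.array_equal(fit.coefficients, fit.coef_path[:, fit.selected_index])
        assert fit.lambda_selected == fit.lambdas[fit.selected_index]
        assert fit.lambda_selected >= fit.lambdas[int(np.argmin(fit.cv_mean_error))]

    def test_same_seed_reproduces_fit(self, sim_dataset):
        config = FeatureConfig(include_genomic=False, include_substitution=False,
                               include_interactions=False)
        a = fit_stacked_caller(sim_dataset, config, seed=5, n_lambdas=20)
        b = fit_stacked_caller(sim_dataset, config, seed=5, n_lambdas=20)
        assert np.array_equal(a.coefficients, b.coefficients)
        assert a.lambda_selected == b.lambda_selected

    def test_zero_coefficient_fit_predicts_half(self, sim_dataset):
        config = FeatureConfig(include_genomic=False, include_substitution=False,
                               include_interactions=False)
        fit = fit_stacked_caller(sim_dataset, config, seed=0, n_lambdas=10)
        fit.coefficients = np.zeros_like(fit.coefficients)
        fit.intercept = 0.0
        assert predict_proba(fit, sim_dataset) == pytest.approx(0.5)

    def test_hand_set_coefficients_give_hand_computed_probability(self, sim_dataset):
        config = FeatureConfig(include_genomic=False, include_substitution=False,
                               include_interactions=False)
        fit = fit_stacked_caller(sim_dataset, config, seed=0, n_lambdas=10)
        fit.coefficients = np.arange(1.0, 7.0) * 0.1
        fit.intercept = -0.5
        dm = build_design_matrix(sim_dataset, config)
        eta = dm.values @ fit.coefficients - 0.5
        assert predict_proba(fit, sim_dataset) == pytest.approx(1 / (1 + np.exp(-eta)))

    def test_monotone_in_positively_weighted_feature(self, sim_dataset):
        config = FeatureConfig(include_substitution=False, include_interactions=False)
        fit = fit_stacked_caller(sim_dataset, config, seed=0, n_lambdas=20)
        fit.coefficients = np.zeros_like(fit.coefficients)
        fit.coefficients[fit.columns.index("vaf_tumor")] = 2.0
        ds = sim_dataset.subset(np.arange(50))
        base = predict_proba(fit, ds)
        ds.features = ds.features.copy()
        ds.features["vaf_tumor"] = np.clip(ds.features["vaf_tumor"] + 0.1, 0, 1)
        assert np.all(predict_proba(fit, ds) >= base)

    def test_caller_name_mismatch_fatal(self, sim_dataset):
        config = FeatureConfig(include_genomic=False, include_substitution=False,
                               include_interactions=False)
        fit = fit_stacked_caller(sim_dataset, config, seed=0, n_lambdas=10)
        other = make_dataset([(1, 0), (0, 1)], labels=[1, 0], caller_names=["X", "Y"])
        with pytest.raises(DataError):
            predict_proba(fit, other)

    def test_json_round_trip(self, sim_dataset, tmp_path):
        config = FeatureConfig(include_genomic=False, include_substitution=False,
                               include_interactions=False)
        fit = fit_stacked_caller(sim_dataset, config, seed=0, n_lambdas=10)
        fit.to_json(tmp_path / "m.json")
        back = StackedFit.from_json(tmp_path / "m.json")
        assert back.columns == fit.columns
        assert np.array_equal(back.coefficients, fit.coefficients)
        assert back.lambda_selected == fit.lambda_selected
        assert predict_proba(back, sim_dataset) == pytest.approx(predict_proba(fit, sim_dataset))
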