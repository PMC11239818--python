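"""Model layer: split arithmetic, elastic-net selection behavior, DeLong
variance against the hand formula, cross-validation, SVM comparators, and
the model grid."""

import numpy as np
import pandas as pd
import pytest

from deltarad.modeling import (
    ModelSpec,
    SplitSpec,
    auc_mann_whitney,
    cross_validate,
    delong_ci,
    delong_variance,
    enumerate_model_grid,
    evaluate_holdout,
    fit_elastic_net,
    fit_svm,
    stratified_split,
)

from oracles import brute_auc


class TestStratifiedSplit:
    def test_clinical_cohort_arithmetic(self):
        """78 pCR / 85 non-pCR at 2:1 -> train 52+57=109, test 26+28=54."""
        labels = np.array([1] * 78 + [0] * 85)
        train, test = stratified_split(labels, SplitSpec(seed=4))
        assert len(train) == 109 and len(test) == 54
        assert labels[train].sum() == 52 and (1 - labels[train]).sum() == 57
        assert labels[test].sum() == 26 and (1 - labels[test]).sum() == 28

    def test_three_per_class(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        train, test = stratified_split(labels, SplitSpec(seed=0))
        assert labels[train].sum() == 2 and len(train) == 4
        assert labels[test].sum() == 1 and len(test) == 2

    def test_partition_exact_and_deterministic(self, rng):
        labels = (rng.uniform(size=50) > 0.4).astype(int)
        tr1, te1 = stratified_split(labels, SplitSpec(seed=9))
        tr2, te2 = stratified_split(labels, SplitSpec(seed=9))
        assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)
        combined = np.sort(np.concatenate([tr1, te1]))
        assert np.array_equal(combined, np.arange(50))

    def test_tiny_stratum_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([0, 1, 1, 1]))


def _planted_table(rng, n=60, n_noise=20, effect=2.0):
    labels = np.zeros(n, dtype=int)
    labels[: n // 2] = 1
    labels = labels[rng.permutation(n)]
    X = pd.DataFrame(rng.normal(size=(n, n_noise + 1)),
                     columns=["signal"] + [f"noise{i}" for i in range(n_noise)])
    X["signal"] += effect * labels
    return X, labels


class TestElasticNet:
    def test_separating_feature_selected(self):
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            X, y = _planted_table(r, n=60, n_noise=30)
            model = fit_elastic_net(X, y, seed=seed)
            if "signal" in model.selected_features:
                hits += 1
        assert hits >= 4

    def test_huge_lasso_penalty_zeroes_coefficients(self, rng):
        X, y = _planted_table(rng)
        model = fit_elastic_net(X, y, l1_ratios=[1.0], n_cs=[1e-4])
        assert model.selected_features == []

    def test_constant_feature_dropped(self, rng):
        X, y = _planted_table(rng, n_noise=5)
        X["flat"] = 3.0
        model = fit_elastic_net(X, y)
        assert "flat" not in model.feature_names

    def test_class_shortage_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 3)))
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            fit_elastic_net(X, y, cv_folds=5)


class TestAUCAndDeLong:
    def test_auc_matches_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 30))
            labels = (rng.uniform(size=n) > 0.5).astype(int)
            if labels.sum() < 2 or (1 - labels).sum() < 2:
                continue
            scores = rng.integers(0, 5, size=n).astype(float)
            assert auc_mann_whitney(labels, scores) == pytest.approx(
                brute_auc(scores, labels), abs=1e-12
            )

    def test_delong_components_hand_example(self):
        """Six scores, no ties: variance from explicit placement values.

        positives {3, 5, 6}, negatives {1, 2, 4}: placements of positives
        over negatives are 2/3, 1, 1 and of negatives over positives are
        1, 1, 2/3; AUC = 8/9 and var = s10^2/3 + s01^2/3 with the sample
        variances of those placement vectors.
        """
        labels = np.array([1, 1, 1, 0, 0, 0])
        scores = np.array([3.0, 5.0, 6.0, 1.0, 2.0, 4.0])
        auc, var = delong_variance(labels, scores)
        v01 = np.array([2 / 3, 1.0, 1.0])
        v10 = np.array([1.0, 1.0, 2 / 3])
        assert auc == pytest.approx(8 / 9)
        assert var == pytest.approx(v01.var(ddof=1) / 3 + v10.var(ddof=1) / 3)

    def test_ci_contains_point_estimate_and_orders(self, rng):
        labels = (rng.uniform(size=40) > 0.5).astype(int)
        scores = rng.normal(size=40) + labels
        auc, (lo, hi), p = delong_ci(labels, scores)
        assert 0.0 <= lo <= auc <= hi <= 1.0
        assert 0.0 <= p <= 1.0


class TestHoldoutEvaluation:
    def _fitted(self, rng):
        X, y = _planted_table(rng, n=60, n_noise=5, effect=4.0)
        model = fit_elastic_net(X, y, seed=0)
        return model, X, y

    def test_perfect_scores(self, rng):
        model, X, y = self._fitted(rng)
        Xt, yt = _planted_table(np.random.default_rng(99), n=30, n_noise=5, effect=6.0)
        result = evaluate_holdout(model, ModelSpec(blocks=(("BL", "DCE"),)),
                                  X, y, Xt, yt)
        assert result.auc_test > 0.9
        assert result.auc_ci[0] <= result.auc_test <= result.auc_ci[1]

    def test_reversed_scores_reported_unoriented(self, rng):
        model, X, y = self._fitted(rng)
        Xt, yt = _planted_table(np.random.default_rng(99), n=30, n_noise=5, effect=6.0)
        result = evaluate_holdout(model, ModelSpec(blocks=(("BL", "DCE"),)),
                                  X, y, Xt, 1 - yt)
        assert result.auc_test < 0.1  # anti-predictive stays below 0.5

    def test_single_class_test_rejected(self, rng):
        model, X, y = self._fitted(rng)
        with pytest.raises(ValueError):
            evaluate_holdout(model, ModelSpec(blocks=(("BL", "DCE"),)),
                             X, y, X, np.ones_like(y))


class TestCrossValidate:
    def test_fold_sizes_and_determinism(self, rng):
        X, y = _planted_table(rng, n=163, n_noise=4, effect=3.0)
        auc1 = cross_validate(X, y, folds=3, seed=1)
        auc2 = cross_validate(X, y, folds=3, seed=1)
        assert auc1 == auc2
        assert auc1 > 0.8

    def test_kfold_sizes_on_163(self):
        from sklearn.model_selection import KFold

        sizes = sorted(len(te) for _, te in KFold(3, shuffle=True,
                                                  random_state=0).split(np.arange(163)))
        assert sizes == [54, 54, 55]


class TestSVM:
    def test_linear_separable_toy(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": np.r_[rng.normal(0, 0.2, 20), rng.normal(3, 0.2, 20)],
                          "b": rng.normal(size=40)})
        y = np.array([0] * 20 + [1] * 20)
        for kernel in ("linear", "rbf"):
            model = fit_svm(X, y, kernel=kernel, seed=0)
            assert auc_mann_whitney(y, model.scores(X)) == 1.0


    def test_elastic_net_not_worse_than_rbf_on_linear_signal(self):
        """With a linear planted signal, the logistic elastic net's test AUC
        is on average no more than 0.05 below the RBF SVM's."""
        gaps = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            X, y = _planted_table(r, n=90, n_noise=15, effect=1.2)
            Xt, yt = _planted_table(np.random.default_rng(seed + 100),
                                    n=45, n_noise=15, effect=1.2)
            enet = fit_elastic_net(X, y, seed=seed)
            svm = fit_svm(X, y, kernel="rbf", seed=seed)
            gaps.append(auc_mann_whitney(yt, enet.scores(Xt))
                        - auc_mann_whitney(yt, svm.scores(Xt)))
        assert np.mean(gaps) >= -0.05


class TestModelGrid:
    def test_default_grid_covers_families(self):
        grid = enumerate_model_grid()
        names = [spec.name for spec in grid]
        assert len(grid) >= 10  # 9 single-family + configured combination
        single = [s for s in grid if len({b for b, _ in s.blocks}) == 1]
        assert len(single) == 9

    def test_combination_spec_has_two_families(self):
        grid = enumerate_model_grid(combinations=(("C4", "AD_C4-BL"),))
        combo = [s for s in grid if len({b for b, _ in s.blocks}) == 2]
        assert len(combo) == 1
        assert {b for b, _ in combo[0].blocks} == {"C4", "AD_C4-BL"}

    def test_serialization_round_trip(self):
        for spec in enumerate_model_grid():
            assert ModelSpec.from_dict(spec.to_dict()) == spec

    def test_column_prefix_selection(self):
        spec = ModelSpec(blocks=(("RD_C2-BL", "DCE"), ("RD_C2-BL", "DWI")))
        table = pd.DataFrame(columns=[
            "DCE_RD_C2-BL_glcm_contrast_d1_a0",
            "DWI_RD_C2-BL_firstorder_mean",
            "DCE_BL_firstorder_mean",
            "DCE_AD_C2-BL_firstorder_mean",
        ])
        assert spec.select_columns(table) == [
            "DCE_RD_C2-BL_glcm_contrast_d1_a0",
            "DWI_RD_C2-BL_firstorder_mean",
        ]
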