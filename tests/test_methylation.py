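"""Methylation score regression: selection, training, prediction."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pytest

from mbcontinuum.core import LabeledMatrix, assign_quantile
from mbcontinuum.methylation import (
    FeatureSelectionConfig,
    TrainConfig,
    moderated_t,
    predict_score,
    select_features,
    train_regressor,
)
from mbcontinuum.synthetic import SimulationConfig, generate_methylation


class TestModeratedT:
    def test_agrees_with_limma_oracle(self):
        """Independent cross-check against limma's eBayes on a tiny fixture."""
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (40, 16))
        X *= rng.gamma(2, 0.5, size=(40, 1))  # heterogeneous row variances
        X[:6, :8] += 1.0
        g = np.array([True] * 8 + [False] * 8)
        t_mine, p_mine = moderated_t(X, g)
        with tempfile.TemporaryDirectory() as d:
            np.savetxt(f"{d}/X.txt", X)
            script = (
                f'X <- as.matrix(read.table("{d}/X.txt"));'
                "suppressMessages(library(limma));"
                "design <- cbind(Intercept=1, Group=c(rep(1,8), rep(0,8)));"
                "fit <- eBayes(lmFit(X, design));"
                f'write.table(cbind(fit$t[,2], fit$p.value[,2]), "{d}/out.txt",'
                "row.names=FALSE, col.names=FALSE)"
            )
            subprocess.run(
                ["Rscript", "-e", script], check=True, capture_output=True
            )
            ref = np.loadtxt(f"{d}/out.txt")
        np.testing.assert_allclose(t_mine, ref[:, 0], atol=1e-8)
        np.testing.assert_allclose(p_mine, ref[:, 1], atol=1e-10)

    def test_detects_planted_shift(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (50, 20))
        X[:10, :10] += 2.0
        g = np.array([True] * 10 + [False] * 10)
        t, p = moderated_t(X, g)
        assert (p[:10] < 0.01).mean() > 0.8
        assert (p[10:] < 0.01).mean() < 0.2

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            moderated_t(np.zeros((3, 4)), np.array([True, False, False, False]))


class TestSelectFeatures:
    def test_block_cpgs_recovered(self, methylation_cohort):
        """Every top list stays within its planted discriminative block."""
        beta, truth, scores, quantiles = methylation_cohort
        cfg = FeatureSelectionConfig(
            n_boot=25, candidate_depth=120, top_per_comparison=30, seed=0
        )
        report = select_features(beta, quantiles, cfg)
        for cat, top in report.top_lists.items():
            planted = {
                c for c, q in truth.block_category.items() if q.value == cat
            }
            informative = planted | {
                c for c, k in truth.cpg_class.items() if k == "switch"
            }
            hits = len(set(top) & informative) / len(top)
            assert hits >= 0.9, f"{cat}: only {hits:.0%} informative"

    def test_final_set_is_union_of_top_lists(self, methylation_cohort):
        beta, truth, scores, quantiles = methylation_cohort
        cfg = FeatureSelectionConfig(n_boot=10, candidate_depth=100,
                                     top_per_comparison=20, seed=1)
        report = select_features(beta, quantiles, cfg)
        union = set().union(*report.top_lists.values())
        assert set(report.final_set) == union
        assert len(report.final_set) <= 20 * 5

    def test_deterministic_and_order_invariant(self, methylation_cohort):
        beta, truth, scores, quantiles = methylation_cohort
        cfg = FeatureSelectionConfig(n_boot=8, candidate_depth=80,
                                     top_per_comparison=15, seed=2)
        r1 = select_features(beta, quantiles, cfg)
        r2 = select_features(beta, quantiles, cfg)
        assert r1.final_set == r2.final_set
        # permuting CpG rows must not change the selected identities
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(beta.row_ids))
        r3 = select_features(beta.subset_rows(perm), quantiles, cfg)
        assert set(r3.final_set) == set(r1.final_set)

    def test_planted_cpgs_strictly_separate_from_null(self, methylation_cohort):
        """Every planted block CpG outranks every null CpG in frequency."""
        beta, truth, scores, quantiles = methylation_cohort
        cfg = FeatureSelectionConfig(
            n_boot=25, candidate_depth=45, top_per_comparison=30, seed=5
        )
        rep = select_features(beta, quantiles, cfg)
        best = rep.frequency.max(axis=1)
        block_min = min(best[c] for c, k in truth.cpg_class.items() if k == "block")
        null_max = max(best[c] for c, k in truth.cpg_class.items() if k == "null")
        assert block_min > null_max

    def test_null_matrix_selection_does_not_generalize(self):
        """Features selected on pure noise carry no signal on fresh data."""
        rng = np.random.default_rng(3)
        beta = LabeledMatrix(
            rng.beta(2, 2, size=(150, 60)),
            [f"cg{i}" for i in range(150)],
            [f"S{j}" for j in range(60)],
            "beta",
        )
        scores = {f"S{j}": float(v) for j, v in enumerate(rng.uniform(0, 1, 60))}
        quantiles = {s: assign_quantile(v) for s, v in scores.items()}
        cfg = FeatureSelectionConfig(n_boot=15, candidate_depth=15,
                                     top_per_comparison=5, seed=3)
        rep = select_features(beta, quantiles, cfg)
        # fresh null cohort with the same CpG ids: the selected CpGs are
        # no better than chance there
        beta2 = LabeledMatrix(
            rng.beta(2, 2, size=(150, 60)), list(beta.row_ids),
            [f"T{j}" for j in range(60)], "beta",
        )
        scores2 = {f"T{j}": float(v) for j, v in enumerate(rng.uniform(0, 1, 60))}
        quantiles2 = {s: assign_quantile(v) for s, v in scores2.items()}
        rep2 = select_features(beta2, quantiles2, cfg)
        overlap = len(set(rep.final_set) & set(rep2.final_set))
        expected_by_chance = len(rep.final_set) * len(rep2.final_set) / 150
        assert overlap <= expected_by_chance + 5

    def test_sparse_category_rejected(self):
        rng = np.random.default_rng(4)
        beta = LabeledMatrix(
            rng.beta(2, 2, size=(20, 12)),
            [f"cg{i}" for i in range(20)],
            [f"S{j}" for j in range(12)],
            "beta",
        )
        quantiles = {f"S{j}": assign_quantile(0.1) for j in range(11)}
        quantiles["S11"] = assign_quantile(0.9)
        with pytest.raises(ValueError, match="<2 samples"):
            select_features(beta, quantiles, FeatureSelectionConfig(n_boot=4))


@pytest.fixture(scope="module")
def trained_regressor():
    """Small but realistic training run shared across prediction tests."""
    rng = np.random.default_rng(9)
    scores = {f"S{i:03d}": float(v) for i, v in enumerate(rng.uniform(0, 1, 80))}
    cfg = SimulationConfig(n_cpgs=400, n_switch_cpgs=80, n_block_cpgs=20, seed=9)
    beta, truth = generate_methylation(cfg, scores)
    quantiles = {s: assign_quantile(v) for s, v in scores.items()}
    selection = select_features(
        beta, quantiles,
        FeatureSelectionConfig(n_boot=12, candidate_depth=60,
                               top_per_comparison=20, seed=9),
    )
    tc = TrainConfig(n_trees=80, rfe_sizes=(10, 25, 50), n_rfe_splits=6,
                     validation_folds=5, seed=9)
    reg = train_regressor(beta, scores, selection, tc)
    return beta, truth, scores, selection, reg


class TestTrainRegressor:
    def test_retained_features_subset_of_selection(self, trained_regressor):
        beta, truth, scores, selection, reg = trained_regressor
        assert set(reg.features) <= set(selection.final_set)
        assert reg.rfe_trace["rmse"].notna().all()

    def test_recovers_planted_scores(self, trained_regressor):
        from scipy.stats import spearmanr

        beta, truth, scores, selection, reg = trained_regressor
        preds = predict_score(reg, beta)
        rho = spearmanr(
            [preds[s] for s in scores], [scores[s] for s in scores]
        ).statistic
        assert rho >= 0.95
        assert reg.validation_rmse < 0.15

    def test_training_error_not_worse_than_validation(self, trained_regressor):
        beta, truth, scores, selection, reg = trained_regressor
        preds = predict_score(reg, beta)
        y = np.array([scores[s] for s in beta.col_ids])
        yhat = np.array([preds[s] for s in beta.col_ids])
        train_rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
        assert train_rmse <= reg.validation_rmse

    def test_permuted_scores_destroy_signal(self, trained_regressor):
        beta, truth, scores, selection, _ = trained_regressor
        rng = np.random.default_rng(0)
        values = np.array(list(scores.values()))
        permuted = dict(zip(scores, rng.permutation(values)))
        tc = TrainConfig(n_trees=60, rfe_sizes=(25,), n_rfe_splits=4,
                         validation_folds=5, seed=1)
        reg = train_regressor(beta, permuted, selection, tc)
        assert reg.validation_rmse >= 0.9 * values.std()

    def test_too_few_samples_rejected(self, trained_regressor):
        beta, truth, scores, selection, _ = trained_regressor
        few = dict(list(scores.items())[:20])
        with pytest.raises(ValueError, match=">= 30"):
            train_regressor(beta, few, selection, TrainConfig())


class TestPredictScore:
    def test_missing_features_reported(self, trained_regressor):
        beta, truth, scores, selection, reg = trained_regressor
        keep = [r for r in beta.row_ids if r not in set(reg.features[:3])]
        with pytest.raises(KeyError, match=reg.features[0]):
            predict_score(reg, beta.subset_rows(keep))

    def test_predictions_clipped_to_unit_interval(self, trained_regressor):
        beta, truth, scores, selection, reg = trained_regressor

        class Overshoot:
            def predict(self, X):
                return np.full(X.shape[0], 1.07)

        from mbcontinuum.methylation import ScoreRegressor

        stub = ScoreRegressor(Overshoot(), reg.features, reg.rfe_trace, 0.0,
                              reg.config)
        preds = predict_score(stub, beta)
        assert all(v == 1.0 for v in preds.values())

    def test_duplicated_sample_gets_identical_prediction(self, trained_regressor):
        beta, truth, scores, selection, reg = trained_regressor
        dup = LabeledMatrix(
            np.hstack([beta.to_dense()[:, :1], beta.to_dense()[:, :1]]),
            list(beta.row_ids), ["a", "b"], "beta",
        )
        preds = predict_score(reg, dup)
        assert preds["a"] == preds["b"]


class TestEvaluateFeatureCounts:
    def test_error_curve_flattens_with_informative_features(self, trained_regressor):
        """Held-out error is non-increasing (up to noise) in feature count."""
        from mbcontinuum.methylation import evaluate_feature_counts
        from scipy.stats import spearmanr

        beta, truth, scores, selection, _ = trained_regressor
        table = evaluate_feature_counts(
            beta, scores, selection, candidate_counts=range(10, 51, 10),
            n_splits=4, seed=0,
        )
        assert len(table) == 5
        rho = spearmanr(table["count"], table["rmse"]).statistic
        assert rho <= 0  # monotone up to noise
        assert table["plateau"].sum() == 1
        assert int(table.loc[table["plateau"], "count"].iloc[0]) <= 50

    def test_counts_beyond_available_features_skipped(self, trained_regressor):
        from mbcontinuum.methylation import evaluate_feature_counts

        beta, truth, scores, selection, _ = trained_regressor
        with pytest.warns(UserWarning, match="exceeds"):
            table = evaluate_feature_counts(
                beta, scores, selection, candidate_counts=[20, 10**4],
                n_splits=2, seed=1,
            )
        assert table["count"].tolist() == [20]
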