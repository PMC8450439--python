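import numpy as np
import pandas as pd
import pytest

from oracles import rank_auc_oracle
from sepsiskit.modeling import (
    ModelSpec,
    balanced_subsample,
    compute_metrics,
    grid_search,
    run_cv_iterations,
    summarize_iterations,
    validate_on_holdout,
)

LOGISTIC = ModelSpec(algorithm="logistic_regression", hyperparameters={})


def toy_problem(n=100, p=8, separation=3.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 0], n // 2)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{j}" for j in range(p)])
    X["f0"] += separation * y
    return X, y


class TestBalancedSubsample:
    def test_cardinality_and_balance(self):
        y = np.array([1] * 10 + [0] * 50)
        idx = balanced_subsample(y, seed=0)
        assert len(idx) == 20
        assert y[idx].sum() == 10

    def test_seeded_determinism(self):
        y = np.array([1] * 5 + [0] * 30)
        np.testing.assert_array_equal(
            balanced_subsample(y, seed=4), balanced_subsample(y, seed=4)
        )

    def test_controls_sampled_without_replacement(self):
        y = np.array([1] * 15 + [0] * 20)
        idx = balanced_subsample(y, seed=1)
        controls = idx[y[idx] == 0]
        assert len(np.unique(controls)) == len(controls)

    def test_control_deficit_warns_and_takes_all(self):
        y = np.array([1] * 10 + [0] * 4)
        with pytest.warns(UserWarning):
            idx = balanced_subsample(y, seed=2)
        assert (y[idx] == 0).sum() == 4


class TestComputeMetrics:
    def test_confusion_arithmetic(self):
        labels = np.array([1] * 100 + [0] * 100)
        scores = np.concatenate(
            [np.full(94, 0.9), np.full(6, 0.1), np.full(90, 0.1), np.full(10, 0.9)]
        )
        m = compute_metrics(scores, labels, threshold=0.5)
        assert m["sensitivity"] == pytest.approx(0.94)
        assert m["specificity"] == pytest.approx(0.90)
        assert m["ppv"] == pytest.approx(94 / 104, abs=5e-5)  # 0.9038

    def test_perfect_scores(self):
        m = compute_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert m["auc"] == 1.0 and m["auprc"] == 1.0
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_random_scores_null_auc(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1], 5000)
        m = compute_metrics(rng.uniform(size=10000), labels)
        assert m["auc"] == pytest.approx(0.5, abs=0.02)
        assert m["auprc"] == pytest.approx(0.5, abs=0.02)

    def test_auc_matches_pair_counting_with_ties(self, rng):
        scores = rng.integers(0, 5, 60) / 4.0  # heavy ties
        labels = rng.integers(0, 2, 60)
        if labels.sum() in (0, len(labels)):
            labels[0] = 1 - labels[0]
        m = compute_metrics(scores, labels)
        assert m["auc"] == pytest.approx(rank_auc_oracle(scores, labels), rel=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(size=80)
        labels = rng.integers(0, 2, 80)
        a = compute_metrics(scores, labels)["auc"]
        b = compute_metrics(np.sqrt(scores), labels)["auc"]
        assert a == pytest.approx(b, rel=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0.2, 0.8], [1, 1])


class TestCvIterations:
    def test_fold_record_count(self):
        X, y = toy_problem()
        _, folds = run_cv_iterations((X, y), LOGISTIC, n_iterations=4, n_folds=5, seed=0)
        assert len(folds) == 20
        assert set(folds["iteration"]) == set(range(4))

    def test_separable_problem_perfect(self):
        X, y = toy_problem(separation=20.0)
        summary, _ = run_cv_iterations((X, y), LOGISTIC, n_iterations=3, seed=0)
        assert summary.table.loc["auc", "mean"] == 1.0
        assert summary.table.loc["sensitivity", "mean"] == 1.0

    def test_permuted_labels_null_auc(self):
        X, y = toy_problem(n=120, separation=3.0, seed=1)
        y_perm = np.random.default_rng(3).permutation(y)
        summary, _ = run_cv_iterations(
            (X, y_perm), LOGISTIC, n_iterations=20, seed=1
        )
        assert 0.45 <= summary.table.loc["auc", "mean"] <= 0.55

    def test_seeded_determinism(self):
        X, y = toy_problem(seed=2)
        a, _ = run_cv_iterations((X, y), LOGISTIC, n_iterations=3, seed=5)
        b, _ = run_cv_iterations((X, y), LOGISTIC, n_iterations=3, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_ci_brackets_mean(self):
        X, y = toy_problem(separation=1.0, seed=4)
        summary, _ = run_cv_iterations((X, y), LOGISTIC, n_iterations=5, seed=4)
        t = summary.table
        assert (t["ci_lower"] <= t["mean"]).all()
        assert (t["mean"] <= t["ci_upper"]).all()

    def test_iteration_means_exchangeable(self):
        rng = np.random.default_rng(6)
        means = pd.DataFrame(rng.uniform(0.6, 0.9, size=(10, 2)), columns=["auc", "ppv"])
        a = summarize_iterations(means, n_folds=5).table
        b = summarize_iterations(
            means.sample(frac=1.0, random_state=1).reset_index(drop=True), n_folds=5
        ).table
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)


class TestGridSearch:
    def test_single_point_grid_returned(self):
        X, y = toy_problem()
        spec = grid_search(
            (X, y), "logistic_regression", {"C": [0.7]}, n_iterations=2, seed=0,
            base_spec=LOGISTIC,
        )
        assert spec.hyperparameters["C"] == 0.7

    def test_seeded_determinism(self):
        X, y = toy_problem(seed=5)
        grid = {"C": [0.1, 1.0]}
        a = grid_search((X, y), "logistic_regression", grid, n_iterations=2, seed=3,
                        base_spec=LOGISTIC)
        b = grid_search((X, y), "logistic_regression", grid, n_iterations=2, seed=3,
                        base_spec=LOGISTIC)
        assert a == b

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(toy_problem(), "logistic_regression", {}, seed=0)

    def test_specificity_floor_excludes_candidates(self):
        from sepsiskit.modeling import pick_stable_candidate

        cands = [
            {"spec": "a", "mean_auc": 0.99, "var_auc": 0.0001, "specificity": 0.3},
            {"spec": "b", "mean_auc": 0.85, "var_auc": 0.0002, "specificity": 0.8},
        ]
        assert pick_stable_candidate(cands, specificity_floor=0.6)["spec"] == "b"

    def test_stability_rule_is_lexicographic(self):
        """Within the variance band of the minimum, the highest mean wins;
        a high-mean but unstable config loses."""
        from sepsiskit.modeling import pick_stable_candidate

        cands = [
            {"spec": "stable_low", "mean_auc": 0.80, "var_auc": 0.001, "specificity": 0.9},
            {"spec": "stable_high", "mean_auc": 0.84, "var_auc": 0.00105, "specificity": 0.9},
            {"spec": "unstable", "mean_auc": 0.95, "var_auc": 0.02, "specificity": 0.9},
        ]
        assert pick_stable_candidate(cands, variance_band=0.1)["spec"] == "stable_high"


class TestHoldout:
    def test_shuffled_copy_scores_like_training(self):
        X, y = toy_problem(n=120, separation=4.0, seed=8)
        perm = np.random.default_rng(8).permutation(len(y))
        summary = validate_on_holdout((X, y), (X.iloc[perm], y[perm]), LOGISTIC, seed=8)
        assert summary.table.loc["auc", "mean"] > 0.95

    def test_label_flip_antisymmetry(self):
        X, y = toy_problem(n=120, separation=2.0, seed=9)
        a = validate_on_holdout((X, y), (X, y), LOGISTIC, seed=9)
        b = validate_on_holdout((X, y), (X, 1 - y), LOGISTIC, seed=9)
        auc_a = a.table.loc["auc", "mean"]
        auc_b = b.table.loc["auc", "mean"]
        assert auc_b == pytest.approx(1.0 - auc_a, abs=1e-9)

    def test_column_mismatch_rejected(self):
        X, y = toy_problem()
        with pytest.raises(ValueError, match="mismatch"):
            validate_on_holdout((X, y), (X[X.columns[:-1]], y), LOGISTIC)


class TestEffectSizeMonotonicity:
    def test_auc_nondecreasing_in_effect_size(self):
        """Planted-effect recovery grows with effect size: mean AUC over ten
        seeded replicates is non-decreasing over effect sizes {0, 1, 2}."""
        from sepsiskit.features import build_feature_matrix
        from sepsiskit.labeling import label_cohort
        from sepsiskit.synthetic import SimulationConfig, simulate_cohort

        mean_auc = []
        for effect in (0.0, 1.0, 2.0):
            aucs = []
            for seed in range(10):
                c = simulate_cohort(
                    SimulationConfig(
                        n_cases=8, n_controls=8, duration_h=30,
                        effect_size=effect, seed=seed,
                    )
                )
                res = label_cohort(c.vitals, c.events, c.labs, seed=seed)
                fm = build_feature_matrix(res.labels, c.vitals)
                s, _ = run_cv_iterations(
                    (fm.X, fm.y.to_numpy(int)), LOGISTIC,
                    n_iterations=2, n_folds=4, seed=seed,
                )
                aucs.append(s.table.loc["auc", "mean"])
            mean_auc.append(np.mean(aucs))
        assert mean_auc[0] <= mean_auc[1] + 0.05
        assert mean_auc[1] <= mean_auc[2] + 0.05
        assert mean_auc[2] > 0.7
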