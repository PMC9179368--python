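"""Feature ranking, CV feature-count selection, linear SVM train/predict."""

import numpy as np
import pytest

from mrsidh.classification import (
    ClassifierConfig,
    DegenerateClassError,
    GridMismatchError,
    fit_linear_svm,
    hinge_objective,
    predict,
    rank_features,
    read_model,
    select_feature_count,
    train,
    write_model,
)
from oracles import svm_primal_oracle


def labels_from(yb):
    return np.where(np.asarray(yb) == 1, "mut", "wt")


def two_signal_dataset(seed, n=200, p=100, delta=8.0):
    """Gaussian noise matrix with exactly two informative columns.

    The mutant group splits into two subgroups, each strongly elevated in
    only one of the two signal columns, so either column alone separates
    only half the mutants (~75% achievable accuracy) while the two
    together separate (nearly) perfectly; every other column is pure
    noise.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    yb = np.array([1] * (n // 2) + [0] * (n - n // 2))
    col_a, col_b = (10, 40) if p > 40 else (1, 5)
    mut_rows = np.nonzero(yb == 1)[0]
    half = len(mut_rows) // 2
    X[mut_rows[:half], col_a] += delta
    X[mut_rows[half:], col_b] += delta
    return X, labels_from(yb)


class TestRankFeatures:
    def test_signal_column_ranked_first(self, rng):
        n, p = 50, 30
        yb = rng.integers(0, 2, size=n)
        while yb.sum() < 2 or yb.sum() > n - 2:
            yb = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, p))
        X[:, 7] = yb + 0.01 * rng.normal(size=n)
        assert rank_features(X, labels_from(yb))[0] == 7

    def test_tied_columns_keep_lower_index_first(self, rng):
        yb = np.array([1, 1, 1, 0, 0, 0])
        col = np.array([2.0, 2.5, 1.8, 0.1, 0.4, -0.2])
        X = np.column_stack([col, col, rng.normal(size=6)])
        order = rank_features(X, labels_from(yb))
        assert list(order[:2]) == [0, 1]

    def test_zero_variance_column_ranked_last(self, rng):
        yb = np.array([1, 1, 1, 0, 0, 0])
        X = rng.normal(size=(6, 4))
        X[:, 2] = 5.0  # constant in both groups -> statistic 0
        assert rank_features(X, labels_from(yb))[-1] == 2

    def test_small_class_is_an_error(self):
        X = np.zeros((3, 4))
        with pytest.raises(DegenerateClassError):
            rank_features(X, ["mut", "wt", "wt"])


class TestSelectFeatureCount:
    def test_single_candidate_is_returned(self):
        X, y = two_signal_dataset(0)
        config = ClassifierConfig(candidate_feature_counts=(3,), cv_seed=0)
        assert select_feature_count(X, y, config).k_star == 3

    def test_deterministic_under_fixed_seed(self):
        X, y = two_signal_dataset(1)
        config = ClassifierConfig(cv_seed=5)
        a = select_feature_count(X, y, config)
        b = select_feature_count(X, y, config)
        assert a.k_star == b.k_star
        assert a.fold_accuracy == b.fold_accuracy

    def test_recovers_two_informative_features(self):
        X, y = two_signal_dataset(2)
        config = ClassifierConfig(cv_seed=0)
        assert select_feature_count(X, y, config).k_star == 2

    def test_oversized_candidates_skipped_with_warning(self):
        X, y = two_signal_dataset(3, p=8)
        config = ClassifierConfig(candidate_feature_counts=(2, 50), cv_seed=0)
        with pytest.warns(UserWarning, match="skipped"):
            result = select_feature_count(X, y, config)
        assert result.k_star == 2
        with pytest.raises(ValueError, match="candidate"):
            select_feature_count(
                X, y, ClassifierConfig(candidate_feature_counts=(50,), cv_seed=0)
            )


class TestTrainAndPredict:
    def test_separable_toy_recovers_max_margin_solution(self):
        # x = -1 (wt), x = +1 (mut): the max-margin boundary is at 0 with
        # margin 2, i.e. w = 1, b = 0 on the (already unit-variance) input
        X = np.array([[-1.0], [1.0]])
        y = ["wt", "mut"]
        model = train(X, y, ClassifierConfig(candidate_feature_counts=(1,)), k=1)
        assert model.weights[0] == pytest.approx(1.0, abs=1e-6)
        assert model.bias == pytest.approx(0.0, abs=1e-6)
        labels, scores = predict(model, X)
        assert list(labels) == ["wt", "mut"]
        assert scores == pytest.approx([-1.0, 1.0], abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objective_matches_bruteforce_qp(self, seed):
        rng = np.random.default_rng(seed)
        n, d = 16, 2
        yb = np.array([1] * (n // 2) + [0] * (n // 2))
        X = rng.normal(size=(n, d)) + 0.8 * yb[:, None]  # overlapping classes
        w, b = fit_linear_svm(X, yb, cost=1.0)
        ours = hinge_objective(w, b, X, yb, cost=1.0)
        oracle = svm_primal_oracle(X, yb, cost=1.0, seed=seed)
        assert ours == pytest.approx(oracle, abs=1e-4)

    def test_objective_below_random_probes(self, rng):
        n = 12
        yb = np.array([1] * 6 + [0] * 6)
        X = rng.normal(size=(n, 2))
        w, b = fit_linear_svm(X, yb, cost=1.0)
        ours = hinge_objective(w, b, X, yb, cost=1.0)
        for _ in range(200):
            wp = rng.normal(size=2) * 3
            bp = rng.normal() * 3
            assert ours <= hinge_objective(wp, bp, X, yb, cost=1.0) + 1e-9

    def test_duplicating_points_keeps_separable_boundary(self):
        X = np.array([[-1.0], [1.0]])
        yb = np.array([0, 1])
        w1, b1 = fit_linear_svm(X, yb, cost=1.0)
        w2, b2 = fit_linear_svm(np.vstack([X, X]), np.tile(yb, 2), cost=1.0)
        assert w2 == pytest.approx(w1, abs=1e-6)
        assert b2 == pytest.approx(b1, abs=1e-6)

    def test_score_zero_predicts_wildtype(self):
        X = np.array([[-1.0], [1.0]])
        model = train(X, ["wt", "mut"], k=1)
        labels, scores = predict(model, np.array([[0.0]]))
        assert scores[0] == pytest.approx(0.0, abs=1e-9)
        assert labels[0] == "wt"

    def test_row_permutation_permutes_outputs(self):
        X, y = two_signal_dataset(4)
        model = train(X, y, k=2)
        perm = np.random.default_rng(0).permutation(len(y))
        labels, scores = predict(model, X)
        labels_p, scores_p = predict(model, X[perm])
        assert np.array_equal(labels_p, labels[perm])
        assert scores_p == pytest.approx(scores[perm])

    def test_grid_mismatch_mentions_harmonization(self):
        X, y = two_signal_dataset(5)
        model = train(X, y, k=2)
        with pytest.raises(GridMismatchError, match="harmonize"):
            predict(model, X[:, :50])

    def test_single_class_training_is_an_error(self):
        X = np.zeros((4, 3))
        with pytest.raises(DegenerateClassError):
            train(X, ["mut"] * 4, k=1)

    def test_model_json_roundtrip(self, tmp_path):
        X, y = two_signal_dataset(6)
        model = train(X, y, k=2)
        path = tmp_path / "model.json"
        write_model(model, path)
        back = read_model(path)
        assert np.array_equal(back.feature_indices, model.feature_indices)
        assert back.weights == pytest.approx(model.weights)
        assert back.bias == pytest.approx(model.bias)
        _, s1 = predict(model, X)
        _, s2 = predict(back, X)
        assert s2 == pytest.approx(s1)


class TestPrevalenceRobustness:
    def test_boundary_direction_survives_prevalence_flip(self):
        # identical class-conditional generators, 2:1 vs 1:2 class mix:
        # the fitted direction must still score mutants above wild types
        from mrsidh.harmonization import harmonize_cohort
        from mrsidh.synthetic_data import config_for_regime, simulate_cohort

        hits = 0
        for seed in range(10):
            cfg = config_for_regime("3T-original", seed=seed)
            ok = True
            for n_mut, n_wt in ((22, 11), (11, 22)):
                cohort = simulate_cohort(cfg, n_mut, n_wt)
                X, _, labels, _ = harmonize_cohort(cohort)
                model = train(X, labels, ClassifierConfig(cv_seed=seed), k=2)
                _, scores = predict(model, X)
                labels = np.asarray(labels)
                if scores[labels == "mut"].mean() <= scores[labels == "wt"].mean():
                    ok = False
            hits += ok
        assert hits >= 9
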