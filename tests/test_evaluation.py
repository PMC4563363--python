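import numpy as np
import pytest

from eigendti import (
    InteractionMatrix,
    PredictorSpec,
    ScoreMatrix,
    auc,
    aupr,
    bootstrap_compare,
    combined_q,
    grid_search_alpha,
    make_folds,
    mask_fold,
    nested_cv,
    predict,
    rank_new_interactions,
)
from eigendti.evaluation import MetricSet, metric_set

from conftest import make_instance


def pair_count_auc(scores, labels):
    """Brute-force Mann-Whitney oracle: wins + half-ties over P*N pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def step_sum_aupr(scores, labels):
    """Average precision oracle: mean precision at each positive's rank."""
    order = np.argsort(-scores, kind="stable")
    lab = labels[order]
    precisions = []
    tp = 0
    for k, l in enumerate(lab, start=1):
        if l == 1:
            tp += 1
            precisions.append(tp / k)
    return float(np.mean(precisions))


class TestMetrics:
    def test_perfect_separation(self):
        assert auc(np.array([0.9, 0.1]), np.array([1, 0])) == 1.0
        assert aupr(np.array([0.9, 0.8, 0.1]), np.array([1, 1, 0])) == 1.0

    def test_constant_scores_give_half_auc(self):
        assert auc(np.ones(6), np.array([1, 0, 1, 0, 0, 1])) == 0.5

    def test_auc_equals_pair_count_oracle(self, rng):
        scores = rng.standard_normal(50)
        labels = (rng.random(50) < 0.3).astype(int)
        labels[:2] = [0, 1]
        assert auc(scores, labels) == pytest.approx(
            pair_count_auc(scores, labels), abs=1e-12
        )

    def test_single_positive_ranked_last(self):
        scores = np.array([0.9, 0.8, 0.7, 0.1])
        labels = np.array([0, 0, 0, 1])
        assert aupr(scores, labels) == pytest.approx(0.25)

    def test_aupr_equals_step_sum_oracle(self, rng):
        for _ in range(5):
            scores = rng.standard_normal(30)
            labels = (rng.random(30) < 0.25).astype(int)
            labels[0] = 1
            assert aupr(scores, labels) == pytest.approx(
                step_sum_aupr(scores, labels), abs=1e-12
            )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.standard_normal(40)
        labels = (rng.random(40) < 0.3).astype(int)
        labels[:2] = [0, 1]
        warped = np.exp(3 * scores)
        assert auc(scores, labels) == auc(warped, labels)
        assert aupr(scores, labels) == aupr(warped, labels)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([1.0, 2.0]), np.array([1, 1]))
        with pytest.raises(ValueError):
            aupr(np.array([1.0, 2.0]), np.array([0, 0]))

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(123)
        vals = [
            auc(rng.standard_normal(2000), (rng.random(2000) < 0.5).astype(int))
            for _ in range(100)
        ]
        assert abs(np.mean(vals) - 0.5) < 0.02


class TestCombinedQ:
    def test_hand_value(self):
        assert combined_q(0.9, 0.5, (0.5, 0.5)) == pytest.approx(0.7)

    def test_degenerate_weight_reduces_to_aupr(self):
        assert combined_q(0.9, 0.5, (0.0, 1.0)) == 0.5

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            combined_q(0.5, 0.5, (0.7, 0.3))  # w2 < w1
        with pytest.raises(ValueError):
            combined_q(0.5, 0.5, (0.4, 0.5))  # do not sum to 1

    def test_monotone_in_each_argument(self):
        grid = np.linspace(0, 1, 6)
        for w in ((0.5, 0.5), (0.3, 0.7)):
            for fixed in grid:
                qs_auc = [combined_q(a, fixed, w) for a in grid]
                qs_aupr = [combined_q(fixed, a, w) for a in grid]
                assert (np.diff(qs_auc) >= 0).all()
                assert (np.diff(qs_aupr) >= 0).all()

    def test_metric_set_q_exact(self):
        m = MetricSet(auc=0.8, aupr=0.6, w1=0.4, w2=0.6)
        assert m.q == 0.4 * 0.8 + 0.6 * 0.6


class TestFolds:
    def _toy_Y(self, rng, n_d=6, n_t=6, density=0.3):
        vals = (rng.random((n_d, n_t)) < density).astype(float)
        vals[0, 0] = 1.0
        vals[1, 1] = 0.0
        return InteractionMatrix(
            tuple(f"d{i}" for i in range(n_d)),
            tuple(f"t{i}" for i in range(n_t)), vals,
        )

    def test_balanced_partition_sizes(self, rng):
        Y = self._toy_Y(rng)
        n_known = int(Y.values.sum())
        folds = make_folds(Y, 3, seed=1)
        sizes = np.bincount(folds.known_fold, minlength=3)
        assert sizes.sum() == n_known
        assert sizes.max() - sizes.min() <= 1
        u_sizes = np.bincount(folds.unknown_fold, minlength=3)
        assert u_sizes.max() - u_sizes.min() <= 1

    def test_deterministic_given_seed(self, rng):
        Y = self._toy_Y(rng)
        f1 = make_folds(Y, 4, seed=7)
        f2 = make_folds(Y, 4, seed=7)
        np.testing.assert_array_equal(f1.known_fold, f2.known_fold)
        np.testing.assert_array_equal(f1.unknown_fold, f2.unknown_fold)
        f3 = make_folds(Y, 4, seed=8)
        assert not (
            np.array_equal(f1.known_fold, f3.known_fold)
            and np.array_equal(f1.unknown_fold, f3.unknown_fold)
        )

    def test_folds_partition_all_pairs(self, rng):
        Y = self._toy_Y(rng)
        folds = make_folds(Y, 3, seed=2)
        seen = set()
        for fold_id in range(3):
            _, test_index = mask_fold(Y, folds, fold_id)
            pairs = {tuple(p) for p in test_index.pairs}
            assert not (pairs & seen)
            seen |= pairs
        assert len(seen) == Y.values.size

    def test_masking_conserves_interactions(self, rng):
        Y = self._toy_Y(rng)
        folds = make_folds(Y, 3, seed=3)
        for fold_id in range(3):
            Y_train, test_index = mask_fold(Y, folds, fold_id)
            held_known = int(test_index.labels.sum())
            assert Y.values.sum() == Y_train.values.sum() + held_known
            # original labels recoverable from the test index
            np.testing.assert_array_equal(
                Y.values[test_index.pairs[:, 0], test_index.pairs[:, 1]],
                test_index.labels,
            )

    def test_too_few_pairs_rejected(self):
        Y = InteractionMatrix(("d1", "d2"), ("t1",), np.array([[1.0], [0.0]]))
        with pytest.raises(ValueError, match="need >="):
            make_folds(Y, 2, seed=0)


class TestGridSearch:
    def test_singleton_grid(self, rng):
        K_d, K_t, Y = make_instance(8, 8, rng, density=0.3)
        spec = PredictorSpec("rls", "kp")
        best, table = grid_search_alpha(spec, K_d, K_t, Y, n_inner=3,
                                        alpha_grid=(1.0,), weights=(0.5, 0.5),
                                        seed=0)
        assert best == 1.0 and set(table) == {1.0}

    def test_argmax_dominates_alpha_one(self, rng):
        K_d, K_t, Y = make_instance(8, 8, rng, density=0.3)
        spec = PredictorSpec("rls", "kp")
        grid = (0.5, 1.0, 1.5)
        best, table = grid_search_alpha(spec, K_d, K_t, Y, n_inner=3,
                                        alpha_grid=grid, weights=(0.5, 0.5),
                                        seed=0)
        assert table[best] >= table[1.0]

    def test_tie_breaks_toward_alpha_one(self, rng, monkeypatch):
        # identical kernels make some alphas tie exactly; closest-to-1 wins
        K_d, K_t, Y = make_instance(8, 8, rng, density=0.3)
        import eigendti.evaluation as ev
        monkeypatch.setattr(
            ev, "predict",
            lambda spec, *a, **k: predict(spec.with_alpha(1.0), *a, **k),
        )
        best, table = grid_search_alpha(PredictorSpec("rls", "kp"), K_d, K_t, Y,
                                        n_inner=3, alpha_grid=(0.5, 1.0, 1.5),
                                        weights=(0.5, 0.5), seed=0)
        assert best == 1.0
        assert len({round(v, 12) for v in table.values()}) == 1


class TestNestedCV:
    def test_degenerate_grid_equals_plain_cv(self, rng):
        K_d, K_t, Y = make_instance(10, 10, rng, density=0.25)
        spec = PredictorSpec("rls", "kp")
        report = nested_cv(spec, K_d, K_t, Y, n_outer=3, n_inner=3,
                           alpha_grid=(1.0,), seed=5)
        # hand-rolled plain CV of the original algorithm, same folds
        folds = make_folds(Y, 3, seed=5)
        for fold_id in range(3):
            Y_train, test_index = mask_fold(Y, folds, fold_id)
            F = predict(spec.with_alpha(1.0), K_d, K_t, Y_train)
            s = test_index.scores_at(F)
            m = metric_set(s, test_index.labels)
            assert report.folds[fold_id].test.auc == m.auc
            assert report.folds[fold_id].test.aupr == m.aupr
            assert report.folds[fold_id].chosen_alpha == 1.0

    def test_same_seed_bit_identical(self, rng):
        K_d, K_t, Y = make_instance(9, 9, rng, density=0.3)
        spec = PredictorSpec("slp", "avg")
        r1 = nested_cv(spec, K_d, K_t, Y, n_outer=3, n_inner=3,
                       alpha_grid=(0.5, 1.0), seed=9, baseline_alpha=1.0,
                       n_boot=50)
        r2 = nested_cv(spec, K_d, K_t, Y, n_outer=3, n_inner=3,
                       alpha_grid=(0.5, 1.0), seed=9, baseline_alpha=1.0,
                       n_boot=50)
        assert r1 == r2

    def test_aggregate_is_mean_of_folds(self, rng):
        K_d, K_t, Y = make_instance(9, 9, rng, density=0.3)
        report = nested_cv(PredictorSpec("rls", "ks"), K_d, K_t, Y, n_outer=3,
                           n_inner=3, alpha_grid=(1.0,), seed=2)
        assert report.mean("auc") == pytest.approx(
            np.mean([f.test.auc for f in report.folds])
        )
        assert all(f.chosen_alpha in (1.0,) for f in report.folds)


class TestBootstrap:
    def test_self_comparison_gives_p_one(self, rng):
        scores = rng.standard_normal(30)
        labels = (rng.random(30) < 0.4).astype(int)
        labels[:2] = [0, 1]
        p = bootstrap_compare(scores, scores, labels, n_boot=100, seed=0)
        assert p == 1.0

    def test_extreme_separation_minimum_p(self):
        labels = np.array([1] * 10 + [0] * 10)
        scores_a = np.array([1.0] * 10 + [0.0] * 10)  # perfect
        scores_b = 1.0 - scores_a  # anti-perfect
        p = bootstrap_compare(scores_a, scores_b, labels, n_boot=200, seed=1)
        assert p == pytest.approx(1 / 201)

    def test_rank_invariance_under_common_monotone_map(self, rng):
        scores_a = rng.standard_normal(40)
        scores_b = rng.standard_normal(40)
        labels = (rng.random(40) < 0.4).astype(int)
        labels[:2] = [0, 1]
        p1 = bootstrap_compare(scores_a, scores_b, labels, n_boot=100, seed=3)
        p2 = bootstrap_compare(np.exp(scores_a), np.exp(scores_b), labels,
                               n_boot=100, seed=3)
        assert p1 == p2

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="share"):
            bootstrap_compare(np.ones(3), np.ones(4), np.array([0, 1, 0]))


class TestRankNewInteractions:
    def test_all_known_yields_empty(self):
        Y = InteractionMatrix(("d1",), ("t1",), np.ones((1, 1)))
        F = ScoreMatrix(("d1",), ("t1",), np.array([[0.4]]))
        assert rank_new_interactions(F, Y) == []

    def test_hand_sorted_example(self):
        Y = InteractionMatrix(("d1", "d2"), ("t1", "t2"),
                              np.array([[1.0, 0.0], [0.0, 0.0]]))
        F = ScoreMatrix(Y.drug_ids, Y.target_ids,
                        np.array([[9.0, 3.0], [2.0, 1.0]]))
        rows = rank_new_interactions(F, Y, top_n=5)
        assert rows == [
            (1, "d1", "t2", 3.0),
            (2, "d2", "t1", 2.0),
            (3, "d2", "t2", 1.0),
        ]

    def test_top_one_is_argmax_over_unknown(self, rng):
        Y_vals = (rng.random((5, 5)) < 0.3).astype(float)
        Y_vals[0, 0] = 0.0
        Y = InteractionMatrix(tuple(f"d{i}" for i in range(5)),
                              tuple(f"t{i}" for i in range(5)), Y_vals)
        F_vals = rng.random((5, 5))
        F = ScoreMatrix(Y.drug_ids, Y.target_ids, F_vals)
        top = rank_new_interactions(F, Y, top_n=1)[0]
        masked = np.where(Y.values == 0, F_vals, -np.inf)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        assert top[1:] == (Y.drug_ids[i], Y.target_ids[j], F_vals[i, j])

    def test_ties_broken_lexically(self):
        Y = InteractionMatrix(("a", "b"), ("t",), np.zeros((2, 1)))
        F = ScoreMatrix(Y.drug_ids, Y.target_ids, np.array([[0.5], [0.5]]))
        rows = rank_new_interactions(F, Y, top_n=2)
        assert [r[1] for r in rows] == ["a", "b"]
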