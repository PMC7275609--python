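"""Predictor grouping, set enumeration and repeated-split AUC evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from splicemark.classifier import (
    ClassifierError,
    correlation_groups,
    enumerate_predictor_sets,
    evaluate_all_sets,
    evaluate_predictor_set,
    fit_logistic,
    roc_auc,
    select_best_model,
)
from splicemark.simulate import simulate_usage_matrix


def brute_force_auc(scores, labels):
    """Oracle: P(score_pos > score_neg) + 1/2 P(tie) by pair counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p, n in itertools.product(pos, neg):
        if p > n:
            wins += 1
        elif p == n:
            ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestCorrelationGroups:
    def test_planted_blocks_recovered(self):
        matrix, _, truth = simulate_usage_matrix(
            n_tumor=150, n_normal=150, within_block_loading=0.9,
            class_shift_sd=0.0, seed=5,
        )
        grouping = correlation_groups(matrix, k=3)
        # the recovered partition equals the planted block partition
        planted = {
            b: set(truth.index[truth["block"] == b]) for b in (1, 2, 3)
        }
        recovered = {}
        for predictor, g in grouping.items():
            recovered.setdefault(g, set()).add(predictor)
        assert set(map(frozenset, planted.values())) == set(
            map(frozenset, recovered.values())
        )

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(
            rng.normal(size=(60, 4)), columns=list("abcd")
        )
        grouping = correlation_groups(matrix, k=4)
        assert sorted(grouping.values()) == [1, 2, 3, 4]

    def test_identical_predictors_co_clustered(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=80)
        matrix = pd.DataFrame(
            {
                "a": base,
                "b": base,
                "c": rng.normal(size=80),
                "d": rng.normal(size=80) + 5,
            }
        )
        grouping = correlation_groups(matrix, k=3)
        assert grouping["a"] == grouping["b"]

    def test_k_larger_than_predictors_rejected(self):
        matrix = pd.DataFrame(np.random.default_rng(2).normal(size=(10, 2)))
        with pytest.raises(ClassifierError):
            correlation_groups(matrix, k=3)


class TestEnumeration:
    @staticmethod
    def _grouping(sizes):
        grouping = {}
        for g, size in enumerate(sizes, 1):
            for i in range(size):
                grouping[f"g{g}p{i}"] = g
        return grouping

    @pytest.mark.parametrize(
        "sizes,expected",
        [
            ((3, 2, 3), 41),   # 8 + 3*5 + 3*2*3
            ((1, 1, 1), 6),    # 3 + 2 + 1
            ((2, 1, 1), 10),   # 4 + 4 + 2
        ],
    )
    def test_counts_match_hand_enumeration(self, sizes, expected):
        sets = enumerate_predictor_sets(self._grouping(sizes))
        assert len(sets) == expected
        assert len(set(sets)) == len(sets)  # distinct, unordered

    def test_closed_form_over_partitions_of_eight(self):
        # n + g1*(g2+g3) + g1*g2*g3 for every composition of 8 into 3 parts
        for g1 in range(1, 7):
            for g2 in range(1, 8 - g1):
                g3 = 8 - g1 - g2
                sets = enumerate_predictor_sets(self._grouping((g1, g2, g3)))
                assert len(sets) == 8 + g1 * (g2 + g3) + g1 * g2 * g3

    def test_pair_constraint_respected(self):
        sets = enumerate_predictor_sets(self._grouping((3, 2, 3)))
        for members in sets:
            if len(members) == 2:
                groups = sorted(int(m[1]) for m in members)
                assert groups[0] == 1 and groups[1] in (2, 3)
            if len(members) == 3:
                assert sorted(int(m[1]) for m in members) == [1, 2, 3]

    def test_empty_group_rejected(self):
        with pytest.raises(ClassifierError):
            enumerate_predictor_sets({"a": 1, "b": 2})


class TestLogistic:
    def test_separable_data_ranks_perfectly(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_logistic(X, y)
        scores = model.predict_proba(X)[:, 1]
        assert roc_auc(scores, y) == 1.0

    def test_null_predictor_coefficient_not_significant(self):
        # pure-noise predictor: |z| < 3 in nearly all replicates
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 1))
            y = rng.integers(0, 2, size=200)
            model = fit_logistic(X, y)
            beta = model.coef_[0][0]
            # Wald se for a single standardized predictor ~ sqrt(4/n)
            p = model.predict_proba(X)[:, 1]
            w = p * (1 - p)
            se = 1.0 / np.sqrt((X[:, 0] ** 2 * w).sum())
            if abs(beta / se) < 3:
                hits += 1
        assert hits >= 38  # >= 95% of seeds

    def test_constant_predictor_predicts_prevalence(self):
        X = np.ones((10, 1))
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        model = fit_logistic(X, y)
        prob = model.predict_proba(X)[0, 1]
        assert prob == pytest.approx(0.3, abs=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ClassifierError):
            fit_logistic(np.ones((4, 1)), np.zeros(4))


class TestRocAuc:
    def test_perfect_and_uninformative(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_tie_counts_half(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.8]
        labels = [1, 1, 0, 0, 0]
        assert roc_auc(scores, labels) == pytest.approx(5.5 / 6)

    def test_single_class_rejected(self):
        with pytest.raises(ClassifierError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.uniform(size=n), 2)  # induce ties
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels)
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(10)
        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, size=40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        base = roc_auc(scores, labels)
        for transform in (np.exp, lambda s: s**3, lambda s: 5 * s - 2):
            assert roc_auc(transform(scores), labels) == pytest.approx(base)


class TestEvaluation:
    def test_separable_predictor_gives_unit_auc(self):
        rng = np.random.default_rng(3)
        n = 100
        labels = pd.Series([1] * 50 + [0] * 50)
        matrix = pd.DataFrame(
            {"sep": np.where(labels == 1, 10.0, 0.0) + rng.uniform(size=n)}
        )
        ev = evaluate_predictor_set(("sep",), matrix, labels, seed=1)
        assert ev.mean_auc == 1.0
        assert len(ev.aucs) == 5

    def test_shuffled_labels_give_chance_auc(self):
        matrix, labels, _ = simulate_usage_matrix(
            n_tumor=200, n_normal=200, class_shift_sd=0.0, seed=6
        )
        ev = evaluate_predictor_set(
            ("junc_b1_1",), matrix, labels, seed=2
        )
        assert 0.4 <= ev.mean_auc <= 0.6

    def test_same_seed_reproduces_aucs(self):
        matrix, labels, _ = simulate_usage_matrix(
            n_tumor=60, n_normal=60, seed=7
        )
        ev1 = evaluate_predictor_set(("junc_b1_1",), matrix, labels, seed=11)
        ev2 = evaluate_predictor_set(("junc_b1_1",), matrix, labels, seed=11)
        assert ev1.aucs == ev2.aucs

    def test_empty_set_rejected(self):
        matrix, labels, _ = simulate_usage_matrix(
            n_tumor=30, n_normal=30, seed=8
        )
        with pytest.raises(ClassifierError):
            evaluate_predictor_set((), matrix, labels)


class TestSelectBestModel:
    @staticmethod
    def _eval(members, mean_auc):
        from splicemark.classifier import PredictorSetEvaluation

        return PredictorSetEvaluation(
            members=tuple(members),
            aucs=(mean_auc,) * 5,
            mean_auc=mean_auc,
            sd_auc=0.0,
            best_intercept=0.0,
            best_coefficients=(1.0,) * len(members),
        )

    def test_highest_mean_auc_wins(self):
        evals = [
            self._eval(("a",), 0.9),
            self._eval(("b",), 0.99),
            self._eval(("c",), 0.95),
        ]
        assert select_best_model(evals).members == ("b",)

    def test_tie_prefers_fewer_predictors(self):
        evals = [
            self._eval(("a", "b", "c"), 0.99),
            self._eval(("d", "e"), 0.99),
        ]
        assert select_best_model(evals).members == ("d", "e")

    def test_single_evaluation_returned(self):
        only = self._eval(("a",), 0.7)
        assert select_best_model([only]) is only

    def test_empty_rejected(self):
        with pytest.raises(ClassifierError):
            select_best_model([])
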