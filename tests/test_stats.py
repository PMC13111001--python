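"""Confusion metrics, fold aggregation, and the Friedman/Nemenyi harness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hmcnet.errors import InputError
from hmcnet.stats import (
    CDDiagram,
    ConfusionMatrix,
    Q_ALPHA_NEMENYI_K4,
    Q_ALPHA_REPORTED,
    aggregate_folds,
    auc_macro,
    average_ranks,
    cd_diagram,
    classification_metrics,
    confusion,
    critical_difference,
    friedman,
    nemenyi,
    rank_summary,
)


class TestConfusion:
    def test_hand_counted_example(self):
        cm = confusion([0, 0, 1, 2], [0, 1, 1, 2], 3)
        assert cm.counts[0, 1] == 1
        assert np.trace(cm.counts) == 3
        assert cm.total == 4

    def test_perfect_predictions_are_diagonal(self):
        y = [0, 1, 1, 2, 2, 2]
        cm = confusion(y, y, 3)
        assert np.all(cm.counts == np.diag([1, 2, 3]))

    def test_fold_matrices_sum_to_aggregate(self):
        rng = np.random.default_rng(0)
        y1, p1 = rng.integers(0, 3, 50), rng.integers(0, 3, 50)
        y2, p2 = rng.integers(0, 3, 60), rng.integers(0, 3, 60)
        total = confusion(np.r_[y1, y2], np.r_[p1, p2], 3)
        summed = confusion(y1, p1, 3) + confusion(y2, p2, 3)
        assert np.all(total.counts == summed.counts)

    def test_length_mismatch_raises(self):
        with pytest.raises(InputError):
            confusion([0, 1], [0], 3)


class TestClassificationMetrics:
    def test_binary_arithmetic_example(self):
        # TP=2, FP=1, FN=1, TN=6 for class 1 of a 2-class matrix
        cm = ConfusionMatrix(np.array([[6, 1], [1, 2]]))
        res = classification_metrics(cm)
        c1 = res.per_class["1"]
        assert c1["precision"] == pytest.approx(2 / 3)
        assert c1["sensitivity"] == pytest.approx(2 / 3)
        assert c1["specificity"] == pytest.approx(6 / 7)
        assert c1["accuracy"] == pytest.approx(0.8)
        assert c1["f1"] == pytest.approx(2 / 3)

    def test_perfect_matrix_gives_ones(self):
        res = classification_metrics(ConfusionMatrix(np.diag([5, 3, 2])))
        assert res.accuracy == 1.0
        for m, v in res.macro.items():
            assert v == pytest.approx(1.0), m

    def test_one_benign_error_out_of_322(self):
        # 207 normal and 51 malignant correct; 63 of 64 benign correct with
        # the single error called malignant
        counts = np.zeros((3, 3), int)
        counts[0, 0] = 207
        counts[1, 1] = 63
        counts[1, 2] = 1
        counts[2, 2] = 51
        res = classification_metrics(ConfusionMatrix(counts))
        assert res.accuracy == pytest.approx(321 / 322)
        assert res.per_class["2"]["sensitivity"] == 1.0  # no missed malignancies

    def test_zero_denominator_flagged_not_raised(self):
        cm = ConfusionMatrix(np.array([[5, 0], [0, 0]]))  # class 1 never occurs
        res = classification_metrics(cm)
        assert res.per_class["1"]["sensitivity"] == 0.0
        assert any("sensitivity[1]" in f for f in res.zero_denominator_flags)

    def test_all_zero_matrix_raises(self):
        with pytest.raises(InputError):
            classification_metrics(ConfusionMatrix(np.zeros((3, 3), int)))


class TestAuc:
    def test_perfect_separation(self):
        y = [0, 0, 1, 1]
        p = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        assert auc_macro(y, p) == pytest.approx(1.0)

    def test_identical_scores_give_half(self):
        y = [0, 1, 0, 1]
        p = np.full((4, 2), 0.5)
        assert auc_macro(y, p) == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self):
        # Mann-Whitney: AUC = (#concordant + 0.5 #ties) / (n_pos * n_neg)
        y = np.array([0, 1, 0, 1, 1, 0])
        s = np.array([0.2, 0.7, 0.4, 0.4, 0.9, 0.1])  # score for class 1
        pos, neg = s[y == 1], s[y == 0]
        pairs = [(a, b) for a in pos for b in neg]
        oracle = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a, b in pairs) / len(pairs)
        p = np.column_stack([1 - s, s])
        assert auc_macro(y, p) == pytest.approx(oracle)

    def test_absent_class_skipped(self):
        y = [0, 0, 1, 1]
        p = np.column_stack([np.array([0.8, 0.7, 0.2, 0.3]),
                             np.array([0.1, 0.2, 0.7, 0.6]),
                             np.array([0.1, 0.1, 0.1, 0.1])])
        assert 0.0 <= auc_macro(y, p) <= 1.0


class TestAggregateFolds:
    def test_printed_accuracy_row(self):
        df = pd.DataFrame({"fold": range(1, 6),
                           "accuracy": [99.68, 99.75, 99.70, 99.80, 99.67]})
        agg = aggregate_folds(df)
        assert agg.loc["accuracy", "mean"] == pytest.approx(99.72)
        assert agg.loc["accuracy", "sd"] == pytest.approx(0.05)

    def test_printed_sensitivity_mean(self):
        df = pd.DataFrame({"fold": range(1, 6),
                           "sensitivity": [98.72, 99.21, 98.93, 99.15, 98.94]})
        assert aggregate_folds(df).loc["sensitivity", "mean"] == pytest.approx(98.99)

    def test_identical_folds_have_zero_sd(self):
        df = pd.DataFrame({"fold": [1, 2, 3], "accuracy": [97.0, 97.0, 97.0]})
        assert aggregate_folds(df).loc["accuracy", "sd"] == 0.0

    def test_translation_and_scale_equivariance_of_mean(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(90, 100, 5)
        base = aggregate_folds(pd.DataFrame({"fold": range(5), "m": vals}), decimals=10)
        shifted = aggregate_folds(pd.DataFrame({"fold": range(5), "m": 2 * vals + 3}), decimals=10)
        assert shifted.loc["m", "mean"] == pytest.approx(2 * base.loc["m", "mean"] + 3)
        assert shifted.loc["m", "sd"] == pytest.approx(2 * base.loc["m", "sd"])

    def test_missing_values_raise(self):
        df = pd.DataFrame({"fold": [1, 2], "accuracy": [99.0, np.nan]})
        with pytest.raises(InputError):
            aggregate_folds(df)


def rank_formula_oracle(matrix):
    """Independent Friedman computation: explicit per-fold ranking loop."""
    matrix = np.asarray(matrix, float)
    n, k = matrix.shape
    ranks = np.zeros_like(matrix)
    for i, row in enumerate(matrix):
        order = np.argsort(-row)
        r = np.empty(k)
        j = 0
        while j < k:
            tied = [order[j]]
            while j + len(tied) < k and row[order[j + len(tied)]] == row[order[j]]:
                tied.append(order[j + len(tied)])
            avg = np.mean(range(j + 1, j + len(tied) + 1))
            for t in tied:
                r[t] = avg
            j += len(tied)
        ranks[i] = r
    rbar = ranks.mean(axis=0)
    return 12 * n / (k * (k + 1)) * (rbar**2).sum() - 3 * n * (k + 1)


class TestFriedman:
    def test_all_identical_scores_give_zero(self):
        m = np.full((5, 4), 97.0)
        stat, p = friedman(m)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_strict_ordering_attains_maximum_fifteen(self):
        # one model strictly best ... strictly worst in every one of 5 folds
        m = np.tile([99.9, 99.0, 98.0, 97.0], (5, 1))
        stat, _ = friedman(m)
        assert stat == pytest.approx(15.0)  # 3*(1+4+9+16) - 75

    def test_matches_independent_oracle_and_scipy(self):
        rng = np.random.default_rng(42)
        m = rng.uniform(90, 100, (5, 4))
        stat, p = friedman(m)
        assert stat == pytest.approx(rank_formula_oracle(m), abs=1e-10)
        s_stat, s_p = sps.friedmanchisquare(*m.T)
        assert stat == pytest.approx(s_stat)
        assert p == pytest.approx(s_p)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(0.9, 1.0, (6, 3))
        stat1, _ = friedman(m)
        stat2, _ = friedman(np.exp(10 * m))
        assert stat1 == pytest.approx(stat2)

    def test_exact_permutation_p_close_to_chisq_for_extreme(self):
        m = np.tile([4.0, 3.0, 2.0], (4, 1))  # k=3, N=4, strict ordering
        stat, p_exact = friedman(m, method="exact")
        assert stat == pytest.approx(8.0)
        assert p_exact == pytest.approx(1 / 6**4 * 6 * 1, rel=0.5)  # only full-order perms reach max

    def test_average_ranks_sum_to_k_k_plus_1_over_2(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            m = rng.uniform(0, 1, (5, 4))
            assert average_ranks(m).sum() == pytest.approx(4 * 5 / 2)

    def test_non_finite_raises(self):
        with pytest.raises(InputError):
            friedman(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestNemenyi:
    def test_diagonal_ones_and_symmetry(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(90, 100, (5, 4))
        p = nemenyi(m)
        assert np.allclose(np.diag(p), 1.0)
        assert np.allclose(p, p.T)
        assert np.all((p >= 0) & (p <= 1))

    def test_equal_average_ranks_give_p_one(self):
        m = np.tile([1.0, 2.0], (4, 1))
        m[2] = [2.0, 1.0]
        m[3] = [2.0, 1.0]  # two folds each way -> equal average ranks
        p = nemenyi(m)
        assert p[0, 1] == pytest.approx(1.0)


class TestCriticalDifference:
    def test_published_constants_give_2_41(self):
        cd = critical_difference(4, 5, Q_ALPHA_REPORTED)
        assert round(cd, 2) == 2.41

    def test_zero_q_alpha(self):
        assert critical_difference(4, 5, 0.0) == 0.0

    def test_direct_formula_evaluation(self):
        assert critical_difference(3, 10, 2.343) == pytest.approx(2.343 * np.sqrt(0.2))

    def test_standard_k4_value_is_about_2_569(self):
        assert Q_ALPHA_NEMENYI_K4 == pytest.approx(2.569, abs=0.005)

    def test_invalid_inputs_raise(self):
        with pytest.raises(InputError):
            critical_difference(1, 5)
        with pytest.raises(InputError):
            critical_difference(4, 0)


class TestCDDiagram:
    def test_published_ranks_mark_exactly_one_significant_pair(self):
        d = cd_diagram([1.10, 1.90, 3.0, 4.0], 2.41,
                       ["hmc", "hierarchical", "multiscale", "baseline"])
        assert d.significant_pairs == [("hmc", "baseline")]
        assert d.models == ["hmc", "hierarchical", "multiscale", "baseline"]

    def test_all_equal_ranks_form_single_group(self):
        d = cd_diagram([2.5, 2.5, 2.5], 1.0)
        assert len(d.groups) == 1 and len(d.groups[0]) == 3
        assert d.significant_pairs == []

    def test_gap_exactly_cd_is_significant(self):
        d = cd_diagram([1.0, 3.0], 2.0, ["a", "b"])
        assert d.significant_pairs == [("a", "b")]
        assert d.groups == [["a"], ["b"]]

    def test_json_round_trip_fields(self):
        import json

        d = cd_diagram([1.0, 2.0], 5.0, ["x", "y"])
        payload = json.loads(d.to_json())
        assert payload["cd"] == 5.0
        assert {e["model"] for e in payload["entries"]} == {"x", "y"}


def test_rank_summary_is_internally_consistent():
    rng = np.random.default_rng(3)
    m = rng.uniform(95, 100, (5, 4))
    rs = rank_summary(m, ["a", "b", "c", "d"])
    assert rs.k == 4 and rs.n == 5
    assert rs.average_ranks.sum() == pytest.approx(10.0)
    assert rs.cd == pytest.approx(critical_difference(4, 5))
    assert np.allclose(np.diag(rs.nemenyi_p), 1.0)
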