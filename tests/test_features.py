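"""Information estimates, JMIM ranking (with brute-force cross-checks),
the boosted classifier and decision-curve net benefit."""

import itertools

import numpy as np
import pandas as pd
import pytest

from icufluid import (
    ValidationError,
    discretize_table,
    jmim_rank,
    joint_mutual_information,
    mutual_information,
    net_benefit,
    select_by_importance,
    train_phenotype_classifier,
)
from icufluid.features import SplitSpec, quantile_discretize


def entropy_bits(x):
    _, counts = np.unique(x, return_counts=True)
    p = counts / counts.sum()
    return -np.sum(p * np.log2(p))


class TestMutualInformation:
    def test_constant_outcome_carries_no_information(self):
        x = np.array([0, 1, 0, 1, 1])
        assert mutual_information(x, np.zeros(5)) == 0.0

    def test_identity_on_uniform_binary_is_one_bit(self):
        x = np.array([0, 1] * 50)
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_hand_computed_2x2_table(self):
        # joint counts ((2,1),(1,2)) over 6 samples
        x = np.array([0, 0, 0, 1, 1, 1])
        y = np.array([0, 0, 1, 0, 1, 1])
        expected = sum(
            c / 6 * np.log2((c / 6) / (0.5 * 0.5)) for c in (2, 1, 1, 2)
        )
        assert mutual_information(x, y) == pytest.approx(expected)

    def test_nonnegative_and_bounded_by_entropy(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            x = rng.integers(0, 4, 60)
            y = rng.integers(0, 3, 60)
            mi = mutual_information(x, y)
            assert 0.0 <= mi <= min(entropy_bits(x), entropy_bits(y)) + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mutual_information([0, 1], [0, 1, 2])


class TestJointMutualInformation:
    def test_constant_partner_degenerates_to_marginal(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 100)
        y = (x + rng.integers(0, 2, 100)) % 3
        const = np.zeros(100)
        assert joint_mutual_information(x, const, y) == pytest.approx(
            mutual_information(x, y)
        )

    def test_xor_is_one_bit_with_zero_marginals(self):
        combos = np.array(list(itertools.product([0, 1], [0, 1])) * 25)
        x1, x2 = combos[:, 0], combos[:, 1]
        y = x1 ^ x2
        assert mutual_information(x1, y) == pytest.approx(0.0, abs=1e-12)
        assert mutual_information(x2, y) == pytest.approx(0.0, abs=1e-12)
        assert joint_mutual_information(x1, x2, y) == pytest.approx(1.0)

    def test_chain_rule_on_random_binary_table(self):
        # I(X1,X2;Y) = I(X1;Y) + I(X2;Y|X1), conditional term by brute force
        rng = np.random.default_rng(2)
        x1 = rng.integers(0, 2, 400)
        x2 = rng.integers(0, 2, 400)
        y = rng.integers(0, 2, 400) & (x1 | x2)
        lhs = joint_mutual_information(x1, x2, y)
        cond = 0.0
        for v in (0, 1):
            m = x1 == v
            cond += m.mean() * mutual_information(x2[m], y[m])
        assert lhs == pytest.approx(mutual_information(x1, y) + cond)


class TestJmimRank:
    def brute_force_two(self, X: pd.DataFrame, y):
        """Best ordered pair under the greedy criterion, by enumeration."""
        cols = list(X.columns)
        mi = {c: mutual_information(X[c], y) for c in cols}
        first = max(cols, key=lambda c: (mi[c], -cols.index(c)))
        rest = [c for c in cols if c != first]
        second = max(
            rest,
            key=lambda c: (joint_mutual_information(X[c], X[first], y), -cols.index(c)),
        )
        return [first, second]

    def test_single_candidate_scores_one(self):
        X = pd.DataFrame({"only": [0, 1, 0, 1, 1, 0]})
        scores = jmim_rank(X, np.array([0, 1, 0, 1, 1, 0]))
        assert scores[0].importance == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_matches_brute_force_on_three_features(self, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({f"f{j}": rng.integers(0, 3, 200) for j in range(3)})
        y = (X["f0"] + rng.integers(0, 2, 200)) % 3
        got = [s.feature for s in jmim_rank(X, y, m=2)]
        assert got == self.brute_force_two(X, y)

    def test_informative_features_rank_above_noise(self):
        rng = np.random.default_rng(3)
        n = 2000
        y = rng.integers(0, 2, n)
        X = {}
        for j in range(3):  # noisy copies of the outcome
            flip = rng.random(n) < 0.2
            X[f"signal{j}"] = np.where(flip, 1 - y, y)
        for j in range(7):
            X[f"noise{j}"] = rng.integers(0, 2, n)
        scores = jmim_rank(pd.DataFrame(X), y, m=10)
        top3 = {s.feature for s in scores[:3]}
        assert top3 == {"signal0", "signal1", "signal2"}

    def test_column_order_invariance(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({f"f{j}": rng.integers(0, 2, 300) for j in range(5)})
        y = X["f2"] ^ X["f4"]
        a = [s.feature for s in jmim_rank(X, y)]
        b = [s.feature for s in jmim_rank(X[list(reversed(X.columns))], y)]
        assert set(a[:2]) == set(b[:2])

    def test_importance_normalised_with_top_at_one(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({f"f{j}": rng.integers(0, 2, 500) for j in range(4)})
        y = X["f0"]
        scores = jmim_rank(X, y)
        imp = [s.importance for s in scores]
        assert max(imp) == 1.0
        assert all(0.0 <= v <= 1.0 for v in imp)
        assert sorted(s.rank for s in scores) == [1, 2, 3, 4]

    def test_threshold_separates_signal_from_noise(self):
        # strong + moderate signal, pure noise: the min-joint criterion keeps
        # noise near the weakest selected feature's marginal information, well
        # under the 0.8 importance bar
        rng = np.random.default_rng(6)
        n = 2000
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(
            {
                "strong": np.where(rng.random(n) < 0.9, y, 1 - y),
                "moderate": np.where(rng.random(n) < 0.7, y, 1 - y),
                **{f"noise{j}": rng.integers(0, 2, n) for j in range(3)},
            }
        )
        scores = jmim_rank(X, y)
        assert set(select_by_importance(scores, 0.8)) == {"strong", "moderate"}
        again = jmim_rank(X, y)
        assert [s.feature for s in again] == [s.feature for s in scores]


class TestDiscretize:
    def test_quantile_bins_balanced(self):
        x = np.arange(1000.0)
        binned = quantile_discretize(x, bins=5)
        _, counts = np.unique(binned, return_counts=True)
        assert len(counts) == 5
        assert counts.max() - counts.min() <= 1

    def test_heavy_ties_collapse_bins(self):
        x = np.r_[np.zeros(900), np.arange(100.0)]
        binned = quantile_discretize(x, bins=5)
        assert binned.min() == 0 and len(np.unique(binned)) >= 2

    def test_table_discretization_covers_all_features(self, small_cohort):
        baseline, _ = small_cohort
        disc = discretize_table(baseline, bins=5)
        assert list(disc.columns) == baseline.features


class TestClassifier:
    def test_separable_labels_reach_perfect_auc(self, small_cohort):
        baseline, _ = small_cohort
        labels = pd.Series(
            np.where(baseline.df["age"] > baseline.df["age"].median(), "old", "young"),
            index=baseline.df["patient_id"],
        )
        _, auc, (lo, hi) = train_phenotype_classifier(
            baseline, labels, ["age"], SplitSpec(test_size=0.3), seed=0
        )
        assert lo > 0.99

    def test_permuted_labels_give_chance_auc(self, small_cohort, true_labels):
        baseline, _ = small_cohort
        rng = np.random.default_rng(0)
        perm = pd.Series(
            rng.permutation(true_labels.to_numpy()), index=true_labels.index
        )
        _, auc, (lo, hi) = train_phenotype_classifier(
            baseline, perm, ["age", "bun", "sofa"], SplitSpec(test_size=0.3), seed=0
        )
        assert 0.45 <= lo and hi <= 0.58

    def test_distilled_model_recovers_phenotypes_well(self, small_cohort, true_labels):
        # nine JMIM-ranked features suffice for strong one-vs-rest AUC on the
        # synthetic cohort (scaled-down analogue of a full-cohort classifier)
        baseline, _ = small_cohort
        disc = discretize_table(baseline, bins=5)
        scores = jmim_rank(disc, true_labels.to_numpy())
        selected = [s.feature for s in scores[:9]]
        _, auc, (lo, hi) = train_phenotype_classifier(
            baseline, true_labels, selected, SplitSpec(test_size=0.3), seed=1
        )
        assert lo >= 0.85

    def test_single_class_rejected(self, small_cohort):
        baseline, _ = small_cohort
        labels = pd.Series("x", index=baseline.df["patient_id"])
        with pytest.raises(ValidationError):
            train_phenotype_classifier(baseline, labels, ["age"], seed=0)


class TestNetBenefit:
    def test_perfect_predictor_equals_prevalence(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        p = y.astype(float)
        curve = net_benefit(p, y, thresholds=[0.1, 0.3, 0.5, 0.9])
        np.testing.assert_allclose(curve["net_benefit"], 0.30)

    def test_treat_none_is_zero(self):
        curve = net_benefit(np.zeros(50), np.r_[np.ones(10), np.zeros(40)], [0.2, 0.5])
        np.testing.assert_allclose(curve["treat_none"], 0.0)

    def test_hand_computed_cell(self):
        # TP=30, FP=20, N=100 at p_t=0.2 -> 0.30 - 0.20*0.25 = 0.25
        y = np.r_[np.ones(30), np.zeros(20), np.zeros(40), np.ones(10)]
        p = np.r_[np.ones(30), np.ones(20), np.zeros(50)]
        curve = net_benefit(p, y, thresholds=[0.2])
        assert curve["net_benefit"].iloc[0] == pytest.approx(0.25)

    def test_treat_all_closed_form(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        pi = y.mean()
        ths = [0.1, 0.25, 0.5, 0.75]
        curve = net_benefit(rng.random(200), y, ths)
        for t, got in zip(ths, curve["treat_all"]):
            assert got == pytest.approx(pi - (1 - pi) * t / (1 - t))

    def test_empty_truth_rejected(self):
        with pytest.raises(ValidationError):
            net_benefit(np.array([]), np.array([]), [0.5])
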