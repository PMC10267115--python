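"""Condition decoding: leakage-safe cross-validation, permutation nulls,
McNemar comparison, out-of-bag importance."""

import numpy as np
import pytest
from scipy import stats as sps

from crossconn.classify import (
    _check_no_split_subjects,
    crossval_rf,
    flip_labels_within_subject,
    mcnemar_compare,
    oob_importance,
    permutation_test_bac,
    prune_features,
    subject_folds,
)


def paired_dataset(rng, n_subjects=12, n_features=10, effect=0.0, noise=1.0):
    """Sessions x features array with paired labels/groups."""
    x, y, g = [], [], []
    for s in range(n_subjects):
        base = rng.normal(0, 1, n_features)
        x.append(base + rng.normal(0, noise, n_features))
        y.append("placebo")
        g.append(f"s{s}")
        x.append(base + effect + rng.normal(0, noise, n_features))
        y.append("drug")
        g.append(f"s{s}")
    return np.array(x), np.array(y), np.array(g)


class TestFoldsAndPruning:
    def test_subject_sessions_share_a_fold(self, rng):
        _, _, groups = paired_dataset(rng)
        folds = subject_folds(groups, 5, rng)
        for s in set(groups.tolist()):
            assert len(set(folds[groups == s].tolist())) == 1

    def test_split_subject_guard_fires(self):
        groups = np.array(["a", "a", "b", "b"])
        with pytest.raises(RuntimeError, match="leakage"):
            _check_no_split_subjects(np.array([0, 1, 0, 0]), groups)

    def test_pruning_drops_constant_and_duplicate_features(self, rng):
        x = rng.normal(size=(20, 4))
        x[:, 1] = 3.0                      # no variance
        x[:, 3] = 2.0 * x[:, 0] + 1e-9     # duplicate of column 0
        kept = prune_features(x)
        assert 1 not in kept and 3 not in kept and 0 in kept and 2 in kept


class TestCrossvalRf:
    def test_separable_study_decodes_near_perfectly(self, rng):
        x, y, g = paired_dataset(rng, effect=3.0, noise=0.2)
        report = crossval_rf(x, y, g, k=4, n_trees=100, seed=0)
        assert report.bac >= 0.9
        assert len(report.y_pred) == len(y)  # every session predicted once

    def test_deterministic_given_seed(self, rng):
        x, y, g = paired_dataset(rng, effect=0.5)
        r1 = crossval_rf(x, y, g, k=3, n_trees=50, seed=11)
        r2 = crossval_rf(x, y, g, k=3, n_trees=50, seed=11)
        np.testing.assert_array_equal(r1.y_pred, r2.y_pred)
        assert r1.bac == r2.bac

    def test_balanced_accuracy_definition(self, rng):
        x, y, g = paired_dataset(rng, effect=1.0, noise=0.5)
        report = crossval_rf(x, y, g, k=3, n_trees=50, seed=2)
        drug = report.y_true == "drug"
        sens = np.mean(report.y_pred[drug] == "drug")
        spec = np.mean(report.y_pred[~drug] == "placebo")
        assert report.bac == pytest.approx((sens + spec) / 2)

    def test_leakage_canary_permuted_labels_stay_at_chance(self, rng):
        # a perfectly separating feature exists, but after within-subject
        # label flips it carries no information about the permuted labels;
        # any preprocessing leak would show up as above-chance decoding
        x, y, g = paired_dataset(rng, n_subjects=14, effect=0.0, noise=1.0)
        x[:, 0] = (y == "drug").astype(float)
        bacs = []
        for seed in range(10):
            perm = flip_labels_within_subject(y, g, np.random.default_rng(seed))
            bacs.append(crossval_rf(x, perm, g, k=4, n_trees=50, seed=seed).bac)
        assert 0.3 < np.mean(bacs) < 0.7


class TestPermutationTest:
    def test_exhaustive_four_subjects_matches_enumeration(self, rng):
        x, y, g = paired_dataset(rng, n_subjects=4)
        preds = y.copy()  # a fixed "classifier" output

        def bac_of(labels):
            drug = labels == "drug"
            return 0.5 * (np.mean(preds[drug] == "drug")
                          + np.mean(preds[~drug] == "placebo"))

        null, p = permutation_test_bac(bac_of, y, g, observed_bac=bac_of(y),
                                       n_perm=100, seed=0)
        assert len(null) == 16  # all 2^4 flips enumerated
        # independent enumeration
        count = 0
        subjects = sorted(set(g.tolist()))
        for code in range(16):
            labels = y.copy()
            for i, s in enumerate(subjects):
                if (code >> i) & 1:
                    sel = g == s
                    labels[sel] = ["drug" if v == "placebo" else "placebo"
                                   for v in labels[sel]]
            count += bac_of(labels) >= bac_of(y) - 1e-12
        assert p == pytest.approx((1 + count) / 17)

    def test_observed_below_null_median_gives_large_p(self, rng):
        x, y, g = paired_dataset(rng, n_subjects=6)
        _, p = permutation_test_bac(lambda labels: 0.5, y, g,
                                    observed_bac=0.1, n_perm=99, seed=0)
        assert p > 0.5


class TestMcnemar:
    def test_identical_predictions_give_p_one(self):
        truth = np.array(["drug", "placebo"] * 5)
        preds = truth.copy()
        stat, p = mcnemar_compare(preds, preds, truth)
        assert p == pytest.approx(1.0)

    def test_one_sided_discordance_matches_binomial_tail(self):
        truth = np.array(["drug"] * 10)
        preds_a = truth.copy()                  # 10 right
        preds_b = np.array(["placebo"] * 10)    # 10 wrong: b=10, c=0
        _, p = mcnemar_compare(preds_a, preds_b, truth)
        oracle = 2 * sum(sps.binom.pmf(k, 10, 0.5) for k in range(10, 11))
        assert p == pytest.approx(oracle, rel=1e-10)
        assert p == pytest.approx(2 * 0.5**10)

    def test_symmetric_discordance_gives_p_one(self):
        truth = np.array(["drug"] * 6)
        preds_a = np.array(["drug"] * 3 + ["placebo"] * 3)
        preds_b = np.array(["placebo"] * 3 + ["drug"] * 3)
        _, p = mcnemar_compare(preds_a, preds_b, truth)
        assert p == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_compare(np.array(["drug"]), np.array(["drug", "drug"]),
                            np.array(["drug", "drug"]))


class TestOobImportance:
    def test_planted_feature_ranks_first_noise_near_zero(self, rng):
        x, y, g = paired_dataset(rng, n_subjects=12, n_features=5,
                                 effect=0.0, noise=1.0)
        x[:, 2] = (y == "drug") + rng.normal(0, 0.05, len(y))
        report = crossval_rf(x, y, g, k=3, n_trees=100, seed=3,
                             keep_models=True)
        imp, sd = oob_importance(report, x, seed=0)
        assert np.argmax(imp) == 2
        others = np.delete(imp, 2)
        assert np.abs(others).max() < imp[2] / 2
        assert sd.shape == imp.shape
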