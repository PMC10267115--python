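"""PLSC: SVD mechanics, permutation inference, bootstrap ratios."""

import numpy as np
import pandas as pd
import pytest

from crossconn.plsc import (
    BSR_CAP,
    BehaviouralPlscData,
    TaskPlscData,
    behavioural_plsc,
    bootstrap_ratios,
    permutation_test,
    task_plsc,
)


def make_task_table(x_placebo, x_drug):
    """Stack per-condition subject x feature arrays into the canonical table."""
    n, f = x_placebo.shape
    rows, idx = [], []
    for s in range(n):
        rows.append(x_placebo[s])
        idx.append((f"s{s}", "placebo"))
        rows.append(x_drug[s])
        idx.append((f"s{s}", "drug"))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(idx, names=["subject_id", "condition"]),
        columns=[f"f{j}" for j in range(f)],
    )


class TestTaskPlsc:
    def test_singular_value_conservation(self, rng):
        table = make_task_table(rng.normal(size=(8, 5)), rng.normal(size=(8, 5)))
        res = task_plsc(table, n_perm=0, n_boot=0)
        m = np.stack([
            table.xs(c, level="condition").mean().to_numpy()
            for c in ("placebo", "drug")
        ])
        mc = m - m.mean(axis=0)
        assert np.sum(res.singular_values**2) == pytest.approx(
            np.sum(mc**2), rel=1e-10
        )

    def test_identical_condition_means_give_zero_spectrum(self, rng):
        x = rng.normal(size=(6, 4))
        table = make_task_table(x, x.copy())
        res = task_plsc(table, n_perm=0, n_boot=0)
        np.testing.assert_allclose(res.singular_values, 0.0, atol=1e-10)

    def test_two_conditions_have_rank_one_structure(self, rng):
        table = make_task_table(rng.normal(size=(7, 6)), rng.normal(size=(7, 6)))
        res = task_plsc(table, n_perm=0, n_boot=0)
        assert res.singular_values[1] == pytest.approx(0.0, abs=1e-10)

    def test_singular_values_match_eigendecomposition_oracle(self):
        mean_p = np.array([1.0, 2.0, 3.0])
        mean_d = np.array([2.0, 1.0, 5.0])
        x_p = np.tile(mean_p, (4, 1))
        x_d = np.tile(mean_d, (4, 1))
        res = task_plsc(make_task_table(x_p, x_d), n_perm=0, n_boot=0)
        m = np.stack([mean_p, mean_d])
        mc = m - m.mean(axis=0)
        eigvals = np.linalg.eigvalsh(mc @ mc.T)[::-1]
        np.testing.assert_allclose(
            res.singular_values, np.sqrt(np.maximum(eigvals, 0)), atol=1e-10
        )

    def test_drug_condition_scores_positive_by_convention(self, rng):
        table = make_task_table(rng.normal(size=(8, 5)),
                                rng.normal(size=(8, 5)) + 1.0)
        res = task_plsc(table, n_perm=0, n_boot=0)
        assert res.condition_scores.loc["drug", "LV1"] > 0

    def test_single_subject_condition_rejected(self, rng):
        table = make_task_table(rng.normal(size=(1, 3)), rng.normal(size=(1, 3)))
        with pytest.raises(ValueError, match=">= 2"):
            task_plsc(table, n_perm=0, n_boot=0)


class TestPermutation:
    def test_exhaustive_enumeration_matches_direct_oracle(self, rng):
        # 3 subjects -> all 8 within-subject flip patterns are enumerated;
        # recompute the p-value by explicit enumeration.
        x_p, x_d = rng.normal(size=(3, 4)), rng.normal(size=(3, 4)) + 0.5
        table = make_task_table(x_p, x_d)
        data = TaskPlscData(table)
        p = permutation_test(data, n_perm=100, rng=np.random.default_rng(0))

        def sv1(xp, xd):
            m = np.stack([xp.mean(axis=0), xd.mean(axis=0)])
            return np.linalg.svd(m - m.mean(axis=0), compute_uv=False)[0]

        obs = sv1(x_p, x_d)
        count = 0
        for code in range(8):
            xp, xd = x_p.copy(), x_d.copy()
            for s in range(3):
                if (code >> s) & 1:
                    xp[s], xd[s] = x_d[s].copy(), x_p[s].copy()
            count += sv1(xp, xd) >= obs - 1e-12
        assert p[0] == pytest.approx((1 + count) / 9)

    def test_low_permutation_count_warns(self, rng):
        table = make_task_table(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_test(TaskPlscData(table), n_perm=50,
                             rng=np.random.default_rng(0))

    def test_add_one_convention_floor(self, rng):
        # a huge planted effect beats every proper flip; the identity and
        # the all-subject flip (which merely swaps the two condition rows)
        # reproduce the observed value, so p bottoms out at 3/9 for n=3
        x_p = rng.normal(size=(3, 4))
        table = make_task_table(x_p, x_p + 100.0)
        p = permutation_test(TaskPlscData(table), n_perm=100,
                             rng=np.random.default_rng(0))
        assert p[0] == pytest.approx(3 / 9)


class TestBehavioural:
    def test_behaviour_copying_a_feature_dominates(self, rng):
        x = rng.normal(size=(10, 6))
        y = x[:, 3].copy()
        # make the remaining features exactly uncorrelated with behaviour so
        # the latent score is carried by feature 3 alone
        yc = (y - y.mean()) / np.linalg.norm(y - y.mean())
        for j in range(6):
            if j != 3:
                xc = x[:, j] - x[:, j].mean()
                x[:, j] = xc - (xc @ yc) * yc
        behaviour = pd.Series(y, index=[f"s{i}" for i in range(10)])
        feats = pd.DataFrame(x, index=behaviour.index,
                             columns=[f"f{j}" for j in range(6)])
        res = behavioural_plsc(feats, behaviour, n_perm=0, n_boot=0)
        assert np.argmax(np.abs(res.saliences[:, 0])) == 3
        assert res.behav_correlation == pytest.approx(1.0, abs=1e-6)

    def test_constant_behaviour_rejected(self, rng):
        feats = pd.DataFrame(rng.normal(size=(8, 3)),
                             index=[f"s{i}" for i in range(8)])
        with pytest.raises(ValueError, match="constant"):
            behavioural_plsc(feats, pd.Series(1.0, index=feats.index),
                             n_perm=0, n_boot=0)

    def test_latent_correlation_is_nonnegative_by_convention(self, rng):
        feats = pd.DataFrame(rng.normal(size=(12, 5)),
                             index=[f"s{i}" for i in range(12)])
        behaviour = pd.Series(rng.normal(size=12), index=feats.index)
        res = behavioural_plsc(feats, behaviour, n_perm=0, n_boot=0)
        assert res.behav_correlation >= 0


class TestBootstrapRatios:
    def test_constant_feature_has_zero_salience_and_bsr(self, rng):
        x_p = rng.normal(size=(8, 4))
        x_d = rng.normal(size=(8, 4)) + 0.5
        x_p[:, 2] = 1.5
        x_d[:, 2] = 1.5
        table = make_task_table(x_p, x_d)
        res = task_plsc(table, n_perm=0, n_boot=100,
                        seed=np.random.default_rng(0))
        assert res.saliences[2, 0] == pytest.approx(0.0, abs=1e-12)
        assert res.bootstrap_ratios[2, 0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.abs(res.bootstrap_ratios) <= BSR_CAP)

    def test_dominant_feature_ranks_first_against_independent_loop(self, rng):
        # one feature carries a large stable condition difference; an
        # independently coded subject-resampling loop must agree on the
        # top-ranked feature
        n = 5
        x_p = rng.normal(0, 0.3, size=(n, 4))
        x_d = x_p.copy()
        x_d[:, 1] += 3.0
        x_d += rng.normal(0, 0.05, size=(n, 4))
        table = make_task_table(x_p, x_d)
        data = TaskPlscData(table)
        bsr = bootstrap_ratios(data, n_boot=200, rng=np.random.default_rng(1))
        assert np.argmax(np.abs(bsr[:, 0])) == 1

        # independent oracle: plain loop over subject resamples
        def salience(xp, xd):
            m = np.stack([xp.mean(axis=0), xd.mean(axis=0)])
            mc = m - m.mean(axis=0)
            _, _, vt = np.linalg.svd(mc, full_matrices=False)
            return vt[0]

        ref = salience(x_p, x_d)
        r2 = np.random.default_rng(99)
        boots = []
        for _ in range(200):
            pick = r2.integers(0, n, n)
            if len(set(pick.tolist())) < 2:
                continue
            v = salience(x_p[pick], x_d[pick])
            boots.append(v * np.sign(v @ ref))
        oracle = np.abs(ref / np.std(boots, axis=0, ddof=1))
        assert np.argmax(oracle) == 1

    def test_behavioural_bootstrap_shape(self, rng):
        feats = pd.DataFrame(rng.normal(size=(10, 4)),
                             index=[f"s{i}" for i in range(10)])
        behaviour = pd.Series(rng.normal(size=10), index=feats.index)
        bsr = bootstrap_ratios(BehaviouralPlscData(feats, behaviour),
                               n_boot=50, rng=np.random.default_rng(0))
        assert bsr.shape == (4, 1)
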