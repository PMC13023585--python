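"""Repeated-measures ANOVA, Friedman, Dunn and paired t."""

import numpy as np
import pandas as pd
import pytest

from plvnet.stats import dunn_posthoc, friedman_test, paired_t, rm_anova_2x2


def random_table(seed: int, n: int = 34, effects=(0.0, 0.0, 0.0)) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    a_eff, b_eff, ab_eff = effects
    rows = []
    for s in range(n):
        subj = rng.normal(0, 0.5)
        for ai, a in enumerate(("without_music", "with_music")):
            for bi, b in enumerate(("pre", "post")):
                val = (
                    subj
                    + a_eff * ai
                    + b_eff * bi
                    + ab_eff * ai * bi
                    + rng.normal(0, 1.0)
                )
                rows.append((s, a, b, val))
    return pd.DataFrame(rows, columns=["subject", "condition", "time", "value"])


class TestRmAnova:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_reference_implementation(self, seed):
        from statsmodels.stats.anova import AnovaRM

        table = random_table(seed, effects=(0.4, 0.2, 0.3))
        mine = rm_anova_2x2(table)
        ref = AnovaRM(
            table, "value", "subject", within=["condition", "time"]
        ).fit().anova_table
        assert mine.condition.F == pytest.approx(ref.loc["condition", "F Value"], abs=1e-8)
        assert mine.time.F == pytest.approx(ref.loc["time", "F Value"], abs=1e-8)
        assert mine.interaction.F == pytest.approx(
            ref.loc["condition:time", "F Value"], abs=1e-8
        )
        assert mine.condition.p == pytest.approx(ref.loc["condition", "Pr > F"], abs=1e-8)

    def test_df_is_1_and_n_minus_1(self):
        res = rm_anova_2x2(random_table(7, n=34))
        assert res.condition.df == (1, 33)
        assert res.time.df == (1, 33)
        assert res.interaction.df == (1, 33)

    def test_partial_eta2_identity(self):
        # for 1-df effects, partial eta^2 = F / (F + df_error)
        res = rm_anova_2x2(random_table(11, effects=(0.5, 0.0, 0.0)))
        for eff in (res.condition, res.time, res.interaction):
            assert eff.partial_eta2 == pytest.approx(eff.F / (eff.F + 33), abs=1e-12)
            assert 0 <= eff.partial_eta2 < 1

    def test_constant_response_gives_zero_f(self):
        table = random_table(0, n=5)
        table["value"] = 1.25
        res = rm_anova_2x2(table)
        assert res.condition.F == 0.0
        assert res.time.F == 0.0
        assert res.interaction.F == 0.0

    def test_ss_conservation(self):
        # total SS equals the sum of all decomposed components
        table = random_table(3, n=10, effects=(0.3, 0.1, 0.2))
        y = table.pivot_table(
            index="subject", columns=["condition", "time"], values="value"
        ).to_numpy()
        ss_total = ((y - y.mean()) ** 2).sum()
        n = y.shape[0]
        ss_subj = 4 * ((y.mean(axis=1) - y.mean()) ** 2).sum()
        grand = y.mean()
        ya = y.reshape(n, 2, 2)
        m_a = ya.mean(axis=(0, 2))
        m_b = ya.mean(axis=(0, 1))
        m_ab = ya.mean(axis=0)
        m_s = ya.mean(axis=(1, 2))
        m_sa = ya.mean(axis=2)
        m_sb = ya.mean(axis=1)
        ss_a = 2 * n * ((m_a - grand) ** 2).sum()
        ss_b = 2 * n * ((m_b - grand) ** 2).sum()
        ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
        ss_as = 2 * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
        ss_bs = 2 * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
        resid = (
            ya - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
            + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :] - grand
        )
        ss_abs = (resid ** 2).sum()
        total = ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs + ss_abs
        assert total == pytest.approx(ss_total, rel=1e-10)

    def test_incomplete_design_lists_missing_cells(self):
        table = random_table(1, n=4).iloc[:-1]
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova_2x2(table)


class TestFriedman:
    def test_concordant_3x3_chi2_is_6(self):
        blocks = np.array([[1.0, 2.0, 3.0]] * 3)
        chi2, df, p = friedman_test(blocks)
        # rank-sum formula: 12/(n k (k+1)) * sum R_j^2 - 3 n (k+1)
        n, k = 3, 3
        r = np.array([3.0, 6.0, 9.0])
        expected = 12 / (n * k * (k + 1)) * (r**2).sum() - 3 * n * (k + 1)
        assert chi2 == pytest.approx(expected) == pytest.approx(6.0)
        assert df == 2
        # exact permutation oracle: only fully concordant tables reach 6
        assert p == pytest.approx((1 / 6) ** 2, abs=1e-12)

    def test_column_permutation_invariance(self, rng):
        blocks = rng.normal(size=(10, 4))
        chi2_a, _, _ = friedman_test(blocks)
        chi2_b, _, _ = friedman_test(blocks[:, [2, 0, 3, 1]])
        assert chi2_a == pytest.approx(chi2_b)

    def test_monotone_transform_invariance(self, rng):
        blocks = rng.normal(size=(12, 4))
        chi2_a, _, p_a = friedman_test(blocks)
        chi2_b, _, p_b = friedman_test(np.exp(blocks) + 5)
        assert chi2_a == pytest.approx(chi2_b)
        assert p_a == pytest.approx(p_b)

    def test_exact_matches_chi2_reference_roughly(self):
        # at moderate n the exact permutation p and the chi-square
        # approximation should be close
        blocks = np.random.default_rng(55).normal(size=(8, 3))
        chi2, _, p_exact = friedman_test(blocks, exact=True)
        from scipy.stats import chi2 as chi2_dist

        p_approx = chi2_dist.sf(chi2, 2)
        assert p_exact == pytest.approx(p_approx, abs=0.08)

    def test_degenerate_constant_rows_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            friedman_test(np.ones((4, 3)))

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(123)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            _, _, p = friedman_test(rng.normal(size=(34, 4)), exact=False)
            rejections += p < 0.05
        rate = rejections / reps
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / reps))


class TestDunn:
    def test_identical_columns_adjusted_p_one(self, rng):
        col = rng.normal(size=6)
        blocks = np.column_stack([col, col, rng.normal(size=6)])
        table = dunn_posthoc(blocks)
        pair = table[(table["i"] == 0) & (table["j"] == 1)].iloc[0]
        assert pair["p_adjusted"] == 1.0

    def test_k4_has_six_pairs(self, rng):
        table = dunn_posthoc(rng.normal(size=(10, 4)))
        assert len(table) == 6

    def test_bonferroni_monotone(self, rng):
        table = dunn_posthoc(rng.normal(size=(10, 4)))
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-15).all()
        assert (table["p_adjusted"] <= 1.0).all()

    def test_z_formula(self):
        blocks = np.array([[1.0, 2.0, 3.0]] * 5)  # fully concordant, n=5, k=3
        table = dunn_posthoc(blocks)
        se = np.sqrt(3 * 4 / (6 * 5))
        pair = table[(table["i"] == 0) & (table["j"] == 2)].iloc[0]
        assert pair["z"] == pytest.approx((1 - 3) / se)


class TestPairedT:
    def test_identical_samples(self, rng):
        x = rng.normal(size=5)
        assert paired_t(x, x.copy()) == (0.0, 4, 1.0)

    def test_printed_difference_vector(self):
        t, df, p = paired_t(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert t == pytest.approx(2 * np.sqrt(3))
        assert df == 2

    def test_sign_flip_symmetry(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        t1, _, p1 = paired_t(a, b)
        t2, _, p2 = paired_t(b, a)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_nonzero_constant_difference_rejected(self):
        with pytest.raises(ValueError, match="zero difference variance"):
            paired_t(np.array([1.0, 2.0, 3.0]), np.array([0.5, 1.5, 2.5]))
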