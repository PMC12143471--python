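"""Descriptive comparison layer: Welch t, U, chi-square, alpha, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import symptomnet as sn
from symptomnet.errors import UndefinedResultError
from symptomnet.stats import group_characteristics


class TestWelchT:
    def test_reproduces_printed_anxiety_contrast(self):
        """Published cohort summaries (HADS-A: 8.25+/-3.56 n=232 vs
        5.70+/-3.55 n=554) give t ~ 9.16 with ~433 df."""
        t, df, p = sn.welch_t(8.25, 3.56, 232, 5.70, 3.55, 554)
        # the summaries are printed to 2 dp, so t is reproducible to ~0.01
        assert t == pytest.approx(9.16, abs=0.01)
        assert df == pytest.approx(433.07, abs=1)
        assert p < 0.001

    def test_identical_summaries_give_zero(self):
        t, _, p = sn.welch_t(5.0, 1.2, 50, 5.0, 1.2, 50)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_hand_case(self):
        t, df, _ = sn.welch_t(1.0, 1.0, 100, 0.0, 1.0, 100)
        assert t == pytest.approx(np.sqrt(50), abs=1e-12)  # 1/sqrt(2/100)
        assert df == pytest.approx(198.0, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedResultError):
            sn.welch_t(1.0, 0.0, 10, 2.0, 0.0, 10)

    def test_summary_equals_raw_vector_path(self, rng):
        x, y = rng.normal(0, 1, 40), rng.normal(0.5, 2, 60)
        t_raw, df_raw, p_raw = sn.welch_t_from_samples(x, y)
        t_sum, df_sum, p_sum = sn.welch_t(
            x.mean(), x.std(ddof=1), 40, y.mean(), y.std(ddof=1), 60
        )
        assert t_raw == pytest.approx(t_sum, abs=1e-12)
        assert df_raw == pytest.approx(df_sum, abs=1e-12)
        # cross-check against scipy's Welch test
        res = sps.ttest_ind(x, y, equal_var=False)
        assert t_raw == pytest.approx(res.statistic, abs=1e-10)
        assert p_raw == pytest.approx(res.pvalue, abs=1e-10)


class TestMannWhitney:
    def test_full_symmetry_midranks(self):
        u, _ = sn.mann_whitney_u([1, 2], [1, 2])
        assert u == 2.0  # n1*n2/2

    def test_extreme_separation_convention(self):
        u_low, _ = sn.mann_whitney_u([1, 2, 3], [10, 11, 12])
        u_high, _ = sn.mann_whitney_u([10, 11, 12], [1, 2, 3])
        assert u_low == 0.0 and u_high == 9.0

    def test_matches_pair_counting_oracle(self, rng):
        x = rng.integers(0, 4, 30).astype(float)
        y = rng.integers(0, 4, 45).astype(float)
        wins = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
        u, _ = sn.mann_whitney_u(x, y)
        assert u == pytest.approx(wins)

    def test_u_complement_identity(self, rng):
        x = rng.integers(0, 4, 25).astype(float)
        y = rng.integers(0, 4, 35).astype(float)
        u_xy, _ = sn.mann_whitney_u(x, y)
        u_yx, _ = sn.mann_whitney_u(y, x)
        assert u_xy + u_yx == pytest.approx(25 * 35)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sn.mann_whitney_u([], [1.0])


class TestChiSquare:
    def test_proportional_table_is_zero(self):
        chi2, p = sn.chi_square_2x2(10, 20, 30, 60)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_formula_oracle(self):
        # all expected counts 15: chi2 = 4 * 25/15
        chi2, _ = sn.chi_square_2x2(20, 10, 10, 20)
        assert chi2 == pytest.approx(100 / 15, abs=1e-12)

    def test_transposition_invariance(self):
        assert sn.chi_square_2x2(7, 13, 21, 9) == pytest.approx(
            sn.chi_square_2x2(7, 21, 13, 9)
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            sn.chi_square_2x2(0, 0, 5, 10)


class TestCronbachAlpha:
    def test_identical_columns_give_one(self, rng):
        col = rng.integers(0, 4, 50).astype(float)
        X = np.column_stack([col] * 5)
        assert sn.cronbach_alpha(X) == pytest.approx(1.0)

    def test_independent_items_near_zero(self, rng):
        X = rng.integers(0, 4, size=(20000, 7)).astype(float)
        assert abs(sn.cronbach_alpha(X)) < 0.05

    def test_hand_table(self):
        X = np.array([[0, 1, 2], [1, 2, 3], [2, 0, 1]], dtype=float)
        k = 3
        item_var = X.var(axis=0, ddof=1).sum()
        total_var = X.sum(axis=1).var(ddof=1)
        expected = k / (k - 1) * (1 - item_var / total_var)
        assert sn.cronbach_alpha(X) == pytest.approx(expected, abs=1e-12)

    def test_zero_total_variance_rejected(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(UndefinedResultError):
            sn.cronbach_alpha(X)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert sn.bh_fdr([0.03]) == pytest.approx([0.03])

    def test_all_equal_stay_equal(self):
        out = sn.bh_fdr([0.2] * 5)
        assert np.allclose(out, 0.2)

    def test_step_up_oracle(self):
        out = sn.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sn.bh_fdr([0.1, 0.0])

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_capped(self, ps):
        adj = sn.bh_fdr(ps)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        assert (adj <= 1.0).all()
        # monotone in the raw p order
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestCompareItemSeverity:
    def make_two_group_table(self, rng, shift_item=None, n=400):
        a = sn.generate_cohort(sn.young_default_config(n=n, seed=31))
        b = sn.generate_cohort(sn.young_default_config(n=n, seed=32))
        b = b.copy()
        b["group"] = "B"
        if shift_item:
            b[shift_item] = np.minimum(b[shift_item] + 1, 3)
        return pd.concat([a, b], ignore_index=True)

    def test_identical_populations_all_null(self, rng):
        table = self.make_two_group_table(rng)
        out = sn.compare_item_severity(table)
        assert len(out) == 14
        assert (out["p_u_fdr"] > 0.05).all()

    def test_shifted_item_detected_specifically(self, rng):
        table = self.make_two_group_table(rng, shift_item="HA5")
        out = sn.compare_item_severity(table).set_index("item")
        assert out.loc["HA5", "p_u_fdr"] < 0.05
        assert out.loc["HA5", "p_t_fdr"] < 0.05

    def test_requires_two_groups(self, random_table):
        with pytest.raises(ValueError):
            sn.compare_item_severity(random_table)


class TestGroupCharacteristics:
    def test_rows_and_statistics_present(self):
        table = sn.generate_two_group_study(
            sn.young_default_config(n=120, seed=1), sn.old_default_config(n=150, seed=2)
        )
        from symptomnet.cohort import score_hads

        out = group_characteristics(table, score_hads(table))
        assert set(out["variable"]) >= {"age", "hads_d_total", "hads_a_total", "sex"}
        sex = out[out["variable"] == "sex"].iloc[0]
        assert sex["statistic"] == "chi2" and 0 < sex["p"] <= 1
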