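import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import oracles
from grslife import analysis
from grslife.analysis import (
    chi2_test,
    fdr_adjust,
    find_cutoff,
    four_group_anova,
    paired_prepost_table,
    stratify_at_median,
    welch_t,
)


class TestFindCutoff:
    def test_perfectly_separated_clusters(self):
        res = find_cutoff([1, 2, 9, 10], [-2, -2, 1, 1], min_class_size=2)
        assert res.cutoff == pytest.approx(5.5)
        assert abs(res.mean_high - res.mean_low) == pytest.approx(3.0)
        assert res.n_high == res.n_low == 2

    def test_all_delta_equal_returns_median_proximal(self):
        scores = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        res = find_cutoff(scores, [1.0] * 6, min_class_size=1)
        # every split ties at objective 0; median is 3.5 -> cutoff 3.5
        assert res.cutoff == pytest.approx(3.5)

    def test_fewer_than_two_distinct_scores(self):
        with pytest.raises(ValueError, match="distinct"):
            find_cutoff([1.0, 1.0, 1.0, 1.0], [0, 1, 2, 3], min_class_size=1)

    def test_min_class_size_respected(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=30)
        y = rng.normal(size=30)
        res = find_cutoff(s, y, min_class_size=10)
        assert res.n_high >= 10 and res.n_low >= 10

    def test_too_small_cohort(self):
        with pytest.raises(ValueError, match="participants"):
            find_cutoff([1, 2, 3], [0, 0, 0], min_class_size=2)

    @pytest.mark.parametrize("criterion", ["mean_diff", "t_stat"])
    def test_matches_bruteforce_oracle(self, criterion):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = rng.integers(4, 13)
            s = np.round(rng.normal(size=n), 3)
            if len(np.unique(s)) < 2:
                continue
            y = rng.normal(size=n)
            res = find_cutoff(s, y, min_class_size=1, criterion=criterion)
            cut, _ = oracles.cutoff_bruteforce(s, y, 1, criterion=criterion)
            assert res.cutoff == pytest.approx(cut, abs=1e-12)

    def test_labels_align_with_cutoff(self):
        s = pd.Series([0.1, 0.9, 0.5, 0.7], index=list("abcd"))
        y = pd.Series([0.0, -1.0, 0.2, -0.8], index=list("abcd"))
        res = find_cutoff(s, y, min_class_size=1)
        assert set(res.labels.index) == set("abcd")
        for pid in "abcd":
            expected = "high" if s[pid] > res.cutoff else "low"
            assert res.labels[pid] == expected

    def test_median_split_balanced(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        y = rng.normal(size=40)
        res = stratify_at_median(s, y)
        assert abs(res.n_high - res.n_low) <= 1


class TestFdrAdjust:
    def test_three_comparison_worked_example(self):
        q = fdr_adjust([0.210, 0.250, 0.0029])
        assert round(q[0], 3) == 0.250
        assert round(q[1], 3) == 0.250
        assert round(q[2], 4) == 0.0087

    def test_single_p_identity(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_textbook_oracle_fixed(self):
        p = [0.01, 0.02, 0.03, 0.04]
        np.testing.assert_allclose(fdr_adjust(p), oracles.bh_stepup(p), atol=1e-14)

    @given(
        st.lists(
            st.floats(0, 1, allow_nan=False, allow_infinity=False),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_textbook_oracle(self, p):
        np.testing.assert_allclose(fdr_adjust(p), oracles.bh_stepup(p), atol=1e-12)

    @given(
        st.lists(
            st.floats(0, 1, allow_nan=False, allow_infinity=False),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_bounded(self, p):
        q = np.asarray(fdr_adjust(p))
        assert (q <= 1.0).all()
        assert (q >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            fdr_adjust([-0.1])
        with pytest.raises(ValueError):
            fdr_adjust([])


class TestFourGroupAnova:
    def _labels(self, cells):
        grs, act, y, ids = [], [], [], []
        i = 0
        for (g, a), values in cells.items():
            for v in values:
                ids.append(f"p{i}")
                grs.append(g)
                act.append(a)
                y.append(v)
                i += 1
        idx = pd.Index(ids)
        return (
            pd.Series(grs, index=idx),
            pd.Series(act, index=idx),
            pd.Series(y, index=idx, dtype=float),
        )

    def test_planted_separation(self):
        rng = np.random.default_rng(0)
        cells = {
            ("high", "active"): rng.normal(-2, 0.01, 10),
            ("high", "inactive"): rng.normal(-1, 0.01, 10),
            ("low", "active"): rng.normal(-1, 0.01, 10),
            ("low", "inactive"): rng.normal(0, 0.01, 10),
        }
        res = four_group_anova(*self._labels(cells))
        assert res.p_value < 1e-6
        assert res.cell_means["high-active"] == pytest.approx(-2, abs=0.05)

    def test_identical_values_f_zero(self):
        cells = {
            (g, a): [1.5] * 5
            for g in ("high", "low")
            for a in ("active", "inactive")
        }
        res = four_group_anova(*self._labels(cells))
        assert res.f_stat == 0.0
        assert res.p_value == 1.0

    def test_empty_cell_named(self):
        cells = {
            ("high", "active"): [1.0, 2.0],
            ("high", "inactive"): [1.0, 2.0],
            ("low", "active"): [1.0, 2.0],
        }
        with pytest.raises(ValueError, match="low-inactive"):
            four_group_anova(*self._labels(cells))

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(7)
        cells = {
            (g, a): rng.normal(0, 1, rng.integers(5, 15))
            for g in ("high", "low")
            for a in ("active", "inactive")
        }
        res = four_group_anova(*self._labels(cells))
        ref = stats.f_oneway(*cells.values())
        assert res.f_stat == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_null_calibration(self):
        # four cells from one normal distribution, n=40/cell, 1000 replicates
        rng = np.random.default_rng(123)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            draws = rng.normal(0, 1, (4, 40))
            ref = stats.f_oneway(*draws)  # same statistic, cheaper loop
            rejections += ref.pvalue < 0.05
        rate = rejections / reps
        assert 0.035 <= rate <= 0.065


class TestPairedPrepostTable:
    def _pheno(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        cols = {"participant_id": [f"P{i}" for i in range(n)]}
        for pre, post in analysis.PREPOST_VARIABLES.values():
            base = rng.normal(50, 10, n)
            cols[pre] = base
            cols[post] = base + rng.normal(-0.5, 1.0, n)
        return pd.DataFrame(cols)

    def test_identity_gives_zero_diff_p_one(self):
        pheno = self._pheno()
        for pre, post in analysis.PREPOST_VARIABLES.values():
            pheno[post] = pheno[pre]
        out = paired_prepost_table(pheno).set_index("variable")
        assert (out["mean_diff"] == 0.0).all()
        assert (out["p_value"] == 1.0).all()

    def test_closed_form_t_from_summary(self):
        # diffs standardized to mean -0.57, sd 1.76, n = 259:
        # |t| = 0.57 / (1.76 / sqrt(259)) ~= 5.21
        rng = np.random.default_rng(4)
        n = 259
        z = rng.normal(size=n)
        z = (z - z.mean()) / z.std(ddof=1)
        diff = -0.57 + 1.76 * z
        pre = rng.normal(19.11, 6.08, n)
        pheno = pd.DataFrame(
            {"participant_id": range(n), "bfm_pre": pre, "bfm_post": pre + diff}
        )
        out = paired_prepost_table(pheno).set_index("variable")
        row = out.loc["body_fat_mass_kg"]
        expected_t = 0.57 / (1.76 / np.sqrt(259))
        assert abs(row["t_stat"]) == pytest.approx(expected_t, abs=1e-9)
        assert row["mean_diff"] == pytest.approx(-0.57, abs=1e-9)
        assert row["sd_diff"] == pytest.approx(1.76, abs=1e-9)

    def test_power_with_planted_drop(self):
        # planted mean drop 0.5 kg, sd 1.8, n = 259 -> p < 0.01 nearly always
        rng = np.random.default_rng(10)
        hits = 0
        reps = 200
        for _ in range(reps):
            pre = rng.normal(19.11, 6.08, 259)
            post = pre + rng.normal(-0.5, 1.8, 259)
            p = stats.ttest_rel(post, pre).pvalue
            hits += p < 0.01
        assert hits / reps >= 0.95

    def test_short_variable_reported_na(self):
        pheno = pd.DataFrame(
            {"participant_id": [0], "bfm_pre": [19.0], "bfm_post": [18.5]}
        )
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = paired_prepost_table(pheno)
        assert np.isnan(out.loc[0, "p_value"])

    def test_schema(self):
        out = paired_prepost_table(self._pheno())
        assert list(out.columns) == [
            "variable", "n", "mean_pre", "sd_pre", "mean_post", "sd_post",
            "mean_diff", "sd_diff", "t_stat", "p_value",
        ]
        assert len(out) == len(analysis.PREPOST_VARIABLES)


class TestGroupSummaryTests:
    def test_chi2_worked_example(self):
        chi2, p = chi2_test([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(60 * 300**2 / 810000, rel=1e-12)  # 6.666...
        assert p == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-12)
        assert p == pytest.approx(0.0098, abs=5e-4)

    def test_chi2_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            chi2_test([[0, 0], [5, 5]])

    def test_welch_identical_groups_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = welch_t(x, x.copy())
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_welch_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            welch_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 2, 20)
        t, p = welch_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestNullSelectionEffect:
    def test_median_cutoff_min_q_calibrated(self, null_calibration):
        frac = (null_calibration["median_min_q"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_optimized_cutoff_inflates_min_q_rate(self, null_calibration):
        frac_opt = (null_calibration["opt_min_q"] < 0.05).mean()
        frac_med = (null_calibration["median_min_q"] < 0.05).mean()
        assert frac_opt > 0.05
        assert frac_opt > frac_med
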