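import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ffnquant import ci95_mean, mixed_anova, rm_anova, t_test


def _long(table, groups=None):
    """subjects x conditions array -> long DataFrame (optionally grouped)."""
    n, k = table.shape
    rows = []
    for i in range(n):
        for j in range(k):
            rows.append(
                {
                    "subject": f"s{i}",
                    "region": groups[i] if groups else "all",
                    "condition": f"c{j}",
                    "value": table[i, j],
                }
            )
    return pd.DataFrame(rows)


class TestTTest:
    def test_identical_unpaired_groups(self):
        res = t_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.ci95[0] < 0 < res.ci95[1]

    def test_paired_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            t_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], paired=True)

    def test_unpaired_matches_scipy_oracle(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1.3, 17)
        res = t_test(x, y)
        oracle = sps.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(oracle.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(oracle.pvalue, abs=1e-10)
        assert res.df == x.size + y.size - 2

    def test_welch_matches_scipy_oracle(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 3.0, 25)
        res = t_test(x, y, welch=True)
        oracle = sps.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(oracle.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(oracle.pvalue, abs=1e-10)

    def test_paired_matches_scipy_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 14)
        y = x + rng.normal(0.4, 0.5, 14)
        res = t_test(x, y, paired=True)
        oracle = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(oracle.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(oracle.pvalue, abs=1e-10)

    def test_ci95_contains_true_difference_usually(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(200):
            x = rng.normal(1.0, 1.0, 15)
            y = rng.normal(0.0, 1.0, 15)
            lo, hi = t_test(x, y).ci95
            hits += lo <= 1.0 <= hi
        assert hits >= 180

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            t_test([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])


class TestCI95:
    def test_constant_data_zero_width(self):
        lo, hi = ci95_mean([3.0, 3.0, 3.0, 3.0])
        assert lo == hi == pytest.approx(3.0)

    def test_worked_example(self):
        # x = [0, 0, 10, 10]: mean 5, SEM 2.8868, t(.975, 3) = 3.1824
        lo, hi = ci95_mean([0.0, 0.0, 10.0, 10.0])
        assert lo == pytest.approx(-4.1874, abs=1e-3)
        assert hi == pytest.approx(14.1874, abs=1e-3)

    def test_width_shrinks_as_sqrt_n(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        lo1, hi1 = ci95_mean(np.tile(x, 4))
        lo2, hi2 = ci95_mean(np.tile(x, 16))
        # replicating 4x halves the SEM; t quantile also shrinks slightly
        assert (hi2 - lo2) < (hi1 - lo1) / 1.9

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            ci95_mean([1.0])


class TestRMAnova:
    def test_all_cells_equal(self):
        table = rm_anova(np.full((5, 3), 7.0))
        row = table[table.effect == "condition"].iloc[0]
        assert row.F == 0.0
        assert row.p == 1.0

    def test_hand_partition_oracle_3x3(self):
        data = np.array([[1.0, 2.0, 4.0], [2.0, 4.0, 6.0], [3.0, 3.0, 8.0]])
        table = rm_anova(data)
        # independent hand computation of the SS partition
        grand = data.mean()
        ss_cond = 3 * sum((data[:, j].mean() - grand) ** 2 for j in range(3))
        ss_subj = 3 * sum((data[i, :].mean() - grand) ** 2 for i in range(3))
        ss_tot = ((data - grand) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        got = {r.effect: r.ss for r in table.itertuples()}
        assert got["condition"] == pytest.approx(ss_cond, abs=1e-9)
        assert got["subject"] == pytest.approx(ss_subj, abs=1e-9)
        assert got["error"] == pytest.approx(ss_err, abs=1e-9)
        f = (ss_cond / 2) / (ss_err / 4)
        row = table[table.effect == "condition"].iloc[0]
        assert row.F == pytest.approx(f, abs=1e-9)
        assert row.p == pytest.approx(float(sps.f.sf(f, 2, 4)), abs=1e-12)

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        data = rng.normal(size=(8, 4)) + rng.normal(size=(8, 1))
        table = rm_anova(data)
        long = _long(data)
        oracle = pingouin.rm_anova(
            data=long, dv="value", within="condition", subject="subject", detailed=True
        )
        row = table[table.effect == "condition"].iloc[0]
        assert row.F == pytest.approx(oracle.loc[0, "F"], abs=1e-9)
        assert row.p == pytest.approx(oracle.loc[0, "p_unc"], abs=1e-9)
        assert row.ss == pytest.approx(oracle.loc[0, "SS"], abs=1e-9)

    def test_two_conditions_reproduce_paired_t(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(10, 2))
        f = rm_anova(data)[lambda d: d.effect == "condition"].iloc[0].F
        t = t_test(data[:, 0], data[:, 1], paired=True).statistic
        assert f == pytest.approx(t**2, abs=1e-9)

    def test_within_subject_effect_detected(self):
        # graded within-subject effect (adjacent-level d = 1.5), n = 16
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(50):
            base = rng.normal(0, 1, size=(16, 1))
            data = base + rng.normal(0, 1, size=(16, 3))
            data += np.array([0.0, 1.5, 3.0])
            p = rm_anova(data)[lambda d: d.effect == "condition"].iloc[0].p
            hits += p < 0.001
        assert hits >= 45  # >= 90 % of seeds

    def test_missing_cells_rejected(self):
        data = np.full((4, 3), 1.0)
        data[2, 1] = np.nan
        with pytest.raises(ValueError):
            rm_anova(data)


class TestMixedAnova:
    def test_all_equal_gives_zero_f(self):
        df = _long(np.full((6, 3), 2.0), groups=["a"] * 3 + ["b"] * 3)
        table = mixed_anova(df)
        for effect in ("region", "condition", "interaction"):
            assert table[table.effect == effect].iloc[0].F == 0.0

    def test_matches_pingouin_oracle_balanced(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        data = rng.normal(size=(10, 3))
        data[5:] += np.array([0.0, 0.5, 1.5])  # group x condition interaction
        groups = ["striatum"] * 5 + ["GPe"] * 5
        table = mixed_anova(_long(data, groups))
        oracle = pingouin.mixed_anova(
            data=_long(data, groups),
            dv="value",
            within="condition",
            between="region",
            subject="subject",
        )
        ours = {r.effect: r for r in table.itertuples()}
        theirs = oracle.set_index("Source")
        assert ours["region"].F == pytest.approx(theirs.loc["region", "F"], abs=1e-9)
        assert ours["condition"].F == pytest.approx(
            theirs.loc["condition", "F"], abs=1e-9
        )
        assert ours["interaction"].F == pytest.approx(
            theirs.loc["Interaction", "F"], abs=1e-9
        )
        assert ours["interaction"].p == pytest.approx(
            theirs.loc["Interaction", "p_unc"], abs=1e-9
        )

    def test_interaction_detected_at_study_like_n(self):
        # calcium slope larger in one region (9 vs 16 subjects, 3 levels)
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(50):
            stri = rng.normal(0, 1, size=(9, 1)) + rng.normal(0, 0.5, size=(9, 3))
            stri += np.array([0.0, 2.0, 4.0])
            gpe = rng.normal(0, 1, size=(16, 1)) + rng.normal(0, 0.5, size=(16, 3))
            gpe += np.array([0.0, 0.7, 1.4])
            data = np.vstack([stri, gpe])
            df = _long(data, groups=["striatum"] * 9 + ["GPe"] * 16)
            p = mixed_anova(df)[lambda d: d.effect == "interaction"].iloc[0].p
            hits += p < 0.05
        assert hits >= 40  # >= 80 % of seeds

    def test_single_subject_group_rejected(self):
        df = _long(np.ones((4, 2)), groups=["a", "b", "b", "b"])
        with pytest.raises(ValueError):
            mixed_anova(df)

    def test_incomplete_within_data_rejected(self):
        df = _long(np.ones((4, 2)), groups=["a", "a", "b", "b"])
        df = df.drop(index=3)
        with pytest.raises(ValueError):
            mixed_anova(df)
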