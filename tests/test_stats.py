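import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as st

from stripephot import stats as sst


class TestOneSampleT:
    def test_closed_form_example(self):
        res = sst.one_sample_t([1.0, 2.0, 3.0], 0.0)
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-10)
        assert round(res.t, 4) == 3.4641
        assert res.df == 2

    def test_symmetric_values_give_zero_t(self):
        res = sst.one_sample_t([-1.0, 1.0], 0.0)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_zero_variance_and_short_input_rejected(self):
        with pytest.raises(sst.StatisticsError):
            sst.one_sample_t([2.0, 2.0, 2.0], 0.0)
        with pytest.raises(sst.StatisticsError):
            sst.one_sample_t([1.0], 0.0)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(12) + 0.4
        res = sst.one_sample_t(x, 0.2)
        ref = st.ttest_1samp(x, 0.2)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)


class TestPairedT:
    def test_reduces_to_one_sample_on_differences(self):
        a = np.array([2.0, 4.0, 6.0])
        b = a - np.array([1.0, 2.0, 3.0])
        res = sst.paired_t(a, b)
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-10)

    def test_antisymmetric_in_argument_order(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(8), rng.standard_normal(8)
        assert sst.paired_t(a, b).t == -sst.paired_t(b, a).t

    def test_identical_samples_rejected(self):
        a = np.arange(5.0)
        with pytest.raises(sst.StatisticsError):
            sst.paired_t(a, a)
        with pytest.raises(ValueError):
            sst.paired_t(a, a[:-1])


class TestSidak:
    @pytest.mark.parametrize("p, m, expected", [
        (0.0, 5, 0.0),
        (0.37, 1, 0.37),
        (0.01, 3, 0.029701),
    ])
    def test_closed_form(self, p, m, expected):
        assert sst.sidak_adjust(p, m) == pytest.approx(expected, abs=1e-12)

    @given(hst.floats(0, 1), hst.floats(0, 1), hst.integers(1, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_p_and_m(self, p1, p2, m):
        lo, hi = sorted([p1, p2])
        assert sst.sidak_adjust(lo, m) <= sst.sidak_adjust(hi, m) + 1e-12
        assert sst.sidak_adjust(lo, m) <= sst.sidak_adjust(lo, m + 1) + 1e-12
        assert sst.sidak_adjust(lo, m) >= lo - 1e-12


class TestLogTransformAndColocalization:
    def test_log_examples(self):
        np.testing.assert_allclose(sst.log_transform_counts([0, 9, 99]), [0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            sst.log_transform_counts([-1.0])

    def test_colocalization_examples(self):
        assert sst.colocalization_percent(1207, 1252) == 96.4
        assert sst.colocalization_percent(0, 10) == 0.0
        assert sst.colocalization_percent(10, 10) == 100.0
        with pytest.raises(ValueError):
            sst.colocalization_percent(1, 0)


def _mixed_table(seed=2, a=2, s=4, b=3, group_effect=0.0, time_effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for gi in range(a):
        for si in range(s):
            subj_bias = rng.standard_normal() * 0.5
            for ti in range(b):
                rows.append({
                    "subject": f"g{gi}s{si}", "between": f"g{gi}", "within": f"t{ti}",
                    "value": rng.standard_normal() + subj_bias
                    + gi * group_effect + ti * time_effect,
                })
    return pd.DataFrame(rows)


def _ss_oracle(df):
    """Explicit mean-deviation sums for the balanced mixed design."""
    y = df["value"].to_numpy()
    grand = y.mean()
    a_levels = sorted(df["between"].unique())
    b_levels = sorted(df["within"].unique())
    s = df["subject"].nunique() // len(a_levels)
    ss_a = sum(
        len(b_levels) * s * (df[df.between == g]["value"].mean() - grand) ** 2
        for g in a_levels)
    ss_b = sum(
        len(a_levels) * s * (df[df.within == t]["value"].mean() - grand) ** 2
        for t in b_levels)
    ss_ab = 0.0
    for g in a_levels:
        for t in b_levels:
            cell = df[(df.between == g) & (df.within == t)]["value"].mean()
            ss_ab += s * (cell - df[df.between == g]["value"].mean()
                          - df[df.within == t]["value"].mean() + grand) ** 2
    ss_subj = 0.0
    for subj in df["subject"].unique():
        sub = df[df.subject == subj]
        g = sub["between"].iloc[0]
        ss_subj += len(b_levels) * (sub["value"].mean()
                                    - df[df.between == g]["value"].mean()) ** 2
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_a - ss_b - ss_ab - ss_subj
    return {"A": ss_a, "B": ss_b, "AB": ss_ab, "subj": ss_subj, "err": ss_err}


class TestMixedAnova:
    def test_identical_groups_give_zero_between_f(self):
        df = _mixed_table(seed=3)
        half = df[df.between == "g0"].copy()
        clone = half.copy()
        clone["between"] = "g1"
        clone["subject"] = clone["subject"].str.replace("g0", "g1")
        res = sst.mixed_anova(pd.concat([half, clone], ignore_index=True))
        assert res.effects.loc[0, "F"] == pytest.approx(0.0, abs=1e-12)

    def test_ss_terms_match_definition_oracle(self):
        df = _mixed_table(seed=4, group_effect=0.5, time_effect=0.2)
        res = sst.mixed_anova(df)
        oracle = _ss_oracle(df)
        eff = res.effects.set_index("Source")
        assert eff.loc["between", "SS"] == pytest.approx(oracle["A"], abs=1e-9)
        assert eff.loc["within", "SS"] == pytest.approx(oracle["B"], abs=1e-9)
        assert eff.loc["between * within", "SS"] == pytest.approx(oracle["AB"], abs=1e-9)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        df = _mixed_table(seed=5, group_effect=0.5, time_effect=0.2)
        res = sst.mixed_anova(df)
        ref = pg.mixed_anova(data=df, dv="value", within="within",
                             subject="subject", between="between")
        np.testing.assert_allclose(res.effects["F"].to_numpy(),
                                   ref["F"].to_numpy(), atol=1e-9)
        np.testing.assert_allclose(res.effects["p"].to_numpy(),
                                   ref["p_unc"].to_numpy(), atol=1e-9)

    def test_unbalanced_design_lists_missing_cells(self):
        df = _mixed_table(seed=6).iloc[:-1]
        with pytest.raises(sst.StatisticsError, match="g1s3"):
            sst.mixed_anova(df)

    def test_within_level_relabeling_leaves_f_unchanged(self):
        df = _mixed_table(seed=7, time_effect=0.3)
        relabeled = df.copy()
        relabeled["within"] = relabeled["within"].map({"t0": "t2", "t1": "t0", "t2": "t1"})
        f1 = sst.mixed_anova(df).effects["F"].to_numpy()
        f2 = sst.mixed_anova(relabeled).effects["F"].to_numpy()
        np.testing.assert_allclose(f1, f2, atol=1e-9)

    def test_posthoc_sidak_family(self):
        df = _mixed_table(seed=8, group_effect=1.0)
        res = sst.mixed_anova(df)
        assert len(res.posthoc) == 3  # 2 groups -> 1 pair x 3 within levels
        assert (res.posthoc["p_sidak"] >= res.posthoc["p_raw"] - 1e-12).all()
        row = res.posthoc.iloc[0]
        assert row["p_sidak"] == pytest.approx(sst.sidak_adjust(row["p_raw"], 3), abs=1e-12)
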