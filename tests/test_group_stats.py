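import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gpcrquant.group_stats import (
    anova_tukey,
    bootstrap_ci,
    classify_rescue,
    compare_mating,
    mating_efficiency,
    normalize_percent,
    summarize_groups,
    welch_t,
)


def meas(groups_values):
    rows = []
    for g, vals in groups_values.items():
        for i, v in enumerate(vals):
            rows.append({"image": "i", "cell_id": i, "group": g,
                         "mean_ring_intensity": float(v)})
    return pd.DataFrame(rows)


class TestNormalizePercent:
    def test_test_value_vs_control_mean(self):
        df = meas({"ctrl": [200, 200], "test": [100]})
        out = normalize_percent(df, "ctrl")
        assert out.loc[out["group"] == "test", "percent"].iloc[0] == pytest.approx(50.0)

    def test_control_group_averages_100(self, rng):
        df = meas({"ctrl": rng.uniform(100, 500, 40)})
        out = normalize_percent(df, "ctrl")
        assert out["percent"].mean() == pytest.approx(100.0)

    def test_strata_normalized_independently(self):
        df = pd.concat(
            [
                meas({"ctrl": [100, 100], "test": [50]}).assign(time=0),
                meas({"ctrl": [200, 200], "test": [50]}).assign(time=1),
            ]
        )
        out = normalize_percent(df, "ctrl", stratum="time")
        t0 = out[(out["group"] == "test") & (out["time"] == 0)]["percent"].iloc[0]
        t1 = out[(out["group"] == "test") & (out["time"] == 1)]["percent"].iloc[0]
        assert (t0, t1) == (pytest.approx(50.0), pytest.approx(25.0))

    def test_scale_invariance(self, rng):
        df = meas({"ctrl": rng.uniform(1, 2, 20), "test": rng.uniform(1, 2, 20)})
        a = normalize_percent(df, "ctrl")["percent"]
        df2 = df.assign(mean_ring_intensity=df["mean_ring_intensity"] * 17.3)
        b = normalize_percent(df2, "ctrl")["percent"]
        np.testing.assert_allclose(a, b)

    def test_nonpositive_control_mean_errors(self):
        with pytest.raises(ValueError, match="not positive"):
            normalize_percent(meas({"ctrl": [-5, 5], "t": [1]}), "ctrl")

    def test_summary_ci_brackets_mean(self, rng):
        df = meas({"ctrl": rng.normal(300, 30, 60), "t": rng.normal(150, 30, 60)})
        out = summarize_groups(normalize_percent(df, "ctrl"), B=1000, seed=5)
        for _, row in out.iterrows():
            assert row["ci_lo"] <= row["mean_percent"] <= row["ci_hi"]


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_textbook_example(self):
        t, df, p = welch_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.2878, abs=1e-3)

    def test_one_tailed_is_half_two_tailed_in_matching_direction(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 2, 15)
        _, _, p2 = welch_t(a, b, tails=2)
        direction = "less" if a.mean() < b.mean() else "greater"
        _, _, p1 = welch_t(a, b, tails=1, direction=direction)
        assert p1 == pytest.approx(p2 / 2)

    def test_antisymmetric_in_arguments(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 2, 14)
        ta, _, pa = welch_t(a, b)
        tb, _, pb = welch_t(b, a)
        assert ta == pytest.approx(-tb)
        assert pa == pytest.approx(pb)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestBootstrap:
    def test_constant_sample_degenerate_interval(self):
        assert bootstrap_ci([3.0, 3.0, 3.0, 3.0], B=200, seed=1) == (3.0, 3.0)

    def test_deterministic_given_seed(self, rng):
        vals = rng.normal(0, 1, 30)
        assert bootstrap_ci(vals, B=500, seed=7) == bootstrap_ci(vals, B=500, seed=7)
        assert bootstrap_ci(vals, B=500, seed=7) != bootstrap_ci(vals, B=500, seed=8)


class TestAnovaTukey:
    def test_two_groups_match_pooled_t(self, rng):
        """For k = 2 the HSD p equals the pooled-variance two-sample t test
        (studentized range q = t * sqrt(2))."""
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.7, 1, 25)
        _, _, mat = anova_tukey({"a": a, "b": b})
        _, p_pooled = sps.ttest_ind(a, b, equal_var=True)
        assert mat.loc["a", "b"] == pytest.approx(p_pooled, rel=1e-4)

    def test_effect_size_sanity(self, rng):
        groups = {
            "a": rng.normal(0, 1, 50), "b": rng.normal(0, 1, 50),
            "c": rng.normal(10, 1, 50), "d": rng.normal(10, 1, 50),
        }
        F, p, mat = anova_tukey(groups)
        assert p < 1e-10
        assert mat.loc["a", "c"] < 1e-6 and mat.loc["b", "d"] < 1e-6
        assert mat.loc["a", "b"] > 0.5 and mat.loc["c", "d"] > 0.5

    def test_pairwise_matrix_symmetric_in_unit_interval(self, rng):
        groups = {g: rng.normal(0, 1, 12) for g in "abcd"}
        _, _, mat = anova_tukey(groups)
        np.testing.assert_allclose(mat.values, mat.values.T)
        assert ((mat.values >= 0) & (mat.values <= 1)).all()

    def test_tukey_p_not_below_unadjusted_pooled_t(self, rng):
        groups = {g: rng.normal(0, 1, 15) for g in "abcd"}
        _, _, mat = anova_tukey(groups)
        for x, y in itertools.combinations("abcd", 2):
            _, p_raw = sps.ttest_ind(groups[x], groups[y], equal_var=True)
            assert mat.loc[x, y] >= p_raw - 1e-12

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            anova_tukey({"a": [1.0, 2.0], "b": [1.0]})


class TestClassifyRescue:
    def _matrix(self, p_u, p_t):
        names = ["wt_untreated", "wt_treated", "m_untreated", "m_treated"]
        mat = pd.DataFrame(1.0, index=names, columns=names)
        mat.loc["m_treated", "wt_untreated"] = mat.loc["wt_untreated", "m_treated"] = p_u
        mat.loc["m_treated", "wt_treated"] = mat.loc["wt_treated", "m_treated"] = p_t
        return mat

    @pytest.mark.parametrize(
        "p_u,p_t,expected",
        [
            (0.001, 0.80, "no_rescue"),
            (0.001, 0.001, "partial_rescue"),
            (0.60, 0.01, "complete_rescue"),
            (0.60, 0.80, "indeterminate"),
        ],
    )
    def test_category_rule_exhaustive(self, p_u, p_t, expected):
        res = classify_rescue(self._matrix(p_u, p_t), strain="m", alpha=0.05)
        assert res.category == expected
        assert res.p_vs_wt_untreated == p_u
        assert res.p_vs_wt_treated == p_t

    def test_missing_group_errors(self):
        mat = self._matrix(0.5, 0.5).drop(index="wt_treated", columns="wt_treated")
        with pytest.raises(KeyError):
            classify_rescue(mat, strain="m")


class TestMatingEfficiency:
    def _counts(self, **over):
        row = {
            "assay_id": "a1", "treatment": "control",
            "competent_colonies": 100, "diploid_colonies": 50,
            "dilution_competent": 1.0, "dilution_diploid": 1.0,
        }
        row.update(over)
        return pd.DataFrame([row])

    def test_simple_percentage(self):
        out = mating_efficiency(self._counts())
        assert out["efficiency_percent"].iloc[0] == pytest.approx(50.0)

    def test_dilution_correction(self):
        out = mating_efficiency(
            self._counts(diploid_colonies=39, dilution_diploid=10.0,
                         competent_colonies=50, dilution_competent=100.0)
        )
        assert out["efficiency_percent"].iloc[0] == pytest.approx(7.8)

    def test_diploid_exceeding_competent_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            mating_efficiency(self._counts(diploid_colonies=120))

    def test_zero_competent_errors(self):
        with pytest.raises(ValueError, match="zero mating-competent"):
            mating_efficiency(self._counts(competent_colonies=0, diploid_colonies=0))

    def test_one_tailed_group_comparison(self, rng):
        rows = []
        for i in range(5):
            rows.append({"assay_id": f"c{i}", "treatment": "control",
                         "competent_colonies": 500,
                         "diploid_colonies": int(390 + rng.integers(-20, 20)),
                         "dilution_competent": 1.0, "dilution_diploid": 1.0})
            rows.append({"assay_id": f"t{i}", "treatment": "rapamycin",
                         "competent_colonies": 500,
                         "diploid_colonies": int(265 + rng.integers(-20, 20)),
                         "dilution_competent": 1.0, "dilution_diploid": 1.0})
        eff = mating_efficiency(pd.DataFrame(rows))
        t, df, p = compare_mating(eff, treated="rapamycin", control="control")
        assert t < 0 and p < 0.05
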