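"""Comparison layer: gates, transforms, linear models, PERMANOVA,
contrasts, FDR, two-sample tests — each against an independent oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from reefphys import stats


class TestNormalityGate:
    def test_level_on_normal_samples(self):
        rng = np.random.default_rng(0)
        passes = sum(
            stats.normality_gate(rng.normal(0, 1, 50))[2] for _ in range(1000)
        )
        assert passes >= 900  # level ~5%: passes ~95% of the time

    def test_power_on_exponential_samples(self):
        rng = np.random.default_rng(1)
        fails = sum(
            not stats.normality_gate(rng.exponential(1, 100))[2]
            for _ in range(200)
        )
        assert fails >= 190  # >= 95% rejection

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            stats.normality_gate([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            stats.normality_gate([1.0, 2.0])


class TestTukeyLadder:
    def test_identity_preferred_for_normal_data(self):
        rng = np.random.default_rng(2)
        hits = sum(
            stats.tukey_ladder(rng.normal(10, 1, 60))[0] == 1.0
            for _ in range(200)
        )
        assert hits >= 150  # vast majority keep lambda = 1

    def test_log_recovers_lognormal(self):
        rng = np.random.default_rng(3)
        hits = sum(
            stats.tukey_ladder(rng.lognormal(0, 1, 80))[0] == 0.0
            for _ in range(200)
        )
        assert hits >= 150

    def test_zero_triggers_recorded_shift(self):
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0])
        _lam, _z, notes = stats.tukey_ladder(y)
        assert notes["shift"] == pytest.approx(1.0)

    def test_negative_lambda_preserves_order(self):
        y = np.array([1.0, 2.0, 4.0, 9.0])
        z = stats._ladder_transform(y, -1.0)
        assert np.all(np.diff(z) > 0)


class TestLinearModel:
    @staticmethod
    def _frame(rng, delta=0.0, n=10):
        temps = np.tile(np.repeat([22.0, 27.0, 31.5], n), 2)
        region = np.repeat(["AG", "GO"], 3 * n)
        y = rng.normal(0, 1, temps.size) + delta * (region == "GO")
        return pd.DataFrame({"value": y, "acclimation_temp": temps,
                             "region": region})

    def test_type1_error_of_region_test(self):
        rng = np.random.default_rng(4)
        rej = sum(
            stats.linear_model_anova(self._frame(rng), "value")[0]
            .loc["C(region)", "PR(>F)"] < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rej / 400 <= 0.09

    def test_power_against_two_sd_shift(self):
        rng = np.random.default_rng(5)
        rej = sum(
            stats.linear_model_anova(self._frame(rng, delta=2.0), "value")[0]
            .loc["C(region)", "PR(>F)"] < 0.05
            for _ in range(100)
        )
        assert rej >= 99

    def test_balanced_design_type1_equals_type2(self):
        rng = np.random.default_rng(6)
        df = self._frame(rng)
        t1, _, _ = stats.linear_model_anova(df, "value", ss_type=1)
        t2, _, _ = stats.linear_model_anova(df, "value", ss_type=2)
        for term in ("C(acclimation_temp)", "C(region)"):
            assert t1.loc[term, "sum_sq"] == pytest.approx(
                t2.loc[term, "sum_sq"], abs=1e-9
            )

    def test_empty_cell_drops_interaction(self, caplog):
        rng = np.random.default_rng(7)
        df = self._frame(rng)
        df = df[~((df["region"] == "GO") & (df["acclimation_temp"] == 31.5))]
        table, _, _ = stats.linear_model_anova(df, "value")
        assert not any("C(acclimation_temp):C(region)" in t for t in table.index)

    def test_mass_covariate_enters_model(self):
        rng = np.random.default_rng(8)
        df = self._frame(rng)
        df["mass_g"] = rng.lognormal(0, 0.3, len(df))
        table, _, _ = stats.linear_model_anova(df, "value", mass_col="mass_g")
        assert "mass_g" in table.index


class TestPermanova:
    def test_identical_observations_are_an_error(self):
        with pytest.raises(ValueError):
            stats.permanova(np.ones(8), np.repeat(["a", "b"], 4))

    def test_exact_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(9)
        y = rng.normal(0, 1, 8)
        labels = np.repeat(["a", "b"], 4)
        res = stats.permanova(y, labels, exact=True)
        f_obs = sps.f_oneway(y[:4], y[4:]).statistic
        count = 0
        for combo in itertools.combinations(range(8), 4):
            in_a = np.zeros(8, bool)
            in_a[list(combo)] = True
            f = sps.f_oneway(y[in_a], y[~in_a]).statistic
            count += f >= f_obs - 1e-12
        assert res.n_perm == 70
        assert res.p_raw == pytest.approx(count / 70, abs=1e-12)
        assert res.statistic == pytest.approx(f_obs, abs=1e-9)

    def test_univariate_pseudo_f_equals_anova_f(self):
        rng = np.random.default_rng(10)
        y = rng.normal(0, 1, 30)
        g = np.repeat(["a", "b", "c"], 10)
        res = stats.permanova(y, g, n_perm=49, seed=0)
        f = sps.f_oneway(y[:10], y[10:20], y[20:]).statistic
        assert res.statistic == pytest.approx(f, abs=1e-9)

    def test_two_factor_sequential_ss_matches_type1_anova(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({
            "t": np.tile(np.repeat(["a", "b", "c"], 4), 2),
            "r": np.repeat(["AG", "GO"], 12),
        })
        y = rng.normal(0, 1, 24)
        res = stats.permanova(y, df, n_perm=19, seed=0)
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        frame = df.assign(y=y)
        tab = anova_lm(smf.ols("y ~ C(t) * C(r)", frame).fit(), typ=1)
        for r, term in zip(res, ("C(t)", "C(r)", "C(t):C(r)")):
            assert r.statistic == pytest.approx(tab.loc[term, "F"], abs=1e-9)

    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(12)
        y = rng.normal(0, 1, 20)
        g = np.repeat(["a", "b"], 10)
        a = stats.permanova(y, g, n_perm=199, seed=7)
        b = stats.permanova(y, g, n_perm=199, seed=7)
        assert a.p_raw == b.p_raw

    def test_multivariate_groups_detected(self):
        rng = np.random.default_rng(13)
        x = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(2.0, 1, (10, 3))])
        res = stats.permanova(x, np.repeat(["a", "b"], 10), n_perm=199, seed=0)
        assert res.p_raw < 0.05


class TestContrastsAndFDR:
    def test_bh_fixture_and_trivial_cases(self):
        assert np.allclose(stats.bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)
        assert stats.bh_fdr([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(stats.bh_fdr([0.2, 0.2, 0.2]), 0.2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_bh_matches_reference_implementation(self, pvals):
        got = stats.bh_fdr(pvals)
        want = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(got, want, atol=1e-12)
        assert np.all(got >= np.asarray(pvals) - 1e-15)  # adjusted >= raw

    def test_five_levels_give_ten_contrasts(self):
        rng = np.random.default_rng(14)
        y = rng.normal(0, 1, 50)
        g = np.repeat(list("abcde"), 10)
        res = stats.pairwise_contrasts(y, g)
        assert len(res) == 10
        assert all(r.p_adjusted >= r.p_raw - 1e-15 for r in res)

    def test_divergent_cell_drives_significant_contrasts(self):
        """One temperature cell shifted by 3 SD: after BH, contrasts that
        involve that cell are significant and (almost always) only those."""
        rng = np.random.default_rng(15)
        good = 0
        for _ in range(200):
            y = rng.normal(0, 1, 50)
            g = np.repeat(list("abcde"), 10)
            y[g == "e"] += 3.0
            res = stats.pairwise_contrasts(y, g)
            sig = {r.test_name for r in res if r.p_adjusted < 0.05}
            involving_e = {r.test_name for r in res if "e" in r.test_name}
            assert involving_e <= sig  # the shifted cell is always detected
            good += sig == involving_e
        # BH controls the false-discovery *rate*, so with four certain
        # discoveries some null contrasts slip through occasionally
        assert good >= 160

    def test_permanova_path(self):
        rng = np.random.default_rng(16)
        y = np.concatenate([rng.normal(0, 1, 8), rng.normal(4, 1, 8),
                            rng.normal(0, 1, 8)])
        g = np.repeat(["a", "b", "c"], 8)
        res = stats.pairwise_contrasts(y, g, method="permanova", n_perm=199,
                                       seed=3)
        assert len(res) == 3
        by_name = {r.test_name: r for r in res}
        assert by_name["permanova[a - b]"].p_adjusted < 0.05
        assert by_name["permanova[a - c]"].p_adjusted > 0.05


class TestTwoSample:
    def test_identical_samples(self):
        r = stats.two_sample_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_raw == pytest.approx(1.0)

    def test_pooled_t_hand_formula(self):
        r = stats.two_sample_test([1, 2, 3], [2, 3, 4])
        assert r.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert r.df == 4
        assert r.p_raw == pytest.approx(0.288, abs=1e-3)

    def test_exact_mann_whitney_enumeration(self):
        r = stats.two_sample_test([1.0, 2.0], [3.0, 4.0], "mann_whitney")
        assert r.p_raw == pytest.approx(1.0 / 3.0)
        assert r.method_notes["method"] == "exact"

    def test_zero_variance_both_groups(self):
        with pytest.raises(ValueError):
            stats.two_sample_test([1.0, 1.0], [1.0, 1.0])


class TestAutoCompare:
    @staticmethod
    def _frame(rng, skew=False):
        temps = np.tile(np.repeat([22.0, 27.0, 31.5], 8), 2)
        region = np.repeat(["AG", "GO"], 24)
        if skew:
            y = rng.lognormal(0, 1.5, temps.size) ** 2
        else:
            y = rng.normal(10, 1, temps.size)
        return pd.DataFrame({"value": y, "acclimation_temp": temps,
                             "region": region})

    def test_normal_residuals_stay_with_lm(self):
        res = stats.auto_compare(self._frame(np.random.default_rng(17)),
                                 "value", n_perm=99)
        assert res.method == "lm"
        assert res.anova_table is not None

    def test_cascade_reaches_transform_or_permanova_on_skewed_data(self):
        res = stats.auto_compare(self._frame(np.random.default_rng(18),
                                             skew=True), "value", n_perm=99)
        assert res.method in ("lm_transformed", "permanova")
        assert res.notes["transform"] is not None
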